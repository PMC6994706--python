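"""Shared fixtures: the default phantom pipeline bundle is expensive
(~30 s, dominated by the exhaustive trajectory search), so it is built once
per session and shared across planner, ablation, disconnection and
acceptance tests."""

from dataclasses import dataclass

import numpy as np
import pytest

from callosoplan import (
    DisconnectionReport,
    LabelVolume,
    PlanSet,
    StreamlineSet,
    VesselTree,
    assess_plan,
    combined_cavity,
    make_head_phantom,
    make_interhemispheric_streamlines,
    plan_callosotomy,
    rasterise_vessels,
    simulate_cavity,
    split_anterior_two_thirds,
)
from callosoplan.ablation import AblationCavity
from callosoplan.phantom import PhantomConfig, adversarial_config


@dataclass
class PhantomBundle:
    config: PhantomConfig
    parcellation: LabelVolume
    tree: VesselTree
    vessels: LabelVolume
    streamlines: StreamlineSet
    plan: PlanSet
    cavities: list[AblationCavity]
    union: np.ndarray
    cc_vol: LabelVolume
    anterior_mask: np.ndarray
    splenium_mask: np.ndarray
    report: DisconnectionReport


def _build_bundle(config: PhantomConfig) -> PhantomBundle:
    vol, tree = make_head_phantom(config)
    vessels = rasterise_vessels(tree, vol.grid)
    streamlines = make_interhemispheric_streamlines(
        vol, config.n_streamlines, config.seed, config)
    plan = plan_callosotomy(vol, None, vessels)
    cc_vol = LabelVolume(vol.grid,
                         vol.role_mask("corpus_callosum").astype(np.uint8))
    cavities = [simulate_cavity(plan.selected[r].trajectory, cc_vol)
                for r in ("anterior", "middle", "posterior")
                if r in plan.selected]
    union = combined_cavity(cavities)
    anterior, splenium = split_anterior_two_thirds(cc_vol)
    report = assess_plan(union, streamlines, cc_vol)
    return PhantomBundle(config, vol, tree, vessels, streamlines, plan,
                         cavities, union, cc_vol, anterior, splenium, report)


@pytest.fixture(scope="session")
def default_bundle() -> PhantomBundle:
    """Default 96³ phantom at seed 7, planned and assessed end to end."""
    return _build_bundle(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def adversarial_bundle() -> PhantomBundle:
    """Phantom with the frontal vascular wall sealing the rostrum approach."""
    return _build_bundle(adversarial_config(PhantomConfig(seed=7)))


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig(seed=7)
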