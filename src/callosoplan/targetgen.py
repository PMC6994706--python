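"""Automatic target- and entry-region generation from a labelled parcellation.

The three callosal target regions (anterior, middle, posterior) are produced
by dilating the subcallosal gyrus and the cingulate subregions by a fixed
radius (default 7 mm), intersecting adjacent pairs, and constraining each
overlap to the corpus callosum: the pairs (subcallosal, anterior cingulate),
(anterior, middle cingulate) and (middle, posterior cingulate) yield the
anterior, middle and posterior targets at the rostrum, genu and posterior
body respectively.  Dilation is an exact Euclidean-distance-transform
threshold, so the radius has true millimetre semantics on anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .volio import LabelVolume, SchemaError, voxel_to_world

__all__ = [
    "TargetRegions",
    "EntryRegions",
    "TargetGenerationError",
    "dilate_mask",
    "generate_targets",
    "extract_entry_regions",
]

TARGET_ROLE_PAIRS: dict[str, tuple[str, str]] = {
    "anterior": ("subcallosal_gyrus", "anterior_cingulate"),
    "middle": ("anterior_cingulate", "middle_cingulate"),
    "posterior": ("middle_cingulate", "posterior_cingulate"),
}


class TargetGenerationError(RuntimeError):
    """A target region came out empty after dilation and intersection."""


@dataclass
class TargetRegions:
    """The three callosal target regions and their representative points."""

    anterior: np.ndarray
    middle: np.ndarray
    posterior: np.ndarray
    centroids: dict[str, np.ndarray]      # region centroid, world mm
    target_points: dict[str, np.ndarray]  # centroid snapped to an in-region voxel centre

    def mask(self, role: str) -> np.ndarray:
        return {"anterior": self.anterior, "middle": self.middle,
                "posterior": self.posterior}[role]

    def roles(self) -> tuple[str, str, str]:
        return ("anterior", "middle", "posterior")


@dataclass
class EntryRegions:
    """Cortical entry masks, keyed by entry-gyrus role."""

    masks: dict[str, np.ndarray]

    def mask(self, role: str) -> np.ndarray:
        if role not in self.masks:
            raise SchemaError(f"entry role {role!r} not available")
        return self.masks[role]


def dilate_mask(mask: np.ndarray, radius_mm: float,
                spacing: np.ndarray | tuple[float, float, float] = (1.0, 1.0, 1.0)
                ) -> np.ndarray:
    """Dilate a binary mask by a Euclidean radius in mm.

    A voxel is set iff its centre lies within ``radius_mm`` of a set input
    voxel centre; radius 0 is the identity.
    """
    if radius_mm < 0:
        raise ValueError("dilation radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm


def _mask_gap_mm(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Minimum centre-to-centre distance between two non-empty masks."""
    if not a.any() or not b.any():
        return float("inf")
    dist = ndimage.distance_transform_edt(~a, sampling=spacing)
    return float(dist[b].min())


def generate_targets(parcellation: LabelVolume,
                     schema: Mapping[str, int] | None = None,
                     radius_mm: float = 7.0) -> TargetRegions:
    """Generate the anterior/middle/posterior callosal target regions.

    Overlap voxels claimed by two regions are assigned to the more anterior
    one, keeping the three regions disjoint.  Raises
    :class:`TargetGenerationError` naming the first empty region and the
    achieved gap the dilations failed to bridge.
    """
    vol = _with_schema(parcellation, schema)
    spacing = vol.grid.spacing
    cc = vol.role_mask("corpus_callosum")
    dilated: dict[str, np.ndarray] = {}
    for role in ("subcallosal_gyrus", "anterior_cingulate",
                 "middle_cingulate", "posterior_cingulate"):
        dilated[role] = dilate_mask(vol.role_mask(role), radius_mm, spacing)

    raw: dict[str, np.ndarray] = {}
    for name, (role_a, role_b) in TARGET_ROLE_PAIRS.items():
        region = dilated[role_a] & dilated[role_b] & cc
        if not region.any():
            gap = _mask_gap_mm(vol.role_mask(role_a), vol.role_mask(role_b), spacing)
            raise TargetGenerationError(
                f"{name} target region is empty: {role_a}/{role_b} overlap "
                f"misses the corpus callosum (pair gap {gap:.1f} mm, "
                f"dilation radius {radius_mm:g} mm)"
            )
        raw[name] = region

    # disjointness: anterior beats middle beats posterior
    anterior = raw["anterior"]
    middle = raw["middle"] & ~anterior
    posterior = raw["posterior"] & ~anterior & ~middle
    for name, region in (("middle", middle), ("posterior", posterior)):
        if not region.any():
            raise TargetGenerationError(
                f"{name} target region is empty after disjointness assignment"
            )

    centroids, points = {}, {}
    for name, region in (("anterior", anterior), ("middle", middle),
                         ("posterior", posterior)):
        ijk = np.argwhere(region).astype(float)
        world = voxel_to_world(vol.grid, ijk)
        c = world.mean(axis=0)
        points[name] = world[np.argmin(np.linalg.norm(world - c, axis=1))]
        centroids[name] = c
    return TargetRegions(anterior, middle, posterior, centroids, points)


def extract_entry_regions(parcellation: LabelVolume,
                          schema: Mapping[str, int] | None = None) -> EntryRegions:
    """Return the five entry-gyrus label masks, unmodified."""
    from .phantom import ENTRY_ROLES

    vol = _with_schema(parcellation, schema)
    masks: dict[str, np.ndarray] = {}
    for role in ENTRY_ROLES:
        mask = vol.role_mask(role)
        if not mask.any():
            raise SchemaError(f"entry region {role!r} is empty")
        masks[role] = mask
    return EntryRegions(masks)


def _with_schema(vol: LabelVolume, schema: Mapping[str, int] | None) -> LabelVolume:
    if schema is None:
        return vol
    table = {int(lab): role for role, lab in schema.items()}
    present = set(np.unique(vol.labels).tolist())
    for lab, role in table.items():
        if lab not in present:
            raise SchemaError(f"schema role {role!r} maps to label {lab}, "
                              "absent from the volume")
    return LabelVolume(vol.grid, vol.labels, table)
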