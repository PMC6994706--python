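"""Constrained multi-trajectory search.

Five candidate trajectories are planned — one per row of the default
entry/target specification table (entry gyrus, callosal target, maximum
skull-to-target length, maximum drilling angle) — and the final three-
trajectory plan is selected from them: the frontal trajectory to the
anterior target, plus the better-ranked of the two middle-target rows and
of the two posterior-target rows.

The search is exhaustive over stride-subsampled entry-surface ×
target-voxel pairs.  Hard constraints: maximum length, maximum drilling
angle, no ventricular transgression, and no passage *through* a vessel
voxel.  Vessel proximity is otherwise soft, entering the weighted objective
through the risk score and the minimum vessel distance, so sub-3 mm
corridors remain admissible when nothing better exists — as they do in
clinical practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .riskmetrics import (
    DistanceMap,
    RiskModel,
    SurfaceNormalField,
    Trajectory,
    TrajectoryMetrics,
    compute_metrics,
    _dense_samples,
    _in_mask,
)
from .targetgen import EntryRegions, TargetRegions, extract_entry_regions, generate_targets
from .volio import LabelVolume, voxel_to_world
from .riskmetrics import vessel_distance_map

__all__ = [
    "TrajectorySpec",
    "ObjectiveWeights",
    "Candidate",
    "PlanSet",
    "PlanningContext",
    "table1_specs",
    "DEFAULT_SPECS",
    "enumerate_candidates",
    "rank_candidates",
    "plan_callosotomy",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """One row of the entry/target specification table."""

    entry_role: str
    target_role: str  # anterior | middle | posterior
    max_length_mm: float
    max_angle_deg: float

    def __post_init__(self):
        if self.max_length_mm <= 0:
            raise ValueError("max_length_mm must be positive")
        if not (0 < self.max_angle_deg < 90):
            raise ValueError("max_angle_deg must lie in (0, 90)")
        if self.target_role not in ("anterior", "middle", "posterior"):
            raise ValueError(f"unknown target role {self.target_role!r}")


def table1_specs(dominant: str = "left") -> tuple[TrajectorySpec, ...]:
    """The five default rows.  Entry laterality follows the dominance flag:
    with left dominance the anterior (non-dominant frontal) row enters on
    the right, the posterior (dominant frontal) rows on the left."""
    specs = (
        TrajectorySpec("right_superior_frontal", "anterior", 60.0, 15.0),
        TrajectorySpec("right_superior_parietal", "middle", 110.0, 35.0),
        TrajectorySpec("right_angular", "middle", 110.0, 35.0),
        TrajectorySpec("left_superior_frontal", "posterior", 90.0, 35.0),
        TrajectorySpec("left_middle_frontal", "posterior", 90.0, 35.0),
    )
    if dominant == "left":
        return specs
    swap = {"right": "left", "left": "right"}
    out = []
    for s in specs:
        side, rest = s.entry_role.split("_", 1)
        out.append(TrajectorySpec(f"{swap[side]}_{rest}", s.target_role,
                                  s.max_length_mm, s.max_angle_deg))
    return tuple(out)


DEFAULT_SPECS: tuple[TrajectorySpec, ...] = table1_specs("left")


@dataclass(frozen=True)
class ObjectiveWeights:
    """Non-negative weights on pool-normalised metrics.  Minimum vessel
    distance and callosal fraction are negated (bigger is better)."""

    risk: float = 0.3
    min_distance: float = 0.1
    length: float = 0.1
    angle: float = 0.05
    cc_fraction: float = 0.45

    def __post_init__(self):
        vals = (self.risk, self.min_distance, self.length, self.angle,
                self.cc_fraction)
        if any(v < 0 for v in vals):
            raise ValueError("objective weights must be >= 0")
        if all(v == 0 for v in vals):
            raise ValueError("at least one objective weight must be positive")


@dataclass
class Candidate:
    trajectory: Trajectory
    metrics: TrajectoryMetrics
    objective: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "entry_mm": [float(v) for v in self.trajectory.entry],
            "target_mm": [float(v) for v in self.trajectory.target],
            "length_mm": float(self.trajectory.length),
            "objective": float(self.objective),
            **self.metrics.as_dict(),
        }


@dataclass
class PlanningContext:
    """Everything the search needs besides the spec table: masks, the vessel
    distance map, the scalp-surface normal field and the search strides."""

    parcellation: LabelVolume
    head_mask: np.ndarray
    brain_vol: LabelVolume          # intracranial mask
    ventricle_mask: np.ndarray
    cc_vol: LabelVolume
    vessel_mask: np.ndarray
    dmap: DistanceMap
    normal_field: SurfaceNormalField
    risk_model: RiskModel = field(default_factory=RiskModel)
    entry_stride: int = 3
    target_stride: int = 4

    @classmethod
    def build(cls, parcellation: LabelVolume, vessel_vol: LabelVolume,
              risk_model: RiskModel | None = None,
              entry_stride: int = 3, target_stride: int = 4) -> "PlanningContext":
        labels = parcellation.labels
        head = labels > 0
        intracranial = head & ~parcellation.role_mask("scalp") \
                            & ~parcellation.role_mask("skull")
        grid = parcellation.grid
        head_vol = LabelVolume(grid, head.astype(np.uint8))
        return cls(
            parcellation=parcellation,
            head_mask=head,
            brain_vol=LabelVolume(grid, intracranial.astype(np.uint8)),
            ventricle_mask=parcellation.role_mask("ventricles"),
            cc_vol=LabelVolume(grid, parcellation.role_mask("corpus_callosum").astype(np.uint8)),
            vessel_mask=vessel_vol.as_mask(),
            dmap=vessel_distance_map(vessel_vol),
            normal_field=SurfaceNormalField(head_vol),
            risk_model=risk_model or RiskModel(),
            entry_stride=entry_stride,
            target_stride=target_stride,
        )


def _surface_entry_points(ctx: PlanningContext, entry_mask: np.ndarray) -> np.ndarray:
    """Project entry-gyrus voxels radially outward (from the head centroid)
    to the outer scalp surface; deduplicate per surface voxel."""
    grid = ctx.parcellation.grid
    ijk = np.argwhere(entry_mask).astype(float)
    pts = voxel_to_world(grid, ijk)
    centroid = voxel_to_world(grid, np.argwhere(ctx.head_mask).mean(axis=0))
    u = pts - centroid[None, :]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    steps = np.arange(0.0, 40.0, 0.5)
    probe = pts[:, None, :] + steps[None, :, None] * u[:, None, :]
    flat = probe.reshape(-1, 3)
    inside = _in_mask(ctx.head_mask, grid, flat).reshape(len(pts), len(steps))
    # outermost in-head probe per ray
    last = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    valid = inside.any(axis=1)
    surf = pts[valid] + steps[last[valid], None] * u[valid]
    # dedupe on the voxel lattice, deterministically
    from .volio import world_to_voxel

    vox = np.clip(np.rint(world_to_voxel(grid, surf)).astype(int),
                  0, np.array(grid.shape) - 1)
    key = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), grid.shape)
    order = np.lexsort((surf[:, 2], surf[:, 1], surf[:, 0]))
    seen, out = set(), []
    for i in order:
        k = int(key[i])
        if k not in seen:
            seen.add(k)
            out.append(surf[i])
    return np.asarray(out)[:: max(1, ctx.entry_stride)]


def _target_points(ctx: PlanningContext, targets: TargetRegions, role: str) -> np.ndarray:
    mask = targets.mask(role)
    pts = voxel_to_world(ctx.parcellation.grid, np.argwhere(mask).astype(float))
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order][:: max(1, ctx.target_stride)]
    return np.vstack([targets.target_points[role][None, :], pts])


def enumerate_candidates(spec: TrajectorySpec, entries: EntryRegions,
                         targets: TargetRegions, ctx: PlanningContext
                         ) -> tuple[list[Candidate], dict[str, int]]:
    """All feasible entry-surface × target-voxel trajectories for one spec,
    with per-constraint rejection counts.

    Constraints, applied in order: length ≤ max, drilling angle ≤ max, no
    ventricle transgression, no vessel-voxel transgression.
    """
    entry_pts = _surface_entry_points(ctx, entries.mask(spec.entry_role))
    target_pts = _target_points(ctx, targets, spec.target_role)
    rejections = {"length": 0, "angle": 0, "ventricle": 0, "vessel_collision": 0}
    if len(entry_pts) == 0 or len(target_pts) == 0:
        return [], rejections

    normals = ctx.normal_field.normal_at(entry_pts)
    E = np.repeat(entry_pts, len(target_pts), axis=0)
    N = np.repeat(normals, len(target_pts), axis=0)
    T = np.tile(target_pts, (len(entry_pts), 1))
    d = T - E
    lengths = np.linalg.norm(d, axis=1)
    ok = lengths > 0
    ok_len = ok & (lengths <= spec.max_length_mm)
    rejections["length"] = int(ok.sum() - ok_len.sum())
    cosang = np.abs(np.einsum("ij,ij->i", d / np.maximum(lengths, 1e-12)[:, None], N))
    angles = np.rad2deg(np.arccos(np.clip(cosang, -1, 1)))
    ok_ang = ok_len & (angles <= spec.max_angle_deg)
    rejections["angle"] = int(ok_len.sum() - ok_ang.sum())

    grid = ctx.parcellation.grid
    out: list[Candidate] = []
    for i in np.where(ok_ang)[0]:
        pts, _ = _dense_samples(E[i], T[i])
        if _in_mask(ctx.ventricle_mask, grid, pts).any():
            rejections["ventricle"] += 1
            continue
        if _in_mask(ctx.vessel_mask, grid, pts).any():
            rejections["vessel_collision"] += 1
            continue
        traj = Trajectory(E[i].copy(), T[i].copy())
        metrics = compute_metrics(
            traj, ctx.dmap, ctx.brain_vol,
            LabelVolume(grid, ctx.head_mask.astype(np.uint8)),
            ctx.cc_vol, ctx.risk_model, normal_field=ctx.normal_field)
        out.append(Candidate(traj, metrics))
    return out, rejections


def _objective_values(cands: Sequence[Candidate], weights: ObjectiveWeights
                      ) -> np.ndarray:
    def norm(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        return np.zeros_like(v) if hi - lo < 1e-12 else (v - lo) / (hi - lo)

    risk = norm(np.array([c.metrics.risk_score for c in cands]))
    mind = norm(np.array([c.metrics.min_vessel_distance_mm for c in cands]))
    icl = norm(np.array([c.metrics.intracerebral_length_mm for c in cands]))
    ang = norm(np.array([c.metrics.drilling_angle_deg for c in cands]))
    ccf = norm(np.array([c.metrics.cc_fraction for c in cands]))
    return (weights.risk * risk + weights.min_distance * (1 - mind)
            + weights.length * icl + weights.angle * ang
            + weights.cc_fraction * (1 - ccf))


def rank_candidates(cands: Sequence[Candidate], weights: ObjectiveWeights | None = None
                    ) -> list[Candidate]:
    """Stable sort by ascending weighted normalised objective; ties broken by
    (risk score, intracerebral length, entry coordinates)."""
    if len(cands) == 0:
        return []
    weights = weights or ObjectiveWeights()
    obj = _objective_values(cands, weights)
    for c, o in zip(cands, obj):
        c.objective = float(o)
    keys = [
        (float(o), c.metrics.risk_score, c.metrics.intracerebral_length_mm,
         tuple(c.trajectory.entry), tuple(c.trajectory.target))
        for c, o in zip(cands, obj)
    ]
    order = sorted(range(len(cands)), key=lambda i: keys[i])
    return [cands[i] for i in order]


@dataclass
class PlanSet:
    """Ranked candidates per spec row and the selected three-trajectory plan."""

    specs: tuple[TrajectorySpec, ...]
    ranked: list[list[Candidate]]
    rejections: list[dict[str, int]]
    selected: dict[str, Candidate]           # target role -> candidate
    selected_spec_index: dict[str, int]
    infeasible_specs: list[int]
    targets: TargetRegions

    @property
    def best_per_spec(self) -> list[Candidate | None]:
        return [r[0] if r else None for r in self.ranked]

    @property
    def fully_feasible(self) -> bool:
        return not self.infeasible_specs

    def n_candidates(self) -> int:
        """Best candidates returned to the user (one per feasible spec)."""
        return sum(1 for c in self.best_per_spec if c is not None)


def _pick_better(cands_a: list[Candidate], cands_b: list[Candidate],
                 weights: ObjectiveWeights) -> int:
    """0 if the best of pool A beats the best of pool B under a joint
    normalisation of both pools, else 1."""
    if not cands_a:
        return 1
    if not cands_b:
        return 0
    pool = list(cands_a) + list(cands_b)
    obj = _objective_values(pool, weights)
    best_a = min(range(len(cands_a)), key=lambda i: obj[i])
    best_b = min(range(len(cands_b)), key=lambda i: obj[len(cands_a) + i])
    return 0 if obj[best_a] <= obj[len(cands_a) + best_b] else 1


def plan_callosotomy(parcellation: LabelVolume,
                     schema: Mapping[str, int] | None,
                     vessel_vol: LabelVolume,
                     specs: Sequence[TrajectorySpec] | None = None,
                     weights: ObjectiveWeights | None = None,
                     risk_model: RiskModel | None = None,
                     radius_mm: float = 7.0,
                     entry_stride: int = 3,
                     target_stride: int = 4) -> PlanSet:
    """Run target generation, candidate enumeration and ranking for every
    spec row, then select the final triple: the anterior trajectory plus the
    better-ranked of the two middle rows and of the two posterior rows.

    Specs with zero feasible candidates are flagged, not fatal: the plan is
    marked partially infeasible and the remaining targets are still planned.
    """
    specs = tuple(specs) if specs is not None else DEFAULT_SPECS
    weights = weights or ObjectiveWeights()
    if schema is not None:
        from .targetgen import _with_schema
        parcellation = _with_schema(parcellation, schema)
    targets = generate_targets(parcellation, None, radius_mm=radius_mm)
    entries = extract_entry_regions(parcellation, None)
    ctx = PlanningContext.build(parcellation, vessel_vol, risk_model,
                                entry_stride, target_stride)

    ranked: list[list[Candidate]] = []
    rejections: list[dict[str, int]] = []
    for spec in specs:
        cands, rej = enumerate_candidates(spec, entries, targets, ctx)
        ranked.append(rank_candidates(cands, weights))
        rejections.append(rej)

    by_role: dict[str, list[int]] = {"anterior": [], "middle": [], "posterior": []}
    for i, spec in enumerate(specs):
        by_role[spec.target_role].append(i)

    selected: dict[str, Candidate] = {}
    selected_idx: dict[str, int] = {}
    for role, idxs in by_role.items():
        pools = [ranked[i] for i in idxs]
        if len(idxs) == 1:
            if pools[0]:
                selected[role] = pools[0][0]
                selected_idx[role] = idxs[0]
        elif len(idxs) >= 2:
            nonempty = [k for k in range(len(idxs)) if pools[k]]
            if len(nonempty) == 1:
                k = nonempty[0]
                selected[role] = pools[k][0]
                selected_idx[role] = idxs[k]
            elif len(nonempty) >= 2:
                k = _pick_better(pools[nonempty[0]], pools[nonempty[1]], weights)
                k = nonempty[k]
                selected[role] = pools[k][0]
                selected_idx[role] = idxs[k]

    infeasible = [i for i, r in enumerate(ranked) if not r]
    return PlanSet(specs, ranked, rejections, selected, selected_idx,
                   infeasible, targets)
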