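"""Per-trajectory safety metrics.

A candidate trajectory is summarised by five quantities a stereotactic
surgeon weighs during planning: intracerebral length, drilling angle from
the skull-surface orthogonal, the proportion of the catheter within the
corpus callosum, the minimum distance to vasculature, and a normalised
vascular risk score sampled at ``n_nodes`` (default 128) equally spaced
nodes along the trajectory.

Risk score
----------
The per-node risk is piecewise linear in the node's distance ``d`` to the
nearest vessel, with a safe margin ``d_safe`` (3 mm) and an outer horizon
``d_risk`` (10 mm)::

    r = 0                              d >= d_risk
    r = (d_risk - d) / (d_risk - d_safe)   d_safe <= d < d_risk   (0 < r <= 1)
    r = 1 + (d_safe - d) / d_safe          d < d_safe             (1 < r <= 2)

and the trajectory score is the maximum (default) or mean over nodes.
Under max-aggregation the calibration holds exactly in both directions:
score < 1  ⟺  every node is more than 3 mm from vasculature.  This
piecewise-linear family is this package's own formulation, chosen as the
simplest one making that calibration statement true; distances at nodes are
trilinearly interpolated from an exact Euclidean distance transform of the
vessel mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import LabelVolume, VoxelGrid, world_to_voxel

__all__ = [
    "Trajectory",
    "RiskModel",
    "TrajectoryMetrics",
    "DistanceMap",
    "vessel_distance_map",
    "sample_nodes",
    "risk_score",
    "min_vessel_distance",
    "intracerebral_length",
    "drilling_angle",
    "cc_fraction",
    "SurfaceNormalField",
    "compute_metrics",
]

DENSE_STEP_MM = 0.5  # sampling step for mask-traversal measurements


@dataclass(frozen=True)
class Trajectory:
    """A straight catheter path from a skull-surface entry to a target,
    both in world mm."""

    entry: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float))
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        if self.entry.shape != (3,) or self.target.shape != (3,):
            raise ValueError("entry and target must be 3-vectors")
        if not (np.isfinite(self.entry).all() and np.isfinite(self.target).all()):
            raise ValueError("trajectory endpoints must be finite")
        if self.length <= 0:
            raise ValueError("trajectory length must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target - self.entry))

    @property
    def direction(self) -> np.ndarray:
        return (self.target - self.entry) / self.length


@dataclass(frozen=True)
class RiskModel:
    d_safe: float = 3.0
    d_risk: float = 10.0
    n_nodes: int = 128
    aggregation: str = "max"

    def __post_init__(self):
        if not (0 < self.d_safe < self.d_risk):
            raise ValueError("require 0 < d_safe < d_risk")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.aggregation not in ("max", "mean"):
            raise ValueError("aggregation must be 'max' or 'mean'")


@dataclass
class TrajectoryMetrics:
    intracerebral_length_mm: float
    drilling_angle_deg: float
    risk_score: float
    min_vessel_distance_mm: float
    cc_fraction: float

    def __post_init__(self):
        vals = (self.intracerebral_length_mm, self.drilling_angle_deg,
                self.risk_score, self.min_vessel_distance_mm, self.cc_fraction)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("metrics must be finite")
        if not (0.0 <= self.cc_fraction <= 1.0):
            raise ValueError("cc_fraction must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "intracerebral_length_mm": float(self.intracerebral_length_mm),
            "drilling_angle_deg": float(self.drilling_angle_deg),
            "risk_score": float(self.risk_score),
            "min_vessel_distance_mm": float(self.min_vessel_distance_mm),
            "cc_fraction": float(self.cc_fraction),
        }


@dataclass
class DistanceMap:
    """Per-voxel Euclidean distance (mm) to the nearest vessel voxel."""

    grid: VoxelGrid
    values: np.ndarray

    def sample(self, points_world: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated distance at world points; raises if any
        point falls outside the grid."""
        pts = np.atleast_2d(points_world)
        ijk = world_to_voxel(self.grid, pts)
        if not self.grid.contains_voxel(ijk).all():
            raise ValueError("point outside the distance-map grid")
        return ndimage.map_coordinates(self.values, ijk.T, order=1, mode="nearest")


def vessel_distance_map(vessel_mask: LabelVolume) -> DistanceMap:
    """Exact Euclidean distance transform of the vessel mask, in mm."""
    mask = vessel_mask.as_mask()
    if not mask.any():
        raise ValueError("vessel mask is empty: vascular risk is undefined")
    dist = ndimage.distance_transform_edt(~mask, sampling=vessel_mask.grid.spacing)
    return DistanceMap(vessel_mask.grid, dist)


def sample_nodes(traj: Trajectory, n_nodes: int = 128) -> np.ndarray:
    """``n_nodes`` points uniformly spaced from entry to target, inclusive."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    s = np.linspace(0.0, 1.0, n_nodes)[:, None]
    return traj.entry[None, :] * (1 - s) + traj.target[None, :] * s


def node_risks(distances: np.ndarray, model: RiskModel) -> np.ndarray:
    """Piecewise-linear per-node risk (see module docstring)."""
    d = np.asarray(distances, dtype=float)
    r = np.zeros_like(d)
    mid = (d >= model.d_safe) & (d < model.d_risk)
    r[mid] = (model.d_risk - d[mid]) / (model.d_risk - model.d_safe)
    close = d < model.d_safe
    r[close] = 1.0 + (model.d_safe - d[close]) / model.d_safe
    return r


def risk_score(traj: Trajectory, dmap: DistanceMap,
               model: RiskModel | None = None) -> float:
    model = model or RiskModel()
    d = dmap.sample(sample_nodes(traj, model.n_nodes))
    r = node_risks(d, model)
    return float(r.max() if model.aggregation == "max" else r.mean())


def min_vessel_distance(traj: Trajectory, dmap: DistanceMap,
                        n_nodes: int = 128) -> float:
    """Minimum over the sampled nodes of the interpolated vessel distance."""
    return float(dmap.sample(sample_nodes(traj, n_nodes)).min())


def _dense_samples(p0: np.ndarray, p1: np.ndarray, step: float = DENSE_STEP_MM
                   ) -> tuple[np.ndarray, float]:
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / step)) + 1, 2)
    s = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - s) + p1[None, :] * s, length / (n - 1)


def _in_mask(mask: np.ndarray, grid: VoxelGrid, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel mask lookup; points off the grid count as outside."""
    ijk = np.rint(world_to_voxel(grid, points)).astype(int)
    ok = grid.contains_voxel(ijk)
    out = np.zeros(len(points), dtype=bool)
    if ok.any():
        sub = ijk[ok]
        out[ok] = mask[sub[:, 0], sub[:, 1], sub[:, 2]]
    return out


def intracerebral_length(traj: Trajectory, brain_mask: LabelVolume) -> float:
    """Length from the first brain-mask entry to the target, by dense
    sampling at ≤0.5 mm steps.  The target must lie inside the brain."""
    mask = brain_mask.as_mask()
    pts, ds = _dense_samples(traj.entry, traj.target)
    inside = _in_mask(mask, brain_mask.grid, pts)
    if not inside[-1]:
        raise ValueError("trajectory target lies outside the brain mask")
    first = int(np.argmax(inside))
    return float((len(pts) - 1 - first) * ds)


class SurfaceNormalField:
    """Outward surface normals of a voxelised solid, from the gradient of a
    Gaussian-smoothed signed distance field (positive outside)."""

    def __init__(self, mask_vol: LabelVolume, sigma_mm: float = 2.0):
        mask = mask_vol.as_mask()
        grid = mask_vol.grid
        sp = grid.spacing
        sdf = (ndimage.distance_transform_edt(~mask, sampling=sp)
               - ndimage.distance_transform_edt(mask, sampling=sp))
        sdf = ndimage.gaussian_filter(sdf, sigma=sigma_mm / sp)
        self.grid = grid
        self.sdf = sdf
        self._grads = np.gradient(sdf, *sp)
        self._surface_tol = 2.0 * float(sp.max())

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        ijk = world_to_voxel(self.grid, np.atleast_2d(points))
        return ndimage.map_coordinates(self.sdf, ijk.T, order=1, mode="nearest")

    def normal_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        ijk = world_to_voxel(self.grid, pts)
        g = np.stack(
            [ndimage.map_coordinates(gc, ijk.T, order=1, mode="nearest")
             for gc in self._grads], axis=-1)
        norm = np.linalg.norm(g, axis=-1, keepdims=True)
        norm[norm == 0] = 1.0
        return g / norm


def drilling_angle(traj: Trajectory, skull_mask: LabelVolume,
                   field: SurfaceNormalField | None = None) -> float:
    """Unsigned angle (degrees) between the trajectory and the outward
    surface normal at the entry; 0° is orthogonal drilling.  The entry must
    lie within 2 voxels of the mask surface."""
    field = field or SurfaceNormalField(skull_mask)
    sd = float(field.signed_distance(traj.entry)[0])
    if abs(sd) > field._surface_tol + 1e-9:
        raise ValueError(
            f"entry point is {abs(sd):.1f} mm from the skull surface "
            f"(limit {field._surface_tol:.1f} mm)")
    n = field.normal_at(traj.entry)[0]
    cosang = abs(float(np.dot(traj.direction, n)))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def cc_fraction(traj: Trajectory, cc_mask: LabelVolume,
                catheter_extent_mm: float) -> float:
    """Fraction of the distal ``catheter_extent_mm`` of the catheter lying
    inside the corpus callosum (≤0.5 mm samples, measured back from the
    target along the trajectory)."""
    if catheter_extent_mm <= 0:
        raise ValueError("catheter extent must be positive")
    extent = min(catheter_extent_mm, traj.length)
    start = traj.target - traj.direction * extent
    pts, _ = _dense_samples(start, traj.target)
    inside = _in_mask(cc_mask.as_mask(), cc_mask.grid, pts)
    return float(inside.mean())


def compute_metrics(traj: Trajectory, dmap: DistanceMap,
                    brain_mask: LabelVolume, skull_mask: LabelVolume,
                    cc_mask: LabelVolume,
                    model: RiskModel | None = None,
                    catheter_extent_mm: float | None = None,
                    normal_field: SurfaceNormalField | None = None
                    ) -> TrajectoryMetrics:
    """Bundle all five safety metrics for one trajectory.

    ``catheter_extent_mm`` defaults to the full intracerebral segment.
    """
    model = model or RiskModel()
    icl = intracerebral_length(traj, brain_mask)
    extent = catheter_extent_mm if catheter_extent_mm is not None else max(icl, 1e-6)
    return TrajectoryMetrics(
        intracerebral_length_mm=icl,
        drilling_angle_deg=drilling_angle(traj, skull_mask, normal_field),
        risk_score=risk_score(traj, dmap, model),
        min_vessel_distance_mm=min_vessel_distance(traj, dmap, model.n_nodes),
        cc_fraction=cc_fraction(traj, cc_mask, extent),
    )
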