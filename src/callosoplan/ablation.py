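"""Simulated laser ablation cavities.

For each catheter, the ablated volume is built from the number of expected
pull-backs: the length of the catheter within the corpus callosum divided
by the pull-back spacing (7 mm, rounded up, minimum one ablation).
Ablation centres are anchored at the distal (target) end of the callosal
segment and stepped proximally; each ablation is a sphere of the configured
diameter (5–15 mm, conservative default 15 mm) and the union of spheres at
confluent spacing converges to a capped cylinder around the catheter.  By
default the cavity is clipped to the corpus callosum dilated by a 2 mm
thermal margin, modelling a surgeon limiting the ablation to the callosum.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, pi

import numpy as np
from scipy import ndimage

from .riskmetrics import Trajectory, _dense_samples, _in_mask
from .targetgen import dilate_mask
from .volio import LabelVolume, world_to_voxel

__all__ = [
    "AblationParams",
    "AblationCavity",
    "cc_segment",
    "n_pullbacks",
    "simulate_cavity",
    "combined_cavity",
    "analytic_capsule_volume_mm3",
]


@dataclass(frozen=True)
class AblationParams:
    diameter_mm: float = 15.0
    pullback_spacing_mm: float = 7.0
    clip_to_cc: bool = True
    clip_margin_mm: float = 2.0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("ablation diameter must be positive")
        if not (0 < self.pullback_spacing_mm <= self.diameter_mm):
            raise ValueError(
                "pull-back spacing must lie in (0, diameter]: larger spacing "
                "cannot produce a confluent cavity")


@dataclass
class AblationCavity:
    mask: np.ndarray
    centres: np.ndarray       # ablation centres, world mm, distal first
    pullbacks: int
    segment_length_mm: float

    def volume_mm3(self, voxel_volume: float) -> float:
        return float(self.mask.sum()) * voxel_volume


def cc_segment(traj: Trajectory, cc_vol: LabelVolume
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """(proximal point, distal point, length mm) of the longest contiguous
    in-callosum interval of the trajectory, by ≤0.5 mm sampling."""
    pts, ds = _dense_samples(traj.entry, traj.target)
    inside = _in_mask(cc_vol.as_mask(), cc_vol.grid, pts)
    if not inside.any():
        raise ValueError("trajectory does not intersect the corpus callosum")
    # longest run of consecutive True
    padded = np.concatenate([[False], inside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1
    k = int(np.argmax(ends - starts))
    i0, i1 = int(starts[k]), int(ends[k])
    return pts[i0], pts[i1], float((i1 - i0) * ds)


def n_pullbacks(segment_length_mm: float, spacing_mm: float = 7.0) -> int:
    """ceil(segment length / spacing), minimum 1 (a zero-length segment
    still receives a single ablation at the target)."""
    if segment_length_mm < 0:
        raise ValueError("segment length must be >= 0")
    return max(1, ceil(segment_length_mm / spacing_mm))


def _rasterise_spheres(centres: np.ndarray, radius: float, vol: LabelVolume
                       ) -> np.ndarray:
    grid = vol.grid
    mask = np.zeros(grid.shape, dtype=bool)
    inv_vox = world_to_voxel(grid, centres)
    pad = radius / grid.spacing + 1
    lo = np.clip(np.floor(inv_vox.min(axis=0) - pad).astype(int), 0, None)
    hi = np.minimum(np.ceil(inv_vox.max(axis=0) + pad).astype(int) + 1,
                    np.array(grid.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    idx = np.indices([s.stop - s.start for s in sl], dtype=float)
    ijk = np.stack([idx[0] + lo[0], idx[1] + lo[1], idx[2] + lo[2]], axis=-1)
    world = ijk.reshape(-1, 3) @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    close = np.zeros(len(world), dtype=bool)
    for c in centres:
        close |= np.linalg.norm(world - c[None, :], axis=1) <= radius
    mask[sl] = close.reshape(idx.shape[1:])
    return mask


def simulate_cavity(traj: Trajectory, cc_vol: LabelVolume,
                    params: AblationParams | None = None) -> AblationCavity:
    """Confluent pull-back cavity for one catheter (see module docstring)."""
    params = params or AblationParams()
    proximal, distal, length = cc_segment(traj, cc_vol)
    n = n_pullbacks(length, params.pullback_spacing_mm)
    u = traj.direction  # distal end points along the catheter direction
    centres = np.array([distal - k * params.pullback_spacing_mm * u
                        for k in range(n)])
    mask = _rasterise_spheres(centres, params.diameter_mm / 2, cc_vol)
    if params.clip_to_cc:
        clip = dilate_mask(cc_vol.as_mask(), params.clip_margin_mm,
                           cc_vol.grid.spacing)
        mask &= clip
    return AblationCavity(mask, centres, n, length)


def combined_cavity(cavities: list[AblationCavity], grid_shape=None
                    ) -> np.ndarray:
    """Voxelwise union of per-trajectory cavities."""
    if not cavities:
        raise ValueError("no cavities to combine")
    out = np.zeros_like(cavities[0].mask)
    for cav in cavities:
        out |= cav.mask
    return out


def cavity_components(mask: np.ndarray) -> int:
    """Number of 26-connected components (1 = confluent)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    _, n = ndimage.label(mask, structure=structure)
    return int(n)


def analytic_capsule_volume_mm3(span_mm: float, diameter_mm: float) -> float:
    """Volume of a sphere swept along a straight span (capsule):
    sphere + cylinder."""
    r = diameter_mm / 2
    return 4 / 3 * pi * r**3 + pi * r**2 * span_mm
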