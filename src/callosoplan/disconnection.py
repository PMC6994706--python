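"""Tractography-based disconnection assessment.

Simulated ablation cavities act as exclusion zones on a set of
interhemispheric streamlines: a streamline is removed when any point of its
densely resampled polyline falls inside the exclusion mask.  Residual
interhemispheric connectivity is the set of corpus-callosum voxels still
traversed by surviving streamlines, reported as a volume in cm³ and
localised along the anterior–posterior extent of the callosum.  The
callosum itself is partitioned by a coronal plane at a configurable
fraction (default 2/3) of its AP extent into the anterior two-thirds and
the spared splenium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import _resample_polyline
from .riskmetrics import _in_mask
from .volio import LabelVolume, StreamlineSet, VoxelGrid, voxel_to_world, world_to_voxel

__all__ = [
    "DisconnectionReport",
    "split_anterior_two_thirds",
    "filter_streamlines",
    "residual_connectivity",
    "assess_plan",
]


@dataclass
class DisconnectionReport:
    input_count: int
    surviving_count: int
    residual_mask: np.ndarray
    residual_volume_cm3: float
    residual_anterior_volume_cm3: float
    residual_in_anterior_two_thirds: bool
    cc_volume_cm3: float
    anterior_volume_cm3: float
    splenium_volume_cm3: float
    residual_anterior_ap_fraction: float | None = None  # 0 = anterior-most
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "input_count": int(self.input_count),
            "surviving_count": int(self.surviving_count),
            "residual_volume_cm3": float(self.residual_volume_cm3),
            "residual_anterior_volume_cm3": float(self.residual_anterior_volume_cm3),
            "residual_in_anterior_two_thirds": bool(self.residual_in_anterior_two_thirds),
            "cc_volume_cm3": float(self.cc_volume_cm3),
            "anterior_volume_cm3": float(self.anterior_volume_cm3),
            "splenium_volume_cm3": float(self.splenium_volume_cm3),
            "residual_anterior_ap_fraction": (
                None if self.residual_anterior_ap_fraction is None
                else float(self.residual_anterior_ap_fraction)),
            **self.extra,
        }


def _ap_axis(grid: VoxelGrid) -> tuple[int, float]:
    """Voxel axis most aligned with world +y (anterior), and its sign."""
    lin = grid.affine[:3, :3]
    axis = int(np.argmax(np.abs(lin[1, :])))
    return axis, float(np.sign(lin[1, axis]))


def split_anterior_two_thirds(cc_vol: LabelVolume, fraction: float = 2 / 3
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Partition the callosum by a coronal plane at ``fraction`` of its AP
    voxel extent; the anterior part contains the anterior-most voxel and the
    two masks partition the callosum exactly."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    mask = cc_vol.as_mask()
    if not mask.any():
        raise ValueError("corpus callosum mask is empty")
    axis, sign = _ap_axis(cc_vol.grid)
    idx = np.argwhere(mask)[:, axis]
    lo, hi = int(idx.min()), int(idx.max())
    n = hi - lo + 1
    n_ant = max(1, int(round(fraction * n)))
    coord = np.arange(cc_vol.grid.shape[axis])
    if sign >= 0:
        anterior_planes = coord > hi - n_ant
    else:
        anterior_planes = coord < lo + n_ant
    plane_mask = np.zeros(cc_vol.grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = anterior_planes
    plane_mask[tuple(sl)] = True
    anterior = mask & plane_mask
    splenium = mask & ~plane_mask
    return anterior, splenium


def filter_streamlines(sset: StreamlineSet, exclusion_vol: LabelVolume,
                       step_mm: float = 0.5
                       ) -> tuple[StreamlineSet, StreamlineSet]:
    """(survivors, removed): a streamline is removed iff any point of its
    ≤step resampled polyline falls inside the exclusion mask.  Survivors
    are preserved verbatim."""
    mask = exclusion_vol.as_mask()
    grid = exclusion_vol.grid
    survivors, removed = [], []
    for line in sset:
        pts = _resample_polyline(line, step_mm)
        if _in_mask(mask, grid, pts).any():
            removed.append(line)
        else:
            survivors.append(line)
    return (StreamlineSet(survivors, provenance=sset.provenance or "survivors"),
            StreamlineSet(removed, provenance="removed"))


def _visited_mask(lines, mask: np.ndarray, grid: VoxelGrid,
                  step_mm: float = 0.5) -> np.ndarray:
    """Mask voxels traversed by any of the resampled polylines."""
    visited = np.zeros(grid.shape, dtype=bool)
    shape = np.array(grid.shape)
    for line in lines:
        pts = _resample_polyline(line, step_mm)
        ijk = np.rint(world_to_voxel(grid, pts)).astype(int)
        ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
        ijk = ijk[ok]
        visited[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    return visited & mask


def residual_connectivity(survivors, cc_vol: LabelVolume,
                          anterior_mask: np.ndarray,
                          step_mm: float = 0.5,
                          input_count: int | None = None) -> DisconnectionReport:
    """Quantify the callosal voxels still traversed by surviving streamlines.

    Volumes are voxel counts × voxel volume, in cm³; the anterior/splenium
    masks must partition the callosum.
    """
    cc_mask = cc_vol.as_mask()
    grid = cc_vol.grid
    vox_cm3 = grid.voxel_volume_mm3 / 1000.0
    lines = list(survivors) if survivors is not None else []
    residual = _visited_mask(lines, cc_mask, grid, step_mm)
    splenium_mask = cc_mask & ~anterior_mask
    res_ant = residual & anterior_mask
    ap_fraction = None
    if res_ant.any():
        axis, sign = _ap_axis(grid)
        cc_idx = np.argwhere(cc_mask)[:, axis]
        lo, hi = cc_idx.min(), cc_idx.max()
        res_idx = np.argwhere(res_ant)[:, axis].astype(float)
        # 0 at the anterior-most callosal plane, 1 at the posterior-most
        if sign >= 0:
            ap_fraction = float(np.mean((hi - res_idx) / max(hi - lo, 1)))
        else:
            ap_fraction = float(np.mean((res_idx - lo) / max(hi - lo, 1)))
    return DisconnectionReport(
        input_count=int(input_count) if input_count is not None else len(lines),
        surviving_count=len(lines),
        residual_mask=residual,
        residual_volume_cm3=residual.sum() * vox_cm3,
        residual_anterior_volume_cm3=res_ant.sum() * vox_cm3,
        residual_in_anterior_two_thirds=bool(res_ant.any()),
        cc_volume_cm3=cc_mask.sum() * vox_cm3,
        anterior_volume_cm3=(cc_mask & anterior_mask).sum() * vox_cm3,
        splenium_volume_cm3=splenium_mask.sum() * vox_cm3,
        residual_anterior_ap_fraction=ap_fraction,
    )


def assess_plan(exclusion_mask: np.ndarray, streamlines: StreamlineSet,
                cc_vol: LabelVolume, fraction: float = 2 / 3,
                step_mm: float = 0.5) -> DisconnectionReport:
    """End-to-end assessment: filter the tractogram through the combined
    cavity mask, then quantify and localise residual callosal connectivity."""
    grid = cc_vol.grid
    excl_vol = LabelVolume(grid, np.asarray(exclusion_mask).astype(np.uint8))
    anterior, _ = split_anterior_two_thirds(cc_vol, fraction)
    survivors, removed = filter_streamlines(streamlines, excl_vol, step_mm)
    report = residual_connectivity(survivors, cc_vol, anterior, step_mm,
                                   input_count=len(streamlines))
    report.extra["removed_count"] = len(removed)
    return report
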