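"""Volume, streamline and plan-report I/O, plus the coordinate conventions
used throughout the package.

All geometry in this package is expressed in world millimetres in a
right-handed RAS-like frame (x: left→right, y: posterior→anterior,
z: inferior→superior).  Voxel indices are 0-based, a voxel index addresses
the voxel *centre*, and rasterisation/lookup happens only at declared
boundaries.  The voxel→world mapping is carried by a 4×4 affine, as in
NIfTI-1 headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "StreamlineSet",
    "PlanDocument",
    "SchemaError",
    "read_label_volume",
    "write_label_volume",
    "read_streamlines",
    "write_streamlines",
    "world_to_voxel",
    "voxel_to_world",
]


class SchemaError(KeyError):
    """A label-schema role could not be resolved against a volume."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice with a voxel-index→world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", aff)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centres_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``shape + (3,)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2]], axis=-1)
        return voxel_to_world(self, pts.reshape(-1, 3)).reshape(*self.shape, 3)

    def contains_voxel(self, ijk: np.ndarray) -> np.ndarray:
        """True where a continuous voxel index lies on the lattice
        (half-open convention: within [-0.5, n-0.5) on each axis)."""
        ijk = np.atleast_2d(ijk)
        lo = ijk >= -0.5
        hi = ijk < np.asarray(self.shape) - 0.5
        return (lo & hi).all(axis=-1)


def voxel_to_world(grid: VoxelGrid, ijk: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices to world mm through the affine."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def world_to_voxel(grid: VoxelGrid, xyz: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous voxel indices (inverse affine)."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(grid.affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class LabelVolume:
    """An integer-labelled volume plus a label-id→role-name table.

    Label 0 is reserved for background.  Binary masks are represented as
    LabelVolumes with labels in {0, 1} and an empty table.
    """

    grid: VoxelGrid
    labels: np.ndarray
    table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")
        if not np.issubdtype(self.labels.dtype, np.integer) and self.labels.dtype != bool:
            raise ValueError("labels must be integer-typed")
        if 0 in self.table:
            raise SchemaError("label 0 is reserved for background")

    def label_for(self, role: str) -> int:
        for label, name in self.table.items():
            if name == role:
                return label
        raise SchemaError(f"role {role!r} is not present in the label table")

    def role_mask(self, role: str) -> np.ndarray:
        """Boolean mask for one semantic role; fails loudly on unknown roles."""
        return self.labels == self.label_for(role)

    def combined_mask(self, roles: Iterable[str]) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for role in roles:
            out |= self.role_mask(role)
        return out

    def as_mask(self) -> np.ndarray:
        return self.labels > 0


def _table_from_schema(schema: Mapping[str, int]) -> dict[int, str]:
    table: dict[int, str] = {}
    for role, label in schema.items():
        label = int(label)
        if label == 0:
            raise SchemaError(f"role {role!r} maps to reserved background label 0")
        if label in table:
            raise SchemaError(
                f"label {label} claimed by both {table[label]!r} and {role!r}"
            )
        table[label] = role
    return table


def read_label_volume(path: str | Path, schema: Mapping[str, int] | None = None) -> LabelVolume:
    """Read an integer NIfTI volume and validate a role→label schema against it.

    Raises :class:`SchemaError` naming the first role whose label id is
    absent from the volume.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3-D volume (ndim={data.ndim})")
    if np.issubdtype(data.dtype, np.floating):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path} contains non-integer label data")
        data = rounded.astype(np.int32)
    grid = VoxelGrid(data.shape, img.affine)
    table: dict[int, str] = {}
    if schema is not None:
        table = _table_from_schema(schema)
        present = set(np.unique(data).tolist())
        for label, role in table.items():
            if label not in present:
                raise SchemaError(
                    f"schema role {role!r} maps to label {label}, absent from {path}"
                )
    return LabelVolume(grid, data.astype(np.int32), table)


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a LabelVolume as NIfTI-1; header affine equals the grid affine."""
    path = Path(path)
    data = vol.labels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_sform(vol.grid.affine, code=1)
    img.header.set_qform(vol.grid.affine, code=1)
    nib.save(img, str(path))
    return path


@dataclass
class StreamlineSet:
    """Polylines in world mm; each has ≥2 points, finite, no repeated
    consecutive points."""

    streamlines: list[np.ndarray]
    provenance: str = ""

    def __post_init__(self):
        cleaned = []
        for i, line in enumerate(self.streamlines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i} is not an (N>=2, 3) polyline")
            if not np.isfinite(arr).all():
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            if np.any(np.all(np.diff(arr, axis=0) == 0, axis=1)):
                raise ValueError(f"streamline {i} has repeated consecutive points")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def write_streamlines(sset: StreamlineSet, path: str | Path) -> Path:
    """Write streamlines as TCK (``.tck``) or the documented plain-text
    fallback (any other suffix): one ``x y z`` row per point, streamlines
    separated by blank lines."""
    path = Path(path)
    if path.suffix.lower() == ".tck":
        tractogram = nib.streamlines.Tractogram(
            sset.streamlines, affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(tractogram, str(path))
    else:
        with open(path, "w") as fh:
            fh.write(f"# callosoplan streamlines: {len(sset)}\n")
            for line in sset.streamlines:
                for p in line:
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
                fh.write("\n")
    return path


def read_streamlines(path: str | Path) -> StreamlineSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".tck":
        tck = nib.streamlines.load(str(path))
        lines = [np.asarray(s, dtype=float) for s in tck.streamlines]
        return StreamlineSet(lines, provenance=f"tck:{path.name}")
    lines: list[np.ndarray] = []
    current: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            row = raw.strip()
            if row.startswith("#"):
                continue
            if not row:
                if current:
                    lines.append(np.asarray(current))
                    current = []
                continue
            vals = row.split()
            if len(vals) != 3:
                raise ValueError(f"malformed streamline row in {path}: {row!r}")
            current.append([float(v) for v in vals])
    if current:
        lines.append(np.asarray(current))
    return StreamlineSet(lines, provenance=f"text:{path.name}")


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class PlanDocument:
    """Single-file structured report for one planning run: config echo,
    per-trajectory metrics and the disconnection summary.  Round-trips
    losslessly through YAML."""

    config: dict = field(default_factory=dict)
    trajectories: list[dict] = field(default_factory=list)
    ablation: dict = field(default_factory=dict)
    disconnection: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _plain(
            {
                "config": self.config,
                "trajectories": self.trajectories,
                "ablation": self.ablation,
                "disconnection": self.disconnection,
            }
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "PlanDocument":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            config=data.get("config", {}),
            trajectories=data.get("trajectories", []),
            ablation=data.get("ablation", {}),
            disconnection=data.get("disconnection", {}),
        )
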