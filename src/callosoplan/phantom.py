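"""Parametric digital head phantom.

Generates every input the planning pipeline needs: a labelled parcellation
with an arched corpus callosum, cingulate band subregions, the five entry
gyri, scalp/skull shells and ventricles; a vessel tree (paired pericallosal
arteries on the dorsal callosal surface, a dorsal midline sinus, cortical
bridging vessels); and synthetic interhemispheric streamlines.

Geometry conventions
--------------------
World frame is RAS-like (x: left→right, y: posterior→anterior,
z: inferior→superior) with the origin at the head centre.  The corpus
callosum is a circular-arch slab in the sagittal plane: a circle of radius
``cc_radius`` centred at ``cc_centre_yz`` swept from the rostrum
(anterior-inferior, arc fraction t=0) over the dorsal body to the splenium
(posterior, t=1), thickened radially and extruded laterally.  The cingulate
band wraps the arch a small radial gap outside it and is partitioned into
subcallosal / anterior / middle / posterior segments at configurable arc
fractions — the construction that makes the 7 mm dilation-and-overlap
target generation land at the rostrum, genu and posterior body.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volio import LabelVolume, StreamlineSet, VoxelGrid

__all__ = [
    "PhantomConfig",
    "VesselTree",
    "GeometryError",
    "DEFAULT_SCHEMA",
    "ENTRY_ROLES",
    "ARCH_SECTORS",
    "make_head_phantom",
    "rasterise_vessels",
    "make_interhemispheric_streamlines",
    "arch_arc_fraction",
    "arch_point",
    "analytic_arch_volume_mm3",
]


class GeometryError(ValueError):
    """A phantom structure would not fit inside the configured grid/head."""


#: role → label id for every structure the planner's default schema needs
DEFAULT_SCHEMA: dict[str, int] = {
    "scalp": 1,
    "skull": 2,
    "brain": 3,
    "ventricles": 4,
    "corpus_callosum": 5,
    "subcallosal_gyrus": 6,
    "anterior_cingulate": 7,
    "middle_cingulate": 8,
    "posterior_cingulate": 9,
    "right_superior_frontal": 10,
    "right_superior_parietal": 11,
    "right_angular": 12,
    "left_superior_frontal": 13,
    "left_middle_frontal": 14,
}

ENTRY_ROLES: tuple[str, ...] = (
    "right_superior_frontal",
    "right_superior_parietal",
    "right_angular",
    "left_superior_frontal",
    "left_middle_frontal",
)

#: arc-fraction sectors of the arch (rostrum → splenium)
ARCH_SECTORS: dict[str, tuple[float, float]] = {
    "rostrum": (0.0, 0.20),
    "genu": (0.20, 0.55),
    "posterior_body": (0.55, 0.85),
    "splenium": (0.85, 1.0),
}

# Entry patch centre directions: scalp points (world mm, left-dominant
# convention) whose surface normals admit Table-style trajectories to the
# corresponding targets; patches are angular windows about these directions.
_ENTRY_PATCH_CENTRES: dict[str, tuple[float, float, float]] = {
    "right_superior_frontal": (4.0, 17.0, 34.0),
    "right_superior_parietal": (10.0, -30.0, 28.3),
    "right_angular": (22.0, -30.0, 20.4),
    "left_superior_frontal": (-8.0, 40.0, 15.1),
    "left_middle_frontal": (-20.0, 35.0, 14.7),
}


@dataclass(frozen=True)
class PhantomConfig:
    """All tunable phantom geometry, lengths in mm, angles in degrees."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.0

    # head: ellipsoid semi-axes, flattened on top so near-orthogonal frontal
    # drilling is geometrically possible, as on a real vertex
    head_axes: tuple[float, float, float] = (41.0, 44.0, 41.0)
    head_cap_z: float = 34.0
    scalp_thickness: float = 3.0
    skull_thickness: float = 3.0

    # corpus callosum arch
    cc_radius: float = 18.0
    cc_thickness: float = 7.0
    cc_half_width: float = 5.0
    cc_centre_yz: tuple[float, float] = (0.0, 0.0)
    cc_phi_deg: tuple[float, float] = (-35.0, 160.0)

    # cingulate band (radially outside the arch)
    band_gap: float = 2.0
    band_thickness: float = 6.0
    band_half_width: float = 5.5
    division_fractions: tuple[float, float, float] = (0.12, 0.45, 0.75)

    # ventricles: paired ellipsoids under the arch
    ventricle_centre: tuple[float, float, float] = (3.5, 0.0, -2.0)
    ventricle_axes: tuple[float, float, float] = (2.5, 11.0, 5.0)

    # entry gyri: angular windows of the cortical shell
    entry_patch_angle_deg: float = 12.0
    entry_patch_depth: float = 4.0

    # vessels
    pericallosal_offset: float = 2.0
    pericallosal_standoff: float = 1.0
    pericallosal_radius: float = 1.0
    sinus_radius: float = 2.0
    bridging_radius: float = 1.0
    frontal_vessel_wall: bool = False

    # streamlines
    n_streamlines: int = 5000
    streamline_t_range: tuple[float, float] = (0.02, 0.98)
    seed: int = 0

    dominant_hemisphere: str = "left"

    def __post_init__(self):
        lengths = (
            self.spacing, *self.head_axes, self.scalp_thickness,
            self.skull_thickness, self.cc_radius, self.cc_thickness,
            self.cc_half_width, self.band_thickness, self.band_half_width,
            *self.ventricle_axes, self.entry_patch_depth,
            self.pericallosal_radius, self.sinus_radius, self.bridging_radius,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all phantom lengths must be positive")
        f = self.division_fractions
        if not (0 < f[0] < f[1] < f[2] < 1):
            raise ValueError(
                "division fractions must be strictly increasing in (0, 1)"
            )
        if self.dominant_hemisphere not in ("left", "right"):
            raise ValueError("dominant_hemisphere must be 'left' or 'right'")
        if self.n_streamlines < 0:
            raise ValueError("n_streamlines must be >= 0")

    @property
    def grid(self) -> VoxelGrid:
        n = self.shape
        s = self.spacing
        affine = np.diag([s, s, s, 1.0])
        # centre the world origin on the grid
        affine[:3, 3] = [-s * (n[0] - 1) / 2, -s * (n[1] - 1) / 2, -s * (n[2] - 1) / 2]
        return VoxelGrid(tuple(n), affine)

    @property
    def phi_range_rad(self) -> tuple[float, float]:
        return tuple(np.deg2rad(self.cc_phi_deg))  # type: ignore[return-value]

    @property
    def mirror_x(self) -> float:
        """-1 when dominance is flipped (mirrors all lateralised geometry)."""
        return 1.0 if self.dominant_hemisphere == "left" else -1.0


@dataclass
class VesselTree:
    """Polyline centrelines in world mm, each with one radius in mm."""

    centrelines: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self):
        for i, (line, radius) in enumerate(self.centrelines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"centreline {i} is not an (N, 3) polyline")
            if radius <= 0:
                raise ValueError(f"centreline {i} has non-positive radius")
            self.centrelines[i] = (arr, float(radius))

    def __len__(self) -> int:
        return len(self.centrelines)


# ---------------------------------------------------------------------------
# arch parametrisation


def arch_point(config: PhantomConfig, t: np.ndarray, radial: float | None = None) -> np.ndarray:
    """(y, z) world coordinates of the arch centreline (or at a given radial
    distance) at arc fractions ``t`` ∈ [0, 1]; t=0 is the rostrum tip."""
    phi0, phi1 = config.phi_range_rad
    phi = phi0 + np.asarray(t, dtype=float) * (phi1 - phi0)
    r = config.cc_radius if radial is None else radial
    yc, zc = config.cc_centre_yz
    return np.stack([yc + r * np.cos(phi), zc + r * np.sin(phi)], axis=-1)


def arch_arc_fraction(config: PhantomConfig, points: np.ndarray) -> np.ndarray:
    """Arc fraction t of world points (nearest angular position on the arch).

    Uses only the sagittal (y, z) components; values are clipped to [0, 1].
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    yc, zc = config.cc_centre_yz
    phi = np.arctan2(pts[..., 2] - zc, pts[..., 1] - yc)
    phi0, phi1 = config.phi_range_rad
    # map into the branch containing the arch sweep
    phi = np.where(phi < phi0 - np.pi / 4, phi + 2 * np.pi, phi)
    return np.clip((phi - phi0) / (phi1 - phi0), 0.0, 1.0)


def analytic_arch_volume_mm3(config: PhantomConfig) -> float:
    """Closed-form volume of the arch slab (annular sector × width)."""
    phi0, phi1 = config.phi_range_rad
    r_out = config.cc_radius + config.cc_thickness / 2
    r_in = config.cc_radius - config.cc_thickness / 2
    return (phi1 - phi0) / 2 * (r_out**2 - r_in**2) * 2 * config.cc_half_width


# ---------------------------------------------------------------------------
# parcellation


def _head_mask(config: PhantomConfig, W: np.ndarray) -> np.ndarray:
    a, b, c = config.head_axes
    inside = (W[..., 0] / a) ** 2 + (W[..., 1] / b) ** 2 + (W[..., 2] / c) ** 2 <= 1.0
    return inside & (W[..., 2] <= config.head_cap_z)


def _brain_surface_z(config: PhantomConfig, x: float, y: float) -> float:
    """z of the brain (head eroded by scalp+skull) surface above (x, y)."""
    a, b, c = config.head_axes
    m = config.scalp_thickness + config.skull_thickness
    v = 1.0 - (x / (a - m)) ** 2 + 0.0 - (y / (b - m)) ** 2
    z = (c - m) * np.sqrt(max(v, 0.0))
    return min(z, config.head_cap_z - m)


def make_head_phantom(config: PhantomConfig | None = None) -> tuple[LabelVolume, VesselTree]:
    """Build the labelled head phantom and its vessel tree.

    Structural labels are pairwise disjoint (assigned with a fixed priority:
    callosum and cingulate band before entry gyri).  The vessel tree is kept
    separate from the parcellation, mirroring pipelines where the vascular
    segmentation comes from angiography rather than the T1 parcellation.
    """
    config = config or PhantomConfig()
    grid = config.grid
    W = grid.voxel_centres_world()
    mx = config.mirror_x
    x, y, z = W[..., 0] * mx, W[..., 1], W[..., 2]

    # ---- head shells -------------------------------------------------------
    head = _head_mask(config, W)
    if not head.any():
        raise GeometryError("head does not intersect the grid")
    spacing = grid.spacing
    depth = ndimage.distance_transform_edt(head, sampling=spacing)
    scalp = head & (depth <= config.scalp_thickness)
    skull = head & (depth > config.scalp_thickness) & (
        depth <= config.scalp_thickness + config.skull_thickness
    )
    brain = head & (depth > config.scalp_thickness + config.skull_thickness)

    # ---- corpus callosum arch ---------------------------------------------
    yc, zc = config.cc_centre_yz
    r = np.hypot(y - yc, z - zc)
    phi = np.arctan2(z - zc, y - yc)
    phi0, phi1 = config.phi_range_rad
    phi = np.where(phi < phi0 - np.pi / 4, phi + 2 * np.pi, phi)
    in_sweep = (phi >= phi0) & (phi <= phi1)
    r_out = config.cc_radius + config.cc_thickness / 2
    if r_out + config.band_gap + config.band_thickness > max(config.head_axes):
        raise GeometryError("cingulate band extends outside the head")
    cc = (
        in_sweep
        & (np.abs(r - config.cc_radius) <= config.cc_thickness / 2)
        & (np.abs(x) <= config.cc_half_width)
        & brain
    )

    # ---- cingulate band segments ------------------------------------------
    band = (
        in_sweep
        & (r > r_out + config.band_gap)
        & (r <= r_out + config.band_gap + config.band_thickness)
        & (np.abs(x) <= config.band_half_width)
        & brain
    )
    t = (phi - phi0) / (phi1 - phi0)
    f1, f2, f3 = config.division_fractions
    subcallosal = band & (t < f1)
    anterior_cing = band & (t >= f1) & (t < f2)
    middle_cing = band & (t >= f2) & (t < f3)
    posterior_cing = band & (t >= f3)

    # ---- ventricles --------------------------------------------------------
    vx, vy, vz = config.ventricle_centre
    va, vb, vc = config.ventricle_axes
    vent = np.zeros_like(brain)
    for side in (+1.0, -1.0):
        vent |= (
            ((x - side * vx) / va) ** 2
            + ((y - vy) / vb) ** 2
            + ((z - vz) / vc) ** 2
        ) <= 1.0
    vent &= brain & ~cc

    # ---- entry gyri patches (cortical shell, angular windows) -------------
    shell = brain & (depth <= config.scalp_thickness + config.skull_thickness
                     + config.entry_patch_depth)
    norms = np.linalg.norm(W, axis=-1)
    norms[norms == 0] = 1.0
    unit = np.stack([x, y, z], axis=-1) / norms[..., None]
    cos_lim = np.cos(np.deg2rad(config.entry_patch_angle_deg))
    patches: dict[str, np.ndarray] = {}
    for role, centre in _ENTRY_PATCH_CENTRES.items():
        cdir = np.asarray(centre) / np.linalg.norm(centre)
        patches[role] = shell & (unit @ cdir >= cos_lim)

    # ---- assemble labels with fixed priority ------------------------------
    labels = np.zeros(grid.shape, dtype=np.int32)
    order: list[tuple[str, np.ndarray]] = [
        ("scalp", scalp),
        ("skull", skull),
        ("brain", brain),
        ("corpus_callosum", cc),
        ("subcallosal_gyrus", subcallosal),
        ("anterior_cingulate", anterior_cing),
        ("middle_cingulate", middle_cing),
        ("posterior_cingulate", posterior_cing),
        ("ventricles", vent),
    ] + [(role, patches[role]) for role in ENTRY_ROLES]
    for role, mask in order:
        lab = DEFAULT_SCHEMA[role]
        if role in ("scalp", "skull", "brain"):
            labels[mask] = lab
        else:
            labels[mask & (labels == DEFAULT_SCHEMA["brain"])] = lab
    for role, lab in DEFAULT_SCHEMA.items():
        if not (labels == lab).any():
            raise GeometryError(f"structure {role!r} is empty on this grid")

    table = {lab: role for role, lab in DEFAULT_SCHEMA.items()}
    vol = LabelVolume(grid, labels, table)
    tree = _make_vessel_tree(config)
    return vol, tree


def _make_vessel_tree(config: PhantomConfig) -> VesselTree:
    mx = config.mirror_x
    lines: list[tuple[np.ndarray, float]] = []
    r_out = config.cc_radius + config.cc_thickness / 2

    # pericallosal arteries: paired, just above the dorsal callosal surface,
    # slightly lateral to the midline — the hazard that forces lateral plans
    t = np.linspace(0.0, 1.0, 160)
    yz = arch_point(config, t, radial=r_out + config.pericallosal_standoff)
    for side in (+1.0, -1.0):
        xs = np.full(len(t), side * config.pericallosal_offset * mx)
        lines.append((np.column_stack([xs, yz[:, 0], yz[:, 1]]),
                      config.pericallosal_radius))

    # superior sagittal sinus: midline, just inside the brain surface
    ys = np.arange(-34.0, 36.5, 1.0)
    pts = np.array([[0.0, yv, _brain_surface_z(config, 0.0, yv) - 1.0] for yv in ys])
    lines.append((pts, config.sinus_radius))

    # cortical bridging vessels: short cortex→sinus segments
    for yv, side in ((34.0, +1.0), (6.0, -1.0), (-16.0, +1.0), (-34.0, -1.0)):
        x1 = side * 10.0 * mx
        p0 = np.array([0.0, yv, _brain_surface_z(config, 0.0, yv) - 1.0])
        p1 = np.array([x1, yv, _brain_surface_z(config, x1, yv) - 1.0])
        seg = np.linspace(p0, p1, 12)
        lines.append((seg, config.bridging_radius))

    if config.frontal_vessel_wall:
        # adversarial variant: a vascular plate sealing the frontal approach
        # to the rostrum on the non-dominant side
        for xv in np.arange(-6.0, 14.5, 1.5):
            seg = np.column_stack([
                np.full(27, xv * mx),
                np.arange(4.0, 31.0, 1.0),
                np.full(27, 30.0),
            ])
            lines.append((seg, 1.0))

    return VesselTree(lines)


# ---------------------------------------------------------------------------
# vessel rasterisation


def rasterise_vessels(tree: VesselTree, grid: VoxelGrid) -> LabelVolume:
    """Binary capsule rasterisation: a voxel is set iff its centre lies
    within radius of a centreline (centrelines are resampled at 0.2 mm, so
    the capsule boundary is honoured to well below voxel size)."""
    if len(tree) == 0:
        return LabelVolume(grid, np.zeros(grid.shape, dtype=np.uint8))
    mask = np.zeros(grid.shape, dtype=bool)
    centres = grid.voxel_centres_world().reshape(-1, 3)
    kdt = cKDTree(centres)
    for line, radius in tree.centrelines:
        samples = _resample_polyline(line, 0.2)
        hit = kdt.query_ball_point(samples, r=radius, return_length=False)
        idx = np.unique(np.concatenate([np.asarray(h, dtype=int) for h in hit])
                        ) if len(samples) else np.array([], dtype=int)
        if idx.size:
            flat = mask.reshape(-1)
            flat[idx] = True
    return LabelVolume(grid, mask.astype(np.uint8))


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at arc-length spacing ≤ step (endpoints kept)."""
    points = np.asarray(points, dtype=float)
    if len(points) == 1:
        return points
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(si, s, points[:, k])
    return out


# ---------------------------------------------------------------------------
# interhemispheric streamlines


def make_interhemispheric_streamlines(
    phantom: LabelVolume,
    n: int,
    seed: int,
    config: PhantomConfig | None = None,
) -> StreamlineSet:
    """Synthetic interhemispheric streamlines: noisy near-coronal circular
    arcs through a sampled callosal crossing point.

    Each polyline starts in the left hemisphere (x < 0), ends in the right,
    and passes through the corpus callosum; crossing arc positions are
    sampled uniformly over ``config.streamline_t_range`` to cover
    rostrum→splenium.  No diffusion physics is simulated.
    """
    if n < 0:
        raise ValueError("streamline count must be >= 0")
    config = config or PhantomConfig()
    # fail loudly if the phantom lacks the roles we anchor to
    phantom.label_for("corpus_callosum")
    phantom.label_for("brain")
    rng = np.random.default_rng(seed)
    t_lo, t_hi = config.streamline_t_range
    lines: list[np.ndarray] = []
    alphas = np.deg2rad(np.linspace(150.0, 30.0, 41))
    for _ in range(n):
        t = rng.uniform(t_lo, t_hi)
        yz = arch_point(config, t)
        x0 = rng.uniform(-1.5, 1.5)
        rho = rng.uniform(11.0, 14.0)
        amp = rng.uniform(0.0, 0.8)
        psi = rng.uniform(0.0, 2 * np.pi)
        xs = x0 + rho * np.cos(alphas)
        zs = float(yz[1]) - rho + rho * np.sin(alphas)
        ys = float(yz[0]) + amp * np.sin(2 * alphas + psi)
        pts = np.column_stack([xs, ys, zs])
        pts += rng.normal(0.0, 0.05, size=pts.shape)
        lines.append(pts)
    return StreamlineSet(lines, provenance=f"phantom arcs seed={seed} n={n}")


def adversarial_config(base: PhantomConfig | None = None) -> PhantomConfig:
    """The vascular-wall variant: cortical vasculature seals the frontal
    approach to the rostrum, the failure mode that leaves residual anterior
    connectivity."""
    base = base or PhantomConfig()
    return replace(base, frontal_vessel_wall=True)
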