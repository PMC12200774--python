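"""Synthetic tensor phantoms and longitudinal cohorts with known truth.

The phantom is an ellipsoidal "brain" of isotropic tensors
(MD 1.0e-3 mm^2/s) carrying three white-matter-like tract systems: a
midline arc (corpus-callosum-like), two lateral straight bundles, and a
horizontal bundle that crosses them.  Tract tensors are prolate
(cigar-shaped) with a prescribed FA, oriented along the local tract
tangent; the background is the isotropic floor tensor.

A cohort emulates a longitudinal infant sample: scans fall into
maturation stages that differ in tract FA and global brain scale, each
scan is displaced by a known random rigid transform and a known smooth
random warp, and tensor-valued noise is added on the matrix-log
components inside the brain (air stays empty, as it would after
skull-stripping).  Ages are drawn from disjoint per-stage ranges so age
binning and similarity clustering can be compared on the same cohort.
All randomness descends from one seed; the same spec reproduces the same
cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .transforms import (
    AffineTransform,
    DisplacementField,
    Grid,
    apply_transform,
    grid_world_coords,
)
from .volumes import LAMBDA_FLOOR, TensorVolume, exp_tensor_field, log_tensor_field

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "make_phantom",
    "make_cohort",
    "phantom_geometry",
    "invert_displacement",
]


@dataclasses.dataclass
class CohortSpec:
    """Generating conditions of a synthetic cohort.

    Defaults describe the packaged heterogeneous cohort: 12 scans in 3
    maturation stages on a 48^3 grid of 2 mm voxels.  Stages differ in
    tract FA (0.35/0.50/0.65, myelination), global scale (0.80/1.00/1.15;
    brain volume nearly doubles over the first half year, so linear size
    spans ~1.4x) and anatomy shape (stage_shape morphs).  Per scan:
    rigid jitter up to 8 degrees / 4 mm (variable infant positioning),
    smooth individual warps up to 4 mm with 12 mm correlation length,
    and log-tensor noise SD 0.08 (about 8% multiplicative eigenvalue
    noise, infant-protocol level).
    """

    n_scans: int = 12
    n_groups: int = 3
    grid: tuple = (48, 48, 48)
    voxel_mm: float = 2.0
    stage_fa: tuple = (0.35, 0.50, 0.65)
    stage_scale: tuple = (0.80, 1.00, 1.15)
    stage_shape: tuple = (0.0, 0.5, 1.0)
    rigid_rot_deg: float = 8.0
    rigid_trans_mm: float = 4.0
    warp_amplitude: float = 4.0
    warp_smoothness: float = 12.0
    noise_sd: float = 0.08
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_groups > self.n_scans:
            raise ValueError("n_groups cannot exceed n_scans")
        if (
            len(self.stage_fa) < self.n_groups
            or len(self.stage_scale) < self.n_groups
            or len(self.stage_shape) < self.n_groups
        ):
            raise ValueError("need stage_fa, stage_scale and stage_shape per group")
        if any(not 0 < f < 1 for f in self.stage_fa):
            raise ValueError("stage FA targets must lie in (0, 1)")
        if min(self.rigid_rot_deg, self.rigid_trans_mm, self.warp_amplitude,
               self.warp_smoothness, self.noise_sd) < 0:
            raise ValueError("amplitudes must be nonnegative")


@dataclasses.dataclass
class GroundTruth:
    """Per-scan generating transforms and labels of a synthetic cohort."""

    labels: dict
    rigid: dict
    warp: dict
    ages: dict
    seeds: dict

    def chain(self, sid) -> list:
        """Pull-back chain that generated the scan from its stage phantom."""
        return [self.rigid[sid], self.warp[sid]]

    def to_json(self, path: str | Path) -> None:
        out = {
            sid: {
                "label": int(self.labels[sid]),
                "age_months": float(self.ages[sid]),
                "rigid_matrix": self.rigid[sid].matrix.tolist(),
                "seed": int(self.seeds[sid]),
            }
            for sid in self.labels
        }
        Path(path).write_text(json.dumps(out, indent=2))


def _phantom_affine(grid: Sequence[int], voxel_mm: float) -> np.ndarray:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -(np.asarray(grid) - 1) / 2.0 * voxel_mm
    return affine


def phantom_geometry(
    grid: Sequence[int] = (48, 48, 48),
    stage_scale: float = 1.0,
    voxel_mm: float = 2.0,
    stage_shape: float = 0.5,
) -> dict:
    """Masks and tangent fields of the phantom's anatomy (world frame).

    ``stage_shape`` in [0, 1] morphs the anatomy the way maturation
    changes it beyond pure growth: the brain outline elongates, the
    midline arc widens and flattens, the lateral bundles migrate outward
    and tilt, and the crossing bundle shifts.  Within a maturation stage
    the geometry is fixed; across stages these non-affine shape
    differences are what subgroup templates can capture and a single
    pooled template blurs.

    Returns brain/tract masks, per-tract unit tangent fields, and the
    crossing region (lateral bundles intersecting the horizontal bundle).
    """
    s = float(stage_shape)
    if not 0.0 <= s <= 1.0:
        raise ValueError("stage_shape must lie in [0, 1]")
    affine = _phantom_affine(grid, voxel_mm)
    X = grid_world_coords(Grid(tuple(grid), affine))
    half = np.asarray(grid) * voxel_mm / 2.0
    ax = 0.84 * half[0] * stage_scale
    ay = (0.66 + 0.10 * s) * half[1] * stage_scale
    az = (0.70 - 0.08 * s) * half[2] * stage_scale
    x, y, z = X[..., 0], X[..., 1], X[..., 2]
    brain = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0

    # midline arc in the sagittal (y-z) plane; radius and reach morph
    zc = (-0.24 + 0.14 * s) * az
    r = (0.46 + 0.18 * s) * az
    rho_arc = 0.16 * az
    ring = np.hypot(y, z - zc)
    arc = (
        (np.abs(ring - r) <= rho_arc)
        & (z - zc >= (0.50 - 0.20 * s) * r)
        & (np.abs(x) <= 0.22 * ax)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        t_arc = np.stack([np.zeros_like(y), (z - zc) / ring, -y / ring], axis=-1)
    t_arc = np.nan_to_num(t_arc)

    # lateral bundles: near-vertical cylinders that migrate and tilt
    x1 = (0.36 + 0.14 * s) * ax
    y1 = (-0.24 + 0.14 * s) * ay
    tilt = np.deg2rad(28.0 * (s - 0.5))  # lean in the y-z plane
    dy, dz = np.sin(tilt), np.cos(tilt)
    rho_cyl = 0.14 * min(ax, ay)
    # distance from the line through (+-x1, y1, 0) with direction (0, dy, dz)
    py, pz = y - y1, z
    along = py * dy + pz * dz
    perp = np.hypot(py - along * dy, pz - along * dz)
    lateral = (
        (np.hypot(np.abs(x) - x1, perp) <= rho_cyl) & (np.abs(along) <= 0.55 * az)
    )
    t_lateral = np.broadcast_to(np.array([0.0, dy, dz]), X.shape).copy()

    # horizontal bundle along x, crossing the lateral bundles
    z2 = (s - 0.5) * 0.36 * az
    y2 = y1 + np.tan(tilt) * z2  # stays on the lateral bundles' axis
    crossing_bundle = (np.hypot(y - y2, z - z2) <= rho_cyl) & (np.abs(x) <= 0.6 * ax)
    t_cross = np.broadcast_to(np.array([1.0, 0.0, 0.0]), X.shape).copy()

    return {
        "affine": affine,
        "brain": brain,
        "arc": arc & brain,
        "lateral": lateral & brain,
        "crossing_bundle": crossing_bundle & brain,
        "crossing_region": (lateral & crossing_bundle) & brain,
        "tangent_arc": t_arc,
        "tangent_lateral": t_lateral,
        "tangent_crossing": t_cross,
    }


def _prolate_components(direction: np.ndarray, fa: float, md: float = 1.0e-3) -> np.ndarray:
    """6 components of prolate tensors with given FA/MD along ``direction``.

    For an axisymmetric tensor with eigenvalues (m(1+2d), m(1-d), m(1-d))
    the FA closed form gives d = FA / sqrt(3 - 2 FA^2); positive
    eigenvalues require FA < 1.
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError(f"FA target {fa} unreachable with positive eigenvalues")
    d = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    lam_long = md * (1.0 + 2.0 * d)
    lam_perp = md * (1.0 - d)
    n = direction
    outer = np.stack(
        [
            n[..., 0] * n[..., 0], n[..., 0] * n[..., 1], n[..., 1] * n[..., 1],
            n[..., 0] * n[..., 2], n[..., 1] * n[..., 2], n[..., 2] * n[..., 2],
        ],
        axis=-1,
    )
    iso = np.zeros(direction.shape[:-1] + (6,))
    iso[..., [0, 2, 5]] = lam_perp
    return iso + (lam_long - lam_perp) * outer


#: internal seed of the parenchymal texture; the texture is anatomy, shared
#: by every stage phantom, so it never varies across scans or stages
_TEXTURE_SEED = 1234


def _parenchyma_texture(grid: Sequence[int], fa_lo: float, fa_hi: float):
    """Smooth coherent mild-anisotropy field emulating brain parenchyma.

    Real brain tissue is weakly anisotropic everywhere (gray matter FA
    ~0.1-0.2) with spatially coherent orientations; an empty isotropic
    "sea" would hand scalar FA registration an unrealistically easy,
    noise-free landscape.  Returns (FA amplitude field, unit direction
    field), deterministic for a given grid.
    """
    rng = np.random.default_rng(_TEXTURE_SEED)
    amp = gaussian_filter(rng.standard_normal(tuple(grid)), 2.0)
    amp = (amp - amp.min()) / max(np.ptp(amp), 1e-12)
    amp = fa_lo + (fa_hi - fa_lo) * amp
    n = np.stack(
        [gaussian_filter(rng.standard_normal(tuple(grid)), 3.0) for _ in range(3)],
        axis=-1,
    )
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    n = np.where(norm > 1e-12, n / np.maximum(norm, 1e-12), [1.0, 0.0, 0.0])
    return amp, n


def make_phantom(
    grid: Sequence[int] = (48, 48, 48),
    stage_fa: float = 0.50,
    stage_scale: float = 1.0,
    seed: int = 0,
    voxel_mm: float = 2.0,
    smooth_sigma: float = 0.8,
    stage_shape: float = 0.5,
    texture_fa: tuple = (0.05, 0.22),
) -> TensorVolume:
    """Deterministic stage phantom: textured brain plus anisotropic tracts.

    Non-tract brain voxels carry mildly anisotropic "parenchyma" tensors
    (FA between ``texture_fa`` bounds, below the 0.25 evaluation
    threshold) with a smooth coherent orientation field shared by all
    stages.  The assembled field is smoothed componentwise
    (``smooth_sigma`` voxels; a convex combination of PSD tensors stays
    PSD) so the phantom is band-limited like acquired DTI data;
    piecewise-constant fields would otherwise let interpolation
    artifacts dominate sub-voxel registration.
    """
    geo = phantom_geometry(grid, stage_scale, voxel_mm, stage_shape=stage_shape)
    tensors = np.zeros(tuple(grid) + (6,))
    tensors[..., [0, 2, 5]] = LAMBDA_FLOOR
    brain = geo["brain"]
    amp, n_tex = _parenchyma_texture(grid, *texture_fa)
    # per-voxel FA needs a per-voxel eigenvalue split; vectorized over brain
    fa_b = amp[brain]
    d = fa_b / np.sqrt(3.0 - 2.0 * fa_b * fa_b)
    md = 1.0e-3
    lam_long = md * (1.0 + 2.0 * d)
    lam_perp = md * (1.0 - d)
    n_b = n_tex[brain]
    outer = np.stack(
        [
            n_b[:, 0] * n_b[:, 0], n_b[:, 0] * n_b[:, 1], n_b[:, 1] * n_b[:, 1],
            n_b[:, 0] * n_b[:, 2], n_b[:, 1] * n_b[:, 2], n_b[:, 2] * n_b[:, 2],
        ],
        axis=-1,
    )
    iso6 = np.zeros((fa_b.size, 6))
    iso6[:, [0, 2, 5]] = lam_perp[:, None]
    tensors[brain] = iso6 + (lam_long - lam_perp)[:, None] * outer
    # priority: arc over lateral over crossing bundle
    for mask_name, tan_name in (
        ("crossing_bundle", "tangent_crossing"),
        ("lateral", "tangent_lateral"),
        ("arc", "tangent_arc"),
    ):
        m = geo[mask_name]
        tensors[m] = _prolate_components(geo[tan_name][m], stage_fa)
    if smooth_sigma > 0:
        tensors = np.stack(
            [gaussian_filter(tensors[..., k], smooth_sigma) for k in range(6)], axis=-1
        )
    return TensorVolume(tensors, geo["affine"])


def _random_smooth_warp(
    grid: Grid, amplitude: float, smoothness_mm: float, voxel_mm: float,
    rng: np.random.Generator,
) -> DisplacementField:
    u = rng.standard_normal(tuple(grid.shape) + (3,))
    sigma = max(smoothness_mm / voxel_mm, 0.5)
    for k in range(3):
        u[..., k] = gaussian_filter(u[..., k], sigma=sigma)
    mags = np.sqrt((u * u).sum(axis=-1))
    peak = mags.max()
    if peak > 0 and amplitude > 0:
        u *= amplitude / peak
    else:
        u[:] = 0.0
    return DisplacementField(u, grid.affine.copy(), provenance=["synthetic warp"])


def make_cohort(spec: CohortSpec) -> tuple[list, GroundTruth, dict]:
    """Generate a cohort: (scans, ground truth, ages).

    Scans are assigned to stages in balanced contiguous blocks; each scan
    is its stage phantom seen through a random rigid transform composed
    with a random smooth warp, plus seeded log-tensor noise inside the
    brain.  Ages are drawn from disjoint per-stage ranges.
    """
    grid = Grid(tuple(spec.grid), _phantom_affine(spec.grid, spec.voxel_mm))
    stages = [
        make_phantom(spec.grid, spec.stage_fa[g], spec.stage_scale[g],
                     voxel_mm=spec.voxel_mm, stage_shape=spec.stage_shape[g])
        for g in range(spec.n_groups)
    ]
    if spec.n_groups == 3:
        age_ranges = [(0.0, 3.0), (3.0, 6.0), (6.0, 8.0)]
    else:
        edges = np.linspace(0.0, 8.0, spec.n_groups + 1)
        age_ranges = list(zip(edges[:-1], edges[1:]))

    seed_seq = np.random.SeedSequence(spec.seed)
    scan_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(spec.n_scans)]

    scans, labels, rigid_t, warp_t, ages, seeds = [], {}, {}, {}, {}, {}
    ids = [f"scan{i:02d}" for i in range(spec.n_scans)]
    for i, sid in enumerate(ids):
        g = i * spec.n_groups // spec.n_scans
        rng = np.random.default_rng(scan_seeds[i])
        rot = np.deg2rad(rng.uniform(-spec.rigid_rot_deg, spec.rigid_rot_deg, 3))
        trans = rng.uniform(-spec.rigid_trans_mm, spec.rigid_trans_mm, 3)
        A = AffineTransform.from_params([*rot, *trans], center=(0.0, 0.0, 0.0))
        W = _random_smooth_warp(grid, spec.warp_amplitude, spec.warp_smoothness,
                                spec.voxel_mm, rng)
        scan = apply_transform(stages[g], [A, W], grid)
        if spec.noise_sd > 0:
            logf = log_tensor_field(scan.tensors)
            brain = (scan.tensors[..., 0] + scan.tensors[..., 2] + scan.tensors[..., 5]) / 3.0 > 1e-6
            noise = rng.normal(0.0, spec.noise_sd, logf.shape) * brain[..., None]
            scan = TensorVolume(exp_tensor_field(logf + noise), grid.affine.copy())
        scans.append(scan)
        labels[sid] = g
        rigid_t[sid] = A
        warp_t[sid] = W
        ages[sid] = float(rng.uniform(*age_ranges[g]))
        seeds[sid] = scan_seeds[i]

    gt = GroundTruth(labels, rigid_t, warp_t, ages, seeds)
    return scans, gt, ages


def invert_displacement(field: DisplacementField, iterations: int = 10) -> DisplacementField:
    """Fixed-point inverse of a displacement field on its own grid.

    Solves u_inv(x) = -u(x + u_inv(x)); accurate for smooth, moderate
    warps (the synthetic ground-truth regime).
    """
    grid = field.grid
    pts = grid_world_coords(grid)
    u_inv = np.zeros_like(field.displacement)
    for _ in range(iterations):
        u_inv = -field.sample(pts + u_inv)
    return DisplacementField(u_inv, field.affine.copy(), provenance=["inverse"])
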