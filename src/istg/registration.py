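"""Pairwise tensor-aware registration: rigid, affine, deformable.

The engine minimizes the mean squared Frobenius difference between the
fixed tensors and the transformed-and-reoriented moving tensors (the
Euclidean tensor metric); in scalar mode the same machinery runs on FA
maps with a squared-difference metric.  Optimization is a deterministic
multi-resolution pattern search (coordinate-wise descent with a halving
step schedule) — no randomness anywhere in the engine, so identical
inputs always give identical transforms.

The deformable stage is hierarchical piecewise-affine: at level L the
fixed domain is split into 2^L uniform blocks per axis, each block fits a
local affine increment on the metric with a penalty tying its corner
displacements to already-estimated neighbors, the block transforms are
blended into a continuous displacement increment by a trilinear partition
of unity over block centers, and increments are composed across levels
while keeping the local Jacobian determinant above a positive floor by
step damping.

Cost is evaluated only where the fixed volume carries signal (MD above a
fraction of its robust maximum; FA above a small floor in scalar mode), so
background voxels never drive the alignment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .interp import trilinear_sample
from .transforms import (
    AffineTransform,
    DisplacementField,
    Grid,
    congruence6,
    grid_world_coords,
    polar_rotation,
    _jacobian_of_mapping,
)
from .volumes import (
    FROBENIUS_WEIGHTS,
    ScalarVolume,
    TensorVolume,
    compute_md,
    log_tensor_field,
)

__all__ = [
    "RegistrationSettings",
    "RegistrationError",
    "register_rigid",
    "register_affine",
    "register_deformable",
    "registration_cost",
]


class RegistrationError(RuntimeError):
    pass


@dataclasses.dataclass
class RegistrationSettings:
    """Engine configuration shared by the rigid/affine/deformable stages.

    metric : "tensor" (Frobenius difference of tensors) or "fa"
        (squared difference of FA values).
    pyramid : coarse-to-fine downsampling factors for the linear stages.
    rot/trans/scale/shear steps : initial pattern-search step sizes at
        pyramid factor 1 (scaled up at coarser levels); translations are
        in voxels of the fixed image, rotations in radians.
    halvings : number of step-halving rounds per pyramid level.
    max_cost_voxels : cap on fixed-mask voxels entering the cost (the mask
        is strided deterministically beyond it).
    mask_fraction : fixed-side MD threshold as a fraction of the robust
        (95th percentile) maximum.
    deform_* : hierarchical piecewise-affine controls; blocks switch from
        full local affines to translation-only above
        ``deform_affine_max_blocks`` blocks per axis.
    """

    metric: str = "tensor"
    pyramid: tuple = (4, 2, 1)
    rot_step: float = 0.02
    trans_step_vox: float = 1.0
    scale_step: float = 0.02
    shear_step: float = 0.02
    halvings: int = 3
    max_sweeps: int = 24
    max_cost_voxels: int = 12000
    mask_fraction: float = 0.1
    scalar_mask_floor: float = 0.01
    min_overlap: float = 0.05
    # deformable stage
    deform_levels: int = 3
    deform_tie_weight: float = 0.05
    deform_affine_max_blocks: int = 4
    deform_min_jacobian: float = 0.1
    deform_min_block_voxels: int = 12
    deform_sweeps: int = 8


# ---------------------------------------------------------------------------
# data preparation


def _metric_arrays(vol, settings: RegistrationSettings):
    """(data (X,Y,Z,C), cval (C,), weights (C,), signal values) for a volume."""
    if settings.metric == "tensor":
        if not isinstance(vol, TensorVolume):
            raise TypeError("tensor metric requires TensorVolume inputs")
        data = vol.tensors
        cval = np.zeros(6)
        w = FROBENIUS_WEIGHTS
        signal = compute_md(vol).values
    elif settings.metric == "fa":
        if isinstance(vol, ScalarVolume):
            values = vol.values
        else:
            from .volumes import compute_fa

            values = compute_fa(vol).values
        data = values[..., None]
        cval = np.zeros(1)
        w = np.ones(1)
        signal = values
    else:
        raise ValueError(f"unknown metric {settings.metric!r}")
    return data, cval, w, signal


def _fixed_mask(signal: np.ndarray, settings: RegistrationSettings) -> np.ndarray:
    if settings.metric == "tensor":
        pos = signal[signal > 0]
        if pos.size == 0:
            raise RegistrationError("fixed volume carries no signal")
        thr = settings.mask_fraction * np.percentile(pos, 95)
    else:
        thr = settings.scalar_mask_floor
    mask = signal > thr
    if not mask.any():
        raise RegistrationError("empty fixed-side cost mask")
    return mask


def _downsample(data: np.ndarray, affine: np.ndarray, factor: int):
    if factor == 1:
        return data, affine
    sm = np.stack(
        [gaussian_filter(data[..., k], sigma=factor / 2.0) for k in range(data.shape[-1])],
        axis=-1,
    )
    sub = sm[::factor, ::factor, ::factor, :]
    scale = np.diag([factor, factor, factor, 1.0])
    return sub, affine @ scale


class _LinearCost:
    """Mean metric cost of an affine map at a fixed pyramid level."""

    def __init__(self, fixed_data, fixed_affine, fixed_mask, moving_data,
                 moving_affine, cval, weights, center, dof, max_voxels):
        idx = np.argwhere(fixed_mask)
        if idx.shape[0] > max_voxels:
            stride = int(np.ceil(idx.shape[0] / max_voxels))
            idx = idx[::stride]
        pts = idx @ fixed_affine[:3, :3].T + fixed_affine[:3, 3]
        self.pts = pts
        self.fvals = fixed_data[idx[:, 0], idx[:, 1], idx[:, 2], :]
        self.moving_data = moving_data
        self.inv_moving = np.linalg.inv(moving_affine)
        self.cval = cval
        self.weights = weights
        self.center = center
        self.dof = dof
        self.tensor = fixed_data.shape[-1] == 6
        self.n_evals = 0

    def transform_of(self, params) -> AffineTransform:
        return AffineTransform.from_params(params, center=self.center)

    def _matrix_of(self, params) -> np.ndarray:
        """from_params without dataclass validation (hot path)."""
        p = np.asarray(params, dtype=float)
        from .transforms import rotation_matrix

        R = rotation_matrix(p[0], p[1], p[2])
        if p.size == 12:
            s = np.exp(p[6:9])
            U = np.array(
                [[s[0], p[9], p[10]], [0.0, s[1], p[11]], [0.0, 0.0, s[2]]]
            )
            L = R @ U
        else:
            L = R
        m = np.eye(4)
        m[:3, :3] = L
        m[:3, 3] = self.center + p[3:6] - L @ self.center
        return m

    def cost_of_matrix(self, matrix: np.ndarray) -> float:
        self.n_evals += 1
        L = matrix[:3, :3]
        pts_m = self.pts @ L.T + matrix[:3, 3]
        vox = pts_m @ self.inv_moving[:3, :3].T + self.inv_moving[:3, 3]
        mvals = trilinear_sample(self.moving_data, vox, cval=self.cval)
        if self.tensor:
            # Frobenius norm is invariant under a rotation congruence, so
            # reorienting the moving samples by R equals counter-rotating
            # the fixed tensors; rotate whichever via two batched matmuls
            R = polar_rotation(L[None])[0].T
            from .volumes import matrices_to_tensors, tensors_to_matrices

            D = tensors_to_matrices(mvals)
            mvals = matrices_to_tensors((R @ D) @ R.T)
        diff = self.fvals - mvals
        return float(np.mean((diff * diff) @ self.weights))

    def __call__(self, params) -> float:
        return self.cost_of_matrix(self._matrix_of(params))

    def overlap_fraction(self, matrix: np.ndarray) -> float:
        pts_m = self.pts @ matrix[:3, :3].T + matrix[:3, 3]
        vox = pts_m @ self.inv_moving[:3, :3].T + self.inv_moving[:3, 3]
        hi = np.array(self.moving_data.shape[:3]) - 1
        inside = np.all((vox >= 0) & (vox <= hi), axis=1)
        return float(inside.mean())


def _pattern_search(f, p0, steps, halvings, max_sweeps, f0=None, rel_tol=1e-4):
    """Deterministic coordinate pattern search; returns (params, cost).

    Sweeps stop early once a full sweep improves the cost by less than
    ``rel_tol`` relatively — late sweeps otherwise trickle negligible
    gains at full cost-evaluation price.
    """
    p = np.asarray(p0, dtype=float).copy()
    fp = f(p) if f0 is None else f0
    steps = np.asarray(steps, dtype=float).copy()
    for _ in range(halvings + 1):
        for _ in range(max_sweeps):
            f_start = fp
            improved = False
            for i in range(p.size):
                for sgn in (1.0, -1.0):
                    q = p.copy()
                    q[i] += sgn * steps[i]
                    fq = f(q)
                    if fq < fp - 1e-15:
                        p, fp = q, fq
                        improved = True
                        break
            if not improved or (f_start - fp) <= rel_tol * max(fp, 1e-300):
                break
        steps *= 0.5
    return p, fp


def _center_of_mass(signal: np.ndarray, affine: np.ndarray) -> np.ndarray:
    w = np.maximum(signal, 0.0)
    total = w.sum()
    if total <= 0:
        raise RegistrationError("cannot compute center of mass of empty signal")
    idx = np.indices(signal.shape, dtype=float)
    com_vox = np.array([(idx[a] * w).sum() / total for a in range(3)])
    return affine[:3, :3] @ com_vox + affine[:3, 3]


def _pyramid_factors(shape, settings: RegistrationSettings):
    return [f for f in settings.pyramid if min(shape) // f >= 8] or [1]


def _register_linear(moving, fixed, dof, settings, init: AffineTransform | None):
    f_data, cval, weights, f_signal = _metric_arrays(fixed, settings)
    m_data, _, _, m_signal = _metric_arrays(moving, settings)
    center = _center_of_mass(f_signal, fixed.affine)

    if init is None:
        t0 = _center_of_mass(m_signal, moving.affine) - center
        params = np.zeros(12)
        params[3:6] = t0
    else:
        params = init.to_params(center=center)
        if dof == 6:
            params[6:] = 0.0
    if dof == 6:
        params = params[:6]

    voxel = float(np.min(np.sqrt((fixed.affine[:3, :3] ** 2).sum(axis=0))))
    cost = None
    for factor in _pyramid_factors(fixed.shape, settings):
        fd, fa = _downsample(f_data, fixed.affine, factor)
        md, ma = _downsample(m_data, moving.affine, factor)
        f_sig = fd[..., 0] if settings.metric == "fa" else (fd[..., 0] + fd[..., 2] + fd[..., 5]) / 3.0
        mask = _fixed_mask(f_sig, settings)
        cost = _LinearCost(fd, fa, mask, md, ma, cval, weights, center, dof,
                           settings.max_cost_voxels)
        if cost.overlap_fraction(cost.transform_of(params).matrix) < settings.min_overlap:
            raise RegistrationError("no overlap between fixed and moving after initialization")
        steps = np.empty(params.size)
        steps[:3] = settings.rot_step * factor
        steps[3:6] = settings.trans_step_vox * voxel * factor
        if dof == 12:
            steps[6:9] = settings.scale_step * factor
            steps[9:12] = settings.shear_step * factor
        params, final_cost = _pattern_search(
            cost, params, steps, settings.halvings, settings.max_sweeps
        )
    out = AffineTransform.from_params(params, center=center)
    return AffineTransform(out.matrix, dof=dof)


def register_rigid(
    moving, fixed, settings: RegistrationSettings | None = None,
    init: AffineTransform | None = None,
) -> AffineTransform:
    """6-dof rigid alignment of ``moving`` onto ``fixed``.

    Initialized from the signal centers of mass unless ``init`` is given;
    parameterized as 3 Euler angles + 3 translations about the fixed
    center of mass.
    """
    settings = settings or RegistrationSettings()
    return _register_linear(moving, fixed, 6, settings, init)


def register_affine(
    moving, fixed, init: AffineTransform | None = None,
    settings: RegistrationSettings | None = None,
) -> AffineTransform:
    """12-dof affine alignment, normally initialized from the rigid result."""
    settings = settings or RegistrationSettings()
    return _register_linear(moving, fixed, 12, settings, init)


def registration_cost(moving, fixed, transform, settings: RegistrationSettings | None = None) -> float:
    """Full-resolution cost of an affine transform (optimizer-independent)."""
    settings = settings or RegistrationSettings()
    f_data, cval, weights, f_signal = _metric_arrays(fixed, settings)
    m_data, _, _, _ = _metric_arrays(moving, settings)
    mask = _fixed_mask(f_signal, settings)
    center = _center_of_mass(f_signal, fixed.affine)
    cost = _LinearCost(f_data, fixed.affine, mask, m_data, moving.affine, cval,
                       weights, center, getattr(transform, "dof", 12),
                       settings.max_cost_voxels)
    return cost.cost_of_matrix(transform.matrix)


# ---------------------------------------------------------------------------
# deformable


class _WarpCost:
    """Masked mean metric cost of a displacement field on the fixed grid."""

    def __init__(self, fixed_data, fixed_affine, fixed_mask, moving_data,
                 moving_affine, cval, weights, max_voxels):
        idx = np.argwhere(fixed_mask)
        if idx.shape[0] > max_voxels:
            stride = int(np.ceil(idx.shape[0] / max_voxels))
            idx = idx[::stride]
        self.idx = idx
        self.pts = idx @ fixed_affine[:3, :3].T + fixed_affine[:3, 3]
        self.fvals = fixed_data[idx[:, 0], idx[:, 1], idx[:, 2], :]
        self.moving_data = moving_data
        self.inv_moving = np.linalg.inv(moving_affine)
        self.cval = cval
        self.weights = weights
        # normalizer so the cost is O(1) and penalty weights are portable
        self.norm = float(np.mean((self.fvals * self.fvals) @ weights)) or 1.0

    def residual_cost(self, pts_warped: np.ndarray, fsel=None) -> float:
        vox = pts_warped @ self.inv_moving[:3, :3].T + self.inv_moving[:3, 3]
        mvals = trilinear_sample(self.moving_data, vox, cval=self.cval)
        fvals = self.fvals if fsel is None else fsel
        diff = fvals - mvals
        return float(np.mean((diff * diff) @ self.weights)) / self.norm


def register_deformable(
    moving, fixed, levels: int | None = None,
    settings: RegistrationSettings | None = None,
) -> DisplacementField:
    """Hierarchical piecewise-affine deformable registration.

    ``moving`` must be affinely pre-aligned to ``fixed``.  Returns the
    displacement field (world mm) on the fixed grid mapping fixed points
    into the moving volume; reorientation of tensors is deferred to
    resampling time (the incremental rotations during optimization are
    second-order).
    """
    settings = settings or RegistrationSettings()
    levels = settings.deform_levels if levels is None else levels
    f_data, cval, weights, f_signal = _metric_arrays(fixed, settings)
    m_data, _, _, _ = _metric_arrays(moving, settings)
    mask = _fixed_mask(f_signal, settings)
    grid = Grid.of(fixed)
    pts0 = grid_world_coords(grid)
    cost = _WarpCost(f_data, fixed.affine, mask, m_data, moving.affine, cval,
                     weights, settings.max_cost_voxels)

    u = np.zeros(grid.shape + (3,))
    voxel = np.sqrt((fixed.affine[:3, :3] ** 2).sum(axis=0))
    trace = [cost.residual_cost(cost.pts + u[cost.idx[:, 0], cost.idx[:, 1], cost.idx[:, 2]])]
    provenance = [("level", 0, trace[0])]

    shape = np.array(grid.shape)
    for level in range(1, levels + 1):
        b = 2 ** level
        block_vox = shape / b  # block extent in voxels (float)
        use_affine = b <= settings.deform_affine_max_blocks
        n_par = 12 if use_affine else 3
        G_grid = np.zeros((b, b, b, 9))
        r_grid = np.zeros((b, b, b, 3))
        centers_world = np.zeros((b, b, b, 3))
        est = np.zeros((b, b, b), dtype=bool)
        corner_cache: dict[tuple, list] = {}

        u_mask = u[cost.idx[:, 0], cost.idx[:, 1], cost.idx[:, 2]]
        blk_of_idx = np.minimum((cost.idx / block_vox).astype(int), b - 1)

        step_t = float(np.min(voxel)) * max(block_vox.min() / 8.0, 0.5)
        step_g = 0.05

        for bx in range(b):
            for by in range(b):
                for bz in range(b):
                    lo_vox = block_vox * (bx, by, bz)
                    c_vox = lo_vox + block_vox / 2.0 - 0.5
                    c_world = fixed.affine[:3, :3] @ c_vox + fixed.affine[:3, 3]
                    centers_world[bx, by, bz] = c_world
                    sel = np.all(blk_of_idx == (bx, by, bz), axis=1)
                    if sel.sum() < settings.deform_min_block_voxels:
                        continue
                    X = cost.pts[sel] + u_mask[sel]
                    Xrel = cost.pts[sel] - c_world
                    fsel = cost.fvals[sel]

                    # corners of this block in world coords and the tie
                    # targets from already-estimated neighbors
                    corners_vox = np.array(
                        [lo_vox + block_vox * d - 0.5 for d in np.ndindex(2, 2, 2)]
                    )
                    corners = corners_vox @ fixed.affine[:3, :3].T + fixed.affine[:3, 3]
                    ties = np.zeros((8, 3))
                    tie_n = np.zeros(8)
                    for ci, cw in enumerate(corners):
                        key = tuple(np.round(cw, 6))
                        for dG, dr, dc in corner_cache.get(key, []):
                            ties[ci] += dG @ (cw - dc) + dr
                            tie_n[ci] += 1.0
                    has_tie = tie_n > 0
                    ties[has_tie] /= tie_n[has_tie, None]
                    corners_rel = corners - c_world
                    lam = settings.deform_tie_weight
                    # penalty scale: squared block extent, so a displacement
                    # of a full block costs O(lam) against the O(1) data term
                    ext2 = float((block_vox * voxel).min()) ** 2

                    def local_cost(q):
                        t = q[:3]
                        G = q[3:].reshape(3, 3) if use_affine and q.size == 12 else np.zeros((3, 3))
                        delta = Xrel @ G.T + t
                        c = cost.residual_cost(X + delta, fsel=fsel)
                        dcorn = corners_rel @ G.T + t
                        pen = np.where(has_tie[:, None], dcorn - ties, dcorn)
                        c += lam * float(np.mean(pen * pen)) / ext2
                        return c

                    q0 = np.zeros(n_par)
                    steps = np.full(n_par, step_t)
                    if use_affine:
                        steps[3:] = step_g
                    q, _ = _pattern_search(
                        local_cost, q0, steps, halvings=2,
                        max_sweeps=settings.deform_sweeps,
                    )
                    t_q = q[:3]
                    G_q = q[3:].reshape(3, 3) if use_affine else np.zeros((3, 3))
                    G_grid[bx, by, bz] = G_q.ravel()
                    r_grid[bx, by, bz] = t_q - G_q @ c_world
                    est[bx, by, bz] = True
                    for cw in corners:
                        key = tuple(np.round(cw, 6))
                        corner_cache.setdefault(key, []).append((G_q, t_q, c_world))

        # blend block affines by a trilinear partition of unity over centers
        params = np.concatenate([G_grid, r_grid], axis=-1)
        # voxel -> block-grid coordinates (block centers at integer positions)
        g_coords = (np.indices(grid.shape, dtype=float).transpose(1, 2, 3, 0) + 0.5) / block_vox - 0.5
        interp = trilinear_sample(params, g_coords, cval=None)
        G_vox = interp[..., :9].reshape(grid.shape + (3, 3))
        r_vox = interp[..., 9:]
        delta = np.einsum("...ij,...j->...i", G_vox, pts0) + r_vox

        # accept the level increment only if it helps, keeping det(J) positive
        prev_cost = trace[-1]
        accepted = False
        for _ in range(8):
            u_cand = delta + _sample_field(u, pts0 + delta, grid)
            J = _jacobian_of_mapping(pts0 + u_cand, grid.affine)
            if np.linalg.det(J).min() <= settings.deform_min_jacobian:
                delta *= 0.5
                continue
            new_cost = cost.residual_cost(
                cost.pts + u_cand[cost.idx[:, 0], cost.idx[:, 1], cost.idx[:, 2]]
            )
            if new_cost <= prev_cost + 1e-12:
                u = u_cand
                trace.append(new_cost)
                accepted = True
                break
            delta *= 0.5
        if not accepted:
            trace.append(prev_cost)
        provenance.append(("level", level, trace[-1]))

    J = _jacobian_of_mapping(pts0 + u, grid.affine)
    if np.linalg.det(J).min() <= 0:
        raise RegistrationError("negative Jacobian after damping")
    return DisplacementField(u, grid.affine.copy(), provenance=provenance)


def _sample_field(u: np.ndarray, pts: np.ndarray, grid: Grid) -> np.ndarray:
    inv = np.linalg.inv(grid.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return trilinear_sample(u, vox, cval=None)
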