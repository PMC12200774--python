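"""Spatial transforms: rigid/affine matrices, dense displacement fields,
chains, composition, Jacobians, and tensor-aware resampling.

Conventions
-----------
All transforms are *pull-back* maps in world (RAS+ mm) coordinates: a
transform sends a point of the fixed/reference space to the corresponding
point of the moving/native space, which is the direction needed to resample
the moving image onto the reference grid.  A :class:`TransformChain` lists
the transforms in the order they were estimated (native-side first), so the
composed map evaluates the chain right-to-left.

Tensor resampling interpolates componentwise on matrix logarithms (PSD-safe)
and reorients each interpolated tensor by the finite-strain rotation — the
rotation polar factor of the local Jacobian of the inverse (moving-to-fixed)
map — which preserves eigenvalues, hence FA and MD, exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple, Sequence, Union

import numpy as np

from .interp import trilinear_sample
from .volumes import (
    LAMBDA_FLOOR,
    Mask,
    ScalarVolume,
    TensorVolume,
    exp_tensor_field,
    log_tensor_field,
)

__all__ = [
    "Grid",
    "AffineTransform",
    "DisplacementField",
    "TransformChain",
    "compose",
    "apply_transform",
    "jacobian_determinant_map",
    "grid_world_coords",
    "rotation_matrix",
    "polar_rotation",
]


class Grid(NamedTuple):
    """A voxel grid: shape plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    @classmethod
    def of(cls, obj) -> "Grid":
        if isinstance(obj, Grid):
            return obj
        return cls(tuple(obj.shape), np.asarray(obj.affine, dtype=float))


def grid_world_coords(grid: Grid) -> np.ndarray:
    """World coordinates of every voxel center, shape ``(*shape, 3)``."""
    shape, affine = Grid.of(grid)
    idx = np.indices(shape, dtype=float)  # (3, X, Y, Z)
    pts = np.einsum("ij,j...->...i", affine[:3, :3], idx) + affine[:3, 3]
    return pts


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation ``Rz(rz) @ Ry(ry) @ Rx(rx)`` (angles in radians)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def polar_rotation(mats: np.ndarray) -> np.ndarray:
    """Special-orthogonal polar factor of a batch of 3x3 matrices."""
    U, _, Vt = np.linalg.svd(mats)
    R = U @ Vt
    det = np.linalg.det(R)
    neg = det < 0
    if np.any(neg):
        U = U.copy()
        U[neg, :, 2] *= -1.0
        R = U @ Vt
    return R


@dataclasses.dataclass
class AffineTransform:
    """A 4x4 world-to-world affine map (fixed -> moving), 6 or 12 dof.

    The parameterization used by the registration engine is
    ``x' = L (x - c) + c + t`` with ``L = R(rx, ry, rz) @ U`` where ``U`` is
    upper triangular with positive diagonal ``exp(s)`` and shears
    ``(hxy, hxz, hyz)``; a 6-dof transform fixes ``U = I``.
    """

    matrix: np.ndarray
    dof: int = 12

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError(f"matrix must be 4x4, got {self.matrix.shape}")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-10):
            raise ValueError("last affine row must be (0, 0, 0, 1)")
        if self.dof not in (6, 12):
            raise ValueError(f"dof must be 6 or 12, got {self.dof}")
        if self.dof == 6:
            L = self.matrix[:3, :3]
            if not (np.allclose(L @ L.T, np.eye(3), atol=1e-6) and np.linalg.det(L) > 0):
                raise ValueError("6-dof transform requires a proper rotation linear part")

    # -- construction -----------------------------------------------------
    @classmethod
    def identity(cls, dof: int = 12) -> "AffineTransform":
        return cls(np.eye(4), dof=dof)

    @classmethod
    def from_params(
        cls, params: Sequence[float], center: Sequence[float] = (0.0, 0.0, 0.0)
    ) -> "AffineTransform":
        """Build from 6 (rigid) or 12 (affine) parameters about ``center``.

        Order: ``rx, ry, rz`` (rad), ``tx, ty, tz`` (mm), and for 12 dof
        additionally ``sx, sy, sz`` (log scales), ``hxy, hxz, hyz`` (shears).
        """
        p = np.asarray(params, dtype=float)
        if p.shape[0] not in (6, 12):
            raise ValueError(f"expected 6 or 12 parameters, got {p.shape[0]}")
        R = rotation_matrix(*p[:3])
        if p.shape[0] == 12:
            s = np.exp(p[6:9])
            hxy, hxz, hyz = p[9:12]
            U = np.array([[s[0], hxy, hxz], [0.0, s[1], hyz], [0.0, 0.0, s[2]]])
            L = R @ U
            dof = 12
        else:
            L = R
            dof = 6
        c = np.asarray(center, dtype=float)
        t = np.asarray(p[3:6], dtype=float)
        m = np.eye(4)
        m[:3, :3] = L
        m[:3, 3] = c + t - L @ c
        return cls(m, dof=dof)

    def to_params(self, center: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
        """Inverse of :meth:`from_params` (12 parameters; exact round trip)."""
        L = self.matrix[:3, :3]
        if np.linalg.det(L) <= 0:
            raise ValueError("cannot parameterize an orientation-reversing affine")
        Q, U = np.linalg.qr(L)
        d = np.sign(np.diag(U))
        Q = Q * d
        U = d[:, None] * U
        rx = np.arctan2(Q[2, 1], Q[2, 2])
        ry = -np.arcsin(np.clip(Q[2, 0], -1.0, 1.0))
        rz = np.arctan2(Q[1, 0], Q[0, 0])
        c = np.asarray(center, dtype=float)
        t = self.matrix[:3, 3] - c + L @ c
        return np.array(
            [rx, ry, rz, *t, *np.log(np.diag(U)), U[0, 1], U[0, 2], U[1, 2]]
        )

    # -- application ------------------------------------------------------
    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), dof=self.dof)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]


@dataclasses.dataclass
class DisplacementField:
    """Dense per-voxel displacement (world mm) on a reference grid.

    Maps a reference-grid world point ``x`` to ``x + u(x)``; between voxel
    centers ``u`` is interpolated trilinearly and extended by its edge
    values outside the grid.  ``provenance`` records the subdivision-level
    history of the hierarchical piecewise-affine estimation.
    """

    displacement: np.ndarray
    affine: np.ndarray
    provenance: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError(
                f"displacement must have shape (X, Y, Z, 3), got {self.displacement.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.affine)

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Displacement vectors at arbitrary world points (edge-extended)."""
        inv = np.linalg.inv(self.affine)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        return trilinear_sample(self.displacement, vox, cval=None)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.sample(pts)


Transform = Union[AffineTransform, DisplacementField]


@dataclasses.dataclass
class TransformChain:
    """Ordered transforms applied native -> template (estimation order).

    ``transform_points`` maps final-reference points back to native space by
    applying the elements right-to-left.
    """

    elements: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.elements:
            if not isinstance(e, (AffineTransform, DisplacementField)):
                raise TypeError(f"unsupported chain element {type(e)}")

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        for t in reversed(self.elements):
            pts = t.apply_points(pts)
        return pts

    def is_affine_only(self) -> bool:
        return all(isinstance(t, AffineTransform) for t in self.elements)

    def affine_matrix(self) -> np.ndarray:
        """Product matrix of an affine-only chain.

        phi_total(x) = phi_1(phi_2(...phi_k(x))), so matrices multiply
        left-to-right in list order.
        """
        if not self.is_affine_only():
            raise ValueError("chain contains non-affine elements")
        m = np.eye(4)
        for t in self.elements:
            m = m @ t.matrix
        return m


def _as_chain(t) -> TransformChain:
    if isinstance(t, TransformChain):
        return t
    if isinstance(t, (AffineTransform, DisplacementField)):
        return TransformChain([t])
    if isinstance(t, Iterable):
        return TransformChain(list(t))
    raise TypeError(f"cannot interpret {type(t)} as a transform chain")


def compose(chain, reference) -> DisplacementField:
    """Collapse a chain into one dense displacement field on ``reference``."""
    chain = _as_chain(chain)
    grid = Grid.of(reference)
    pts0 = grid_world_coords(grid)
    pts = chain.transform_points(pts0)
    return DisplacementField(pts - pts0, grid.affine, provenance=["composed"])


# ---------------------------------------------------------------------------
# Jacobians


def _jacobian_of_mapping(mapped: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Spatial Jacobian d(mapped)/d(world) of a mapping sampled on a grid.

    Central differences interior, one-sided at boundaries (via np.gradient
    along voxel axes), then chain-ruled through the grid affine.
    """
    grads = np.stack(np.gradient(mapped, axis=(0, 1, 2)), axis=-1)  # (...,3comp,3vox)
    inv_lin = np.linalg.inv(affine[:3, :3])
    return grads @ inv_lin


def jacobian_determinant_map(t, reference) -> ScalarVolume:
    """Per-voxel determinant of the spatial Jacobian of the composed map."""
    grid = Grid.of(reference)
    chain = _as_chain(t)
    if chain.is_affine_only():
        det = float(np.linalg.det(chain.affine_matrix()[:3, :3]))
        return ScalarVolume(np.full(grid.shape, det), grid.affine, unit="1")
    pts0 = grid_world_coords(grid)
    pts = chain.transform_points(pts0)
    J = _jacobian_of_mapping(pts, grid.affine)
    return ScalarVolume(np.linalg.det(J), grid.affine, unit="1")


# ---------------------------------------------------------------------------
# resampling


#: matrix-log components of the isotropic floor tensor, used as the
#: out-of-field fill value in log-space interpolation
_LOG_FLOOR = np.log(LAMBDA_FLOOR)
LOG_FLOOR_COMPONENTS = np.array([_LOG_FLOOR, 0.0, _LOG_FLOOR, 0.0, 0.0, _LOG_FLOOR])


def congruence6(t6: np.ndarray, R: np.ndarray) -> np.ndarray:
    """R D R^T applied to 6-component tensors; R is (3,3) or (...,3,3)."""
    from .volumes import matrices_to_tensors, tensors_to_matrices

    D = tensors_to_matrices(t6)
    if R.ndim == 2:
        out = np.einsum("ij,...jk,lk->...il", R, D, R)
    else:
        out = np.einsum("...ij,...jk,...lk->...il", R, D, R)
    return matrices_to_tensors(out)


def resample_log_tensors(
    log_field: np.ndarray, src_affine: np.ndarray, t, reference
) -> np.ndarray:
    """Warp a log-tensor field onto ``reference``, staying in log space.

    Interpolation is componentwise linear on the matrix logarithms and the
    finite-strain reorientation is applied directly to the log tensors
    (a rotation congruence commutes with the matrix logarithm).  Returns
    the warped log components, shape ``(*reference.shape, 6)``.
    """
    chain = _as_chain(t)
    grid = Grid.of(reference)
    pts0 = grid_world_coords(grid)
    pts = chain.transform_points(pts0)
    inv = np.linalg.inv(src_affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    sampled = trilinear_sample(log_field, vox, cval=LOG_FLOOR_COMPONENTS)

    if chain.is_affine_only():
        J = chain.affine_matrix()[:3, :3]
        if abs(np.linalg.det(J)) < 1e-12:
            raise ValueError("composed affine map is not invertible")
        R = polar_rotation(J[None])[0].T  # rotation of the forward map J^-1
    else:
        J = _jacobian_of_mapping(pts, grid.affine)
        det = np.linalg.det(J)
        if np.any(det == 0):
            bad = np.argwhere(det == 0)[0]
            raise ValueError(f"non-invertible local Jacobian at voxel {tuple(bad)}")
        Rj = polar_rotation(J.reshape(-1, 3, 3)).reshape(J.shape)
        R = np.swapaxes(Rj, -1, -2)  # rotation of J^-1 = transpose of rotation of J
    return congruence6(sampled, R)


def apply_transform(vol, t, reference=None):
    """Resample a volume through a transform chain onto ``reference``.

    Tensor volumes are interpolated componentwise on matrix logarithms and
    reoriented by the finite-strain rotation of the local composed-map
    Jacobian; out-of-field voxels become the isotropic floor tensor.
    Scalar volumes and masks are interpolated trilinearly (fill value 0).
    The native volume is interpolated exactly once regardless of chain
    length.
    """
    chain = _as_chain(t)
    grid = Grid.of(reference) if reference is not None else Grid.of(vol)

    if isinstance(vol, (ScalarVolume, Mask)):
        pts0 = grid_world_coords(grid)
        pts = chain.transform_points(pts0)
        inv = np.linalg.inv(vol.affine)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        if isinstance(vol, Mask):
            out = trilinear_sample(
                vol.values[..., None].astype(float), vox, cval=np.zeros(1)
            )[..., 0]
            return Mask(out >= 0.5, grid.affine.copy(), provenance=vol.provenance)
        out = trilinear_sample(vol.values[..., None], vox, cval=np.zeros(1))[..., 0]
        return ScalarVolume(out, grid.affine.copy(), unit=vol.unit)
    if not isinstance(vol, TensorVolume):
        raise TypeError(f"cannot resample {type(vol)}")

    log_field = log_tensor_field(vol.tensors)
    warped_log = resample_log_tensors(log_field, vol.affine, chain, grid)
    return TensorVolume(exp_tensor_field(warped_log), grid.affine.copy(), "world")
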