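"""Volumes of diffusion tensors and scalars, and tensor-derived maps.

A diffusion tensor image stores one symmetric positive-definite 3x3 tensor
per voxel (units mm^2/s).  Tensors are kept as 6 unique components in
NIfTI lower-triangular order ``(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)`` and are
expressed in the world (RAS+) frame; the voxel grid is related to world
coordinates by an invertible 4x4 affine with 0-based voxel indices.

Scalar maps derived from the tensor field — fractional anisotropy (FA,
dimensionless in [0, 1]) and mean diffusivity (MD, mm^2/s) — are the
substrate of the similarity and evaluation computations.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LAMBDA_FLOOR",
    "FROBENIUS_WEIGHTS",
    "TensorVolume",
    "ScalarVolume",
    "Mask",
    "FormatError",
    "read_tensor_volume",
    "write_tensor_volume",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_mask",
    "write_mask",
    "compute_fa",
    "compute_md",
    "principal_eigenvector",
    "make_fa_mask",
    "tensors_to_matrices",
    "matrices_to_tensors",
    "eigh_field",
    "clamp_eigenvalues",
    "log_tensor_field",
    "exp_tensor_field",
    "fa_from_eigenvalues",
]

#: Eigenvalues below this floor (mm^2/s) are raised to it before any
#: log-space or FA computation, so matrix logarithms stay defined even for
#: tensors made indefinite by noise or interpolation.
LAMBDA_FLOOR = 1e-12

#: Squared-Frobenius weights of the 6 unique components (off-diagonals twice).
FROBENIUS_WEIGHTS = np.array([1.0, 2.0, 1.0, 2.0, 2.0, 1.0])

# row/col indices of the 6 components within the symmetric 3x3 matrix
_ROW = np.array([0, 0, 1, 0, 1, 2])
_COL = np.array([0, 1, 1, 2, 2, 2])

# permutation mapping upper-triangular component order
# (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) to canonical lower-triangular order
# (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); it is its own inverse.
_UPPER_TO_LOWER = np.array([0, 1, 3, 2, 4, 5])


class FormatError(ValueError):
    """A file or array does not conform to the expected tensor-image layout."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise FormatError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise FormatError("affine is not invertible")
    return affine


@dataclasses.dataclass
class TensorVolume:
    """A 3-D grid of symmetric 3x3 diffusion tensors plus a world affine.

    ``tensors`` has shape ``(*shape, 6)`` in canonical lower-triangular
    component order; symmetry is guaranteed by the storage itself.
    ``tensor_frame`` records the frame the tensors are expressed in
    (``"world"`` by default; all internal math assumes world-frame tensors).
    """

    tensors: np.ndarray
    affine: np.ndarray
    tensor_frame: str = "world"

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 4 or self.tensors.shape[-1] != 6:
            raise FormatError(
                f"tensors must have shape (X, Y, Z, 6), got {self.tensors.shape}"
            )
        self.affine = _check_affine(self.affine)
        if self.tensor_frame not in ("world", "voxel"):
            raise FormatError(f"unknown tensor_frame {self.tensor_frame!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy(self) -> "TensorVolume":
        return TensorVolume(self.tensors.copy(), self.affine.copy(), self.tensor_frame)


@dataclasses.dataclass
class ScalarVolume:
    """A 3-D scalar map (FA, MD, Jacobian determinant, ...) with affine."""

    values: np.ndarray
    affine: np.ndarray
    unit: str = "1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(f"values must be 3-D, got shape {self.values.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.values.copy(), self.affine.copy(), self.unit)


@dataclasses.dataclass
class Mask:
    """A boolean voxel mask with a provenance note (e.g. the FA threshold)."""

    values: np.ndarray
    affine: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise FormatError(f"mask must be 3-D, got shape {self.values.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# tensor component algebra


def tensors_to_matrices(t6: np.ndarray) -> np.ndarray:
    """Expand ``(..., 6)`` unique components into full ``(..., 3, 3)`` matrices."""
    t6 = np.asarray(t6, dtype=float)
    out = np.empty(t6.shape[:-1] + (3, 3), dtype=float)
    out[..., _ROW, _COL] = t6
    out[..., _COL, _ROW] = t6
    return out


def matrices_to_tensors(m: np.ndarray) -> np.ndarray:
    """Collapse symmetric ``(..., 3, 3)`` matrices into their 6 components."""
    m = np.asarray(m, dtype=float)
    return m[..., _ROW, _COL]


def eigh_field(t6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose a field of symmetric tensors.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvalues ascending and
    ``eigenvectors[..., :, k]`` the unit vector of the k-th eigenvalue.
    """
    return np.linalg.eigh(tensors_to_matrices(t6))


def _rebuild(vals: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    return matrices_to_tensors(
        np.einsum("...ik,...k,...jk->...ij", vecs, vals, vecs)
    )


def clamp_eigenvalues(t6: np.ndarray, floor: float = LAMBDA_FLOOR) -> np.ndarray:
    """Raise eigenvalues below ``floor`` to it, preserving eigenvectors."""
    vals, vecs = eigh_field(t6)
    if vals.min() >= floor:
        return np.asarray(t6, dtype=float)
    return _rebuild(np.maximum(vals, floor), vecs)


def log_tensor_field(t6: np.ndarray, floor: float = LAMBDA_FLOOR) -> np.ndarray:
    """Matrix logarithm per voxel (eigenvalues clamped to ``floor`` first)."""
    vals, vecs = eigh_field(t6)
    return _rebuild(np.log(np.maximum(vals, floor)), vecs)


def exp_tensor_field(l6: np.ndarray) -> np.ndarray:
    """Matrix exponential per voxel; inverse of :func:`log_tensor_field`."""
    vals, vecs = eigh_field(l6)
    return _rebuild(np.exp(vals), vecs)


def fa_from_eigenvalues(vals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||; 0 where the
    tensor is (numerically) zero."""
    vals = np.asarray(vals, dtype=float)
    mean = vals.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(vals - mean)).sum(axis=-1))
    den = np.sqrt(np.square(vals).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den <= 3e-12, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)


# ---------------------------------------------------------------------------
# derived maps


def compute_fa(vol: TensorVolume, mask: Mask | None = None) -> ScalarVolume:
    """Fractional anisotropy map of a tensor volume.

    Eigenvalues are clamped to :data:`LAMBDA_FLOOR` first; an all-zero
    tensor therefore becomes isotropic and maps to FA = 0.  Voxels outside
    ``mask`` (if given) are set to 0.
    """
    vals, _ = eigh_field(vol.tensors)
    fa = fa_from_eigenvalues(np.maximum(vals, LAMBDA_FLOOR))
    if mask is not None:
        _check_same_grid(mask.shape, vol.shape, "mask")
        fa = np.where(mask.values, fa, 0.0)
    return ScalarVolume(fa, vol.affine.copy(), unit="1")


def compute_md(vol: TensorVolume, mask: Mask | None = None) -> ScalarVolume:
    """Mean diffusivity (trace / 3) map, in mm^2/s."""
    md = (vol.tensors[..., 0] + vol.tensors[..., 2] + vol.tensors[..., 5]) / 3.0
    if mask is not None:
        _check_same_grid(mask.shape, vol.shape, "mask")
        md = np.where(mask.values, md, 0.0)
    return ScalarVolume(md, vol.affine.copy(), unit="mm^2/s")


def principal_eigenvector(
    vol: TensorVolume, mask: Mask | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel unit eigenvector of the largest eigenvalue.

    Returns ``(vectors, degenerate)`` where ``vectors`` has shape
    ``(*shape, 3)`` and ``degenerate`` flags voxels whose two leading
    eigenvalues are equal to within ``1e-12 * lambda_1`` (the returned
    vector is still valid there, but its direction is not unique).  The
    sign convention makes the first nonzero component positive, so the
    output is deterministic; downstream dyadic statistics are sign-blind.
    """
    vals, vecs = eigh_field(vol.tensors)
    e1 = vecs[..., :, 2]
    lam1, lam2 = vals[..., 2], vals[..., 1]
    degenerate = (lam1 - lam2) < 1e-12 * np.maximum(np.abs(lam1), LAMBDA_FLOOR)
    # sign convention: first nonzero component positive
    sign = np.where(e1[..., 0] != 0, np.sign(e1[..., 0]), 0.0)
    sign = np.where(sign == 0, np.where(e1[..., 1] != 0, np.sign(e1[..., 1]), 0.0), sign)
    sign = np.where(sign == 0, np.where(e1[..., 2] != 0, np.sign(e1[..., 2]), 1.0), sign)
    e1 = e1 * sign[..., None]
    if mask is not None:
        _check_same_grid(mask.shape, vol.shape, "mask")
        e1 = np.where(mask.values[..., None], e1, 0.0)
        degenerate = degenerate & mask.values
    return e1, degenerate


def make_fa_mask(fa: ScalarVolume, threshold: float) -> Mask:
    """Strict-inequality threshold mask ``FA > threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    values = fa.values > threshold
    if not values.any():
        raise ValueError(f"FA > {threshold} selects no voxels; evaluation undefined")
    return Mask(values, fa.affine.copy(), provenance=f"FA>{threshold:g}")


def _check_same_grid(a, b, what: str) -> None:
    if tuple(a) != tuple(b):
        raise FormatError(f"{what} shape {tuple(a)} does not match volume {tuple(b)}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_tensor_volume(path: str | Path, component_order: str = "lower") -> TensorVolume:
    """Read a 6-component symmetric-tensor NIfTI image.

    Accepts data laid out as ``(X, Y, Z, 6)`` or the NIfTI vector-intent
    layout ``(X, Y, Z, 1, 6)``.  ``component_order`` is ``"lower"`` for the
    canonical (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) ordering or ``"upper"`` for
    DTI-TK-style (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) files.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 6:
        raise FormatError(
            f"{path}: expected 6 tensor components per voxel, got shape {data.shape}"
        )
    if component_order == "upper":
        data = data[..., _UPPER_TO_LOWER]
    elif component_order != "lower":
        raise ValueError(f"component_order must be 'lower' or 'upper', got {component_order!r}")
    return TensorVolume(data, img.affine)


def write_tensor_volume(vol: TensorVolume, path: str | Path) -> None:
    """Write a tensor volume as a 5-D NIfTI with symmetric-matrix intent."""
    data = vol.tensors[:, :, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float64), vol.affine)
    img.header.set_intent("symmetric matrix", (3,))
    nib.save(img, str(path))


def read_scalar_volume(path: str | Path, unit: str = "1") -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D scalar image, got shape {data.shape}")
    return ScalarVolume(data, img.affine, unit=unit)


def write_scalar_volume(vol: ScalarVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), vol.affine), str(path))


def read_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask image, got shape {data.shape}")
    return Mask(data > 0, img.affine, provenance=str(path))


def write_mask(mask: Mask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine), str(path))
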