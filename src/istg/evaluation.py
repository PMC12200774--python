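"""Registration-quality metrics and method comparisons.

Four metrics, all computed over an FA > 0.25 evaluation mask on the
average aligned FA map unless stated otherwise:

* dyadic coherence kappa — per voxel, form the mean dyadic tensor
  <e1 e1^T> of the aligned principal eigenvectors across scans; with its
  eigenvalues b1 >= b2 >= b3, kappa = 1 - sqrt((b2 + b3) / (2 b1)).
  0 for random orientations, 1 for perfect alignment; sign-blind.
* sigma_FA — the voxelwise coefficient of variation of FA across scans
  (sample SD over mean); lower is better.
* NMI — normalized mutual information between each aligned FA map and the
  cohort-average FA map, from a joint histogram over the mask.  The
  symmetric-uncertainty form 2 I(A;B) / (H(A) + H(B)) is the default (it
  spans [0, 1] and grows with similarity); the joint/marginal-sum entropy
  ratio H(A,B) / (H(A) + H(B)) is available via ``variant="entropy_ratio"``.
* Jacobian determinant summaries — voxelwise mean/SD maps across scans and
  per-scan |mean Jacobian - 1| (deformation burden; smaller is better).

Method pairs are compared by pooled-variance two-sample two-tailed
t-tests with Cohen's d, a seeded bootstrap 95% CI on d, and a Bonferroni
correction for the three method pairs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .volumes import Mask, ScalarVolume

__all__ = [
    "EvaluationReport",
    "ComparisonResult",
    "dyadic_coherence",
    "sigma_fa",
    "nmi",
    "jacobian_summary",
    "ecdf",
    "compare_methods",
]


@dataclasses.dataclass
class EvaluationReport:
    """Per-method evaluation: metric maps, per-scan values, and the mask."""

    method_label: str
    mask: Mask
    sigma_fa_map: ScalarVolume
    nmi_values: dict
    jacobian_mean_map: ScalarVolume | None = None
    jacobian_sd_map: ScalarVolume | None = None
    jacobian_abs_dev: dict = dataclasses.field(default_factory=dict)
    kappa_map: ScalarVolume | None = None

    def save(self, outdir, prefix: str = "") -> None:
        """Export maps as NIfTI and per-scan values / ECDF points as CSV."""
        import pandas as pd

        from .volumes import write_mask, write_scalar_volume

        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = prefix or self.method_label
        write_scalar_volume(self.sigma_fa_map, outdir / f"{tag}_sigma_fa.nii.gz")
        write_mask(self.mask, outdir / f"{tag}_mask.nii.gz")
        if self.kappa_map is not None:
            write_scalar_volume(self.kappa_map, outdir / f"{tag}_kappa.nii.gz")
        if self.jacobian_mean_map is not None:
            write_scalar_volume(self.jacobian_mean_map, outdir / f"{tag}_jacobian_mean.nii.gz")
            write_scalar_volume(self.jacobian_sd_map, outdir / f"{tag}_jacobian_sd.nii.gz")
        rows = {
            "id": list(self.nmi_values),
            "nmi": list(self.nmi_values.values()),
        }
        if self.jacobian_abs_dev:
            rows["jacobian_abs_dev"] = [
                self.jacobian_abs_dev[i] for i in self.nmi_values
            ]
        pd.DataFrame(rows).to_csv(outdir / f"{tag}_per_scan.csv", index=False)
        m = self.mask.values
        curves = {"sigma_fa": ecdf(self.sigma_fa_map.values[m])}
        if self.kappa_map is not None:
            curves["kappa"] = ecdf(self.kappa_map.values[m])
        for name, pts in curves.items():
            pd.DataFrame(pts, columns=["value", "cdf"]).to_csv(
                outdir / f"{tag}_ecdf_{name}.csv", index=False
            )

    def summary(self) -> dict:
        m = self.mask.values
        out = {
            "method": self.method_label,
            "mean_sigma_fa": float(self.sigma_fa_map.values[m].mean()),
            "mean_nmi": float(np.mean(list(self.nmi_values.values()))),
        }
        if self.kappa_map is not None:
            kv = self.kappa_map.values[m]
            out["median_kappa"] = float(np.median(kv))
            out["mean_kappa"] = float(kv.mean())
        if self.jacobian_abs_dev:
            out["mean_jacobian_abs_dev"] = float(
                np.mean(list(self.jacobian_abs_dev.values()))
            )
        return out


@dataclasses.dataclass
class ComparisonResult:
    """Two-sample comparison of a per-scan metric between two methods."""

    t_statistic: float
    p_value: float
    p_bonferroni: float
    cohens_d: float
    d_ci: tuple
    n_per_group: tuple


def dyadic_coherence(
    e1_fields: Sequence[np.ndarray], mask: Mask
) -> ScalarVolume:
    """Dyadic coherence map of aligned principal-eigenvector fields.

    Each field has shape ``(*grid, 3)``.  Voxels where the mean dyadic is
    all-zero (every scan contributed a zero vector) are removed from the
    returned map's support (value 0) — kappa is undefined there.
    """
    if len(e1_fields) < 2:
        raise ValueError("need at least 2 eigenvector fields")
    shape = e1_fields[0].shape
    for f in e1_fields:
        if f.shape != shape:
            raise ValueError("eigenvector fields must share a grid")
    m = mask.values
    vecs = np.stack([f[m] for f in e1_fields])  # (S, N, 3)
    dyad = np.einsum("sni,snj->nij", vecs, vecs) / len(e1_fields)
    beta = np.linalg.eigvalsh(dyad)  # ascending: b3, b2, b1
    b1 = beta[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = 1.0 - np.sqrt((beta[:, 1] + beta[:, 0]) / (2.0 * b1))
    kappa = np.where(b1 <= 1e-12, 0.0, np.clip(kappa, 0.0, 1.0))
    out = np.zeros(shape[:3])
    out[m] = kappa
    return ScalarVolume(out, mask.affine.copy(), unit="1")


def sigma_fa(fa_maps: Sequence[ScalarVolume], mask: Mask) -> ScalarVolume:
    """Voxelwise normalized SD (sample SD / mean) of FA across scans.

    Voxels whose across-scan mean FA is <= 1e-6 are removed from the map's
    support (the ratio is undefined there).
    """
    if len(fa_maps) < 2:
        raise ValueError("need at least 2 FA maps")
    shape = fa_maps[0].shape
    for f in fa_maps:
        if f.shape != shape:
            raise ValueError("FA maps must share a grid")
    m = mask.values
    vals = np.stack([f.values[m] for f in fa_maps])  # (S, N)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv = np.where(mean <= 1e-6, 0.0, cv)
    out = np.zeros(shape)
    out[m] = cv
    return ScalarVolume(out, mask.affine.copy(), unit="1")


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(
    image: ScalarVolume,
    reference: ScalarVolume,
    mask: Mask,
    bins: int = 64,
    variant: str = "symmetric",
) -> float:
    """Normalized mutual information between two scalar maps over a mask.

    ``variant="symmetric"`` (default) returns 2 I(A;B) / (H(A) + H(B)),
    in [0, 1] and increasing with similarity; ``variant="entropy_ratio"``
    returns the literal joint-to-marginal entropy ratio
    H(A,B) / (H(A) + H(B)), which spans [0.5, 1] and decreases with
    similarity.  Histograms use ``bins`` equal-width bins spanning each
    image's masked range.
    """
    if image.shape != reference.shape:
        raise ValueError("images must share a grid")
    a = image.values[mask.values]
    b = reference.values[mask.values]
    if a.size == 0:
        raise ValueError("empty evaluation mask")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant image has zero marginal entropy; NMI undefined")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    h_a = _entropy(p.sum(axis=1))
    h_b = _entropy(p.sum(axis=0))
    h_ab = _entropy(p.ravel())
    if variant == "symmetric":
        mi = h_a + h_b - h_ab
        return float(np.clip(2.0 * mi / (h_a + h_b), 0.0, 1.0))
    if variant == "entropy_ratio":
        return float(h_ab / (h_a + h_b))
    raise ValueError(f"unknown NMI variant {variant!r}")


def jacobian_summary(
    jac_maps: Sequence[ScalarVolume],
    mask: Mask,
    ids: Sequence | None = None,
) -> tuple[ScalarVolume, ScalarVolume, dict]:
    """Voxelwise mean/SD maps of Jacobian determinants and per-scan
    |mean-over-mask - 1| deviations."""
    if len(jac_maps) < 1:
        raise ValueError("need at least 1 Jacobian map")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(jac_maps))]
    m = mask.values
    vals = np.stack([j.values for j in jac_maps])
    mean_map = ScalarVolume(vals.mean(axis=0), mask.affine.copy(), unit="1")
    sd = vals.std(axis=0, ddof=1) if len(jac_maps) > 1 else np.zeros_like(vals[0])
    sd_map = ScalarVolume(sd, mask.affine.copy(), unit="1")
    devs = {sid: float(abs(j.values[m].mean() - 1.0)) for sid, j in zip(ids, jac_maps)}
    return mean_map, sd_map, devs


def ecdf(values: Sequence[float]) -> np.ndarray:
    """Empirical CDF as sorted (value, fraction <= value) pairs."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty value list")
    frac = np.arange(1, v.size + 1) / v.size
    return np.column_stack([v, frac])


def compare_methods(
    a: Sequence[float],
    b: Sequence[float],
    seed: int = 0,
    n_boot: int = 10_000,
    n_comparisons: int = 3,
) -> ComparisonResult:
    """Pooled-variance two-sample two-tailed t-test with Cohen's d.

    The 95% CI on d comes from a seeded nonparametric bootstrap
    (``n_boot`` resamples); the Bonferroni-adjusted p multiplies by
    ``n_comparisons`` (the three method pairs) and caps at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")

    def cohens_d(x, y):
        nx, ny = x.size, y.size
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        if sp2 <= 0:
            raise ValueError("zero pooled variance; effect size undefined")
        return (x.mean() - y.mean()) / np.sqrt(sp2)

    d = float(cohens_d(a, b))
    t_res = stats.ttest_ind(a, b, equal_var=True)
    rng = np.random.default_rng(seed)
    na, nb = a.size, b.size
    xa = a[rng.integers(0, na, (n_boot, na))]
    xb = b[rng.integers(0, nb, (n_boot, nb))]
    sp2 = ((na - 1) * xa.var(axis=1, ddof=1) + (nb - 1) * xb.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(sp2)
    boots = np.where(sp2 > 0, boots, d)  # degenerate resamples fall back to d
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, d), max(hi, d)
    return ComparisonResult(
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        p_bonferroni=float(min(1.0, t_res.pvalue * n_comparisons)),
        cohens_d=d,
        d_ci=(float(lo), float(hi)),
        n_per_group=(int(a.size), int(b.size)),
    )
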