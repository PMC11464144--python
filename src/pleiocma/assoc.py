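"""Family-aware genome scans.

Each trait is analysed with a linear mixed model

    y = X b + g + e,   g ~ N(0, sg^2 * A),   e ~ N(0, se^2 * I),

where ``A = 2 * phi`` is the numerator relationship matrix from the
pedigree kinship and ``X`` carries the covariates (age, age^2, sex, field
center, PC1).  Variance components are estimated once by REML under the
null (no variant), using a single eigendecomposition of A and a
one-dimensional profile over the variance ratio; per-variant tests then fix
the variance components at the null estimates and perform generalized
least-squares Wald tests of the dosage effect (the EMMAX-style
approximation).  Two-sided p-values use the normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import KinshipMatrix

__all__ = [
    "SCAN_COLUMNS",
    "LmmFit",
    "prepare_trait",
    "build_design",
    "mac_filter",
    "lmm_reml_fit",
    "lmm_association",
    "genomic_lambda",
]

SCAN_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P", "MAC", "MAF", "N"]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


def prepare_trait(values, covariates: pd.DataFrame, *, ids=None) -> np.ndarray:
    """Natural-log transform a positive trait and validate its covariates.

    The covariates are not residualized out here; they are carried forward
    as fixed effects into the mixed-model design (see :func:`build_design`).

    Raises
    ------
    ValueError
        Nonpositive trait values or missing covariate cells, naming the
        offending individual; an ``age2`` column inconsistent with
        ``age**2``.
    """
    values = np.asarray(values, dtype=float)
    labels = list(ids) if ids is not None else list(range(len(values)))
    bad = np.flatnonzero(~(values > 0))
    if bad.size:
        raise ValueError(f"nonpositive trait value for individual {labels[bad[0]]!r}")
    if len(covariates) != len(values):
        raise ValueError("covariate table length does not match trait")
    null_cells = covariates.isna()
    if null_cells.any().any():
        i = int(np.flatnonzero(null_cells.any(axis=1))[0])
        col = null_cells.columns[null_cells.iloc[i].to_numpy()][0]
        raise ValueError(f"missing covariate {col!r} for individual {labels[i]!r}")
    if "age" in covariates and "age2" in covariates:
        if not np.allclose(covariates["age2"], covariates["age"] ** 2):
            raise ValueError("age2 column is not age squared")
    return np.log(values)


def build_design(covariates: pd.DataFrame) -> np.ndarray:
    """Fixed-effects design: intercept, age, age^2, sex, centers, PC1.

    Categorical columns (``sex``, ``center``) are dummy-coded dropping one
    level; numeric columns are used as-is and ``age2`` is added when absent.
    """
    cov = covariates.copy()
    if "age" in cov and "age2" not in cov:
        cov["age2"] = cov["age"] ** 2
    parts = [np.ones((len(cov), 1))]
    for col in cov.columns:
        x = cov[col]
        if x.dtype.kind in "OUSb" or isinstance(x.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(x, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
        else:
            parts.append(x.to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


def mac_filter(genotypes, threshold: int = 20) -> np.ndarray:
    """Indices of variants to keep: MAC >= threshold, single-base alleles.

    Variants whose minor allele count is below ``threshold`` are excluded,
    as are insertions/deletions/structural variants (any allele string
    longer than one base).
    """
    mac = genotypes.mac()
    keep = mac >= threshold
    snv = np.array([len(r) == 1 and len(a) == 1 for r, a in zip(genotypes.ref, genotypes.alt)])
    return np.flatnonzero(keep & snv)


@dataclass
class LmmFit:
    """Null-model REML fit on the eigenbasis of A = 2*phi."""

    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    reml_loglik: float
    eigenvalues: np.ndarray
    rotation: np.ndarray  # U such that A = U diag(w) U'

    @property
    def delta(self) -> float:
        """Variance ratio se^2 / sg^2 (inf when sg^2 = 0)."""
        return np.inf if self.sigma2_g == 0 else self.sigma2_e / self.sigma2_g

    @property
    def heritability(self) -> float:
        """sg^2 / (sg^2 + se^2) on the A-scale."""
        tot = self.sigma2_g + self.sigma2_e
        return 0.0 if tot == 0 else self.sigma2_g / tot


def _reml_neg_loglik(log_delta: float, w: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    delta = np.exp(log_delta)
    n, p = Xr.shape
    v = w + delta
    Wy = yr / v
    XtWX = Xr.T @ (Xr / v[:, None])
    XtWy = Xr.T @ Wy
    beta = np.linalg.solve(XtWX, XtWy)
    rss = float(yr @ Wy - XtWy @ beta)
    df = n - p
    sg2 = rss / df
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    ll = -0.5 * (df * np.log(sg2) + np.sum(np.log(v)) + logdet_XtWX + df)
    return -ll


def lmm_reml_fit(y: np.ndarray, X: np.ndarray, kinship: KinshipMatrix) -> LmmFit:
    """REML variance components by 1-D profile over the ratio delta.

    A single eigendecomposition of ``A = 2*phi`` rotates the problem to
    independent observations; the fixed effects and the genetic variance
    are profiled out analytically, leaving a scalar optimization over
    ``log delta`` (grid scan + local refinement).  Deterministic.

    Raises
    ------
    ValueError
        If A has eigenvalues below -1e-8 (not positive semidefinite beyond
        numerical tolerance).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0] or kinship.n != y.shape[0]:
        raise ValueError("dimension mismatch between y, X, and kinship")
    A = kinship.relationship()
    w, U = np.linalg.eigh(A)
    if w.min() < -1e-8:
        raise ValueError(f"kinship relationship matrix not PSD (min eigenvalue {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    grid = np.linspace(-10.0, 10.0, 81)
    vals = [_reml_neg_loglik(g, w, yr, Xr) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(w, yr, Xr), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    delta = np.exp(log_delta)
    n, p = Xr.shape
    v = w + delta
    XtWX = Xr.T @ (Xr / v[:, None])
    XtWy = Xr.T @ (yr / v)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = float(yr @ (yr / v) - XtWy @ beta)
    sg2 = rss / (n - p)
    se2 = sg2 * delta
    # Collapse to a pure-noise model when the ratio hits the upper boundary.
    if log_delta >= 10.0 - 1e-6:
        sg2 = 0.0
    return LmmFit(
        sigma2_g=sg2,
        sigma2_e=se2,
        beta=beta,
        reml_loglik=-float(res.fun),
        eigenvalues=w,
        rotation=U,
    )


def lmm_association(
    fit: LmmFit,
    genotypes,
    y: np.ndarray,
    X: np.ndarray,
    *,
    variant_index: np.ndarray | None = None,
    scan_id: str = "trait",
) -> pd.DataFrame:
    """Per-variant Wald tests with variance components fixed at the null fit.

    Returns a scan table with columns :data:`SCAN_COLUMNS`.  Variants whose
    dosage is constant in the analysed samples are skipped (not rows in the
    output).  Effect allele is the alternate allele.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    idx = np.arange(genotypes.m) if variant_index is None else np.asarray(variant_index)
    G = genotypes.dosages[:, idx].astype(float)

    U, w = fit.rotation, fit.eigenvalues
    delta = fit.delta
    if np.isinf(delta):
        v = np.ones_like(w)
        sigma2 = fit.sigma2_e
    else:
        v = w + delta
        sigma2 = fit.sigma2_g
    yr = U.T @ y
    Xr = U.T @ X
    Gr = U.T @ G
    Wy = yr / v
    WX = Xr / v[:, None]
    XtWX_inv = np.linalg.inv(Xr.T @ WX)
    # GLS-residualize y and every dosage column against X
    y_perp = yr - Xr @ (XtWX_inv @ (WX.T @ yr))
    G_perp = Gr - Xr @ (XtWX_inv @ (WX.T @ Gr))
    gWg = np.einsum("ij,ij->j", G_perp, G_perp / v[:, None])
    gWy = G_perp.T @ (y_perp / v)

    nonconst = G.std(axis=0) > 0
    ok = nonconst & (gWg > 1e-12)
    beta = np.full(idx.shape, np.nan)
    se = np.full(idx.shape, np.nan)
    beta[ok] = gWy[ok] / gWg[ok]
    se[ok] = np.sqrt(sigma2 / gWg[ok])
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    mac = genotypes.mac()[idx]
    maf = genotypes.maf()[idx]
    table = pd.DataFrame(
        {
            "SNP": np.asarray(genotypes.snp, dtype=object)[idx],
            "CHR": genotypes.chrom[idx],
            "POS": genotypes.pos[idx],
            "EA": np.asarray(genotypes.alt, dtype=object)[idx],
            "OA": np.asarray(genotypes.ref, dtype=object)[idx],
            "BETA": beta,
            "SE": se,
            "P": p,
            "MAC": mac,
            "MAF": maf,
            "N": genotypes.n,
        }
    )
    table.attrs["scan_id"] = scan_id
    table.attrs["test"] = "wald-normal, null-model variance components"
    return table[ok].reset_index(drop=True)


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor.

    lambda = median(qchisq_1(1 - p)) / median(chi2_1); 1.0 indicates a
    calibrated scan, values above ~1.1 suggest inflation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)
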