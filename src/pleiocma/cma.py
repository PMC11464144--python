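"""Correlated meta-analysis of dependent association scans.

Per-trait genome (or transcriptome) scans computed on overlapping samples
of correlated traits are not independent: combining their p-values with
Fisher's method as if they were inflates type-1 error.  The correlated
meta-analysis implemented here

1. estimates the between-scan null correlation empirically, by
   median-dichotomizing each scan's p-values (after trimming genuine
   signal) and recovering the latent-normal correlation of the resulting
   2x2 concordance table by maximum likelihood — on the folded scale for
   two-sided scans (:func:`folded_normal_correlation`), or as a plain
   tetrachoric for signed statistics; and
2. combines each marker's p-values with Fisher's statistic
   ``T = sum(-2 ln p_i)`` referred to Brown's scaled chi-square null, whose
   variance uses the Kost-McDermott cubic approximation
   ``cov_ij = 3.263 r + 0.710 r^2 + 0.027 r^3``.

A correlated Stouffer (weighted-Z) combiner is provided for sensitivity
analysis.  For each marker every trait subset whose members all reach the
eligibility cut (p < 0.01) is combined; the subset with the smallest
combined p-value is the marker's headline record.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ScanCorrelation",
    "CmaRecord",
    "dichotomize_scans",
    "tetrachoric",
    "tetrachoric_cosine",
    "folded_normal_correlation",
    "scan_correlation",
    "kost_covariance",
    "brown_combine",
    "brown_combine_many",
    "stouffer_combine",
    "cma_scan",
]

RHO_CAP = 0.999


@dataclass
class ScanCorrelation:
    """Between-scan null correlation matrix with its evidence."""

    scan_ids: list[str]
    rho: np.ndarray
    counts: dict[tuple[str, str], tuple[int, int, int, int]]
    estimator: str = "ml-tetrachoric"

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        k = len(self.scan_ids)
        if r.shape != (k, k) or not np.allclose(r, r.T):
            raise ValueError("rho must be a symmetric k x k matrix")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("rho diagonal must be 1")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.rho = r

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.scan_ids.index(s) for s in ids]
        return self.rho[np.ix_(idx, idx)]


@dataclass
class CmaRecord:
    """One combined test: marker, trait subset, statistic and p-value."""

    marker: str
    subset: tuple[str, ...]
    p_values: tuple[float, ...]
    statistic: float
    scale: float  # Brown's c (or sqrt(1'R1) for Stouffer)
    dof: float  # Brown's f (nan for Stouffer)
    p_cma: float
    combiner: str = "brown"


def dichotomize_scans(
    p1: np.ndarray,
    p2: np.ndarray,
    *,
    cut: float = 0.5,
    trim: float = 1e-4,
) -> tuple[int, int, int, int]:
    """Cross-classify two aligned p-value vectors at ``cut``.

    Markers significant in either scan (p < ``trim``) are removed first so
    the concordance table reflects the null correlation rather than shared
    signal.  Returns counts ``(a, b, c, d)``: a = below cut in both,
    b = below in scan 1 only, c = below in scan 2 only, d = neither.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.size == 0:
        raise ValueError("scans share no markers")
    keep = (p1 >= trim) & (p2 >= trim) if trim > 0 else np.ones(p1.shape, bool)
    x = p1[keep] < cut
    y = p2[keep] < cut
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return a, b, c, d


def folded_normal_correlation(a: int, b: int, c: int, d: int) -> float:
    """|z|-scale correlation from a 2x2 table of two-sided p-value indicators.

    Two-sided p-values depend on the test statistic only through ``|z|``, so
    the concordance table of ``I(p < cut)`` indicators is generated by the
    *folded* bivariate normal: ``P(|z1| > c1, |z2| > c2; rho)``, which is
    symmetric in the sign of rho.  This inverts that orthant probability by
    maximum likelihood (margins fixed at the sample proportions), returning
    the magnitude of the latent z-score correlation in [0, 0.999].  A plain
    tetrachoric fit to the same table assumes a signed latent normal and
    systematically underestimates the dependence of the chi-square
    statistics.
    """
    counts = np.array([a, b, c, d])
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = counts.sum()
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate margin in 2x2 table")
    q1 = (a + b) / n  # fraction with p < cut in scan 1
    q2 = (a + c) / n
    c1 = stats.norm.isf(q1 / 2.0)  # |z| exceedance threshold
    c2 = stats.norm.isf(q2 / 2.0)
    target = a / n

    def upper(h: float, k: float, r: float) -> float:
        return 1.0 - stats.norm.cdf(h) - stats.norm.cdf(k) + _bvn_cdf(h, k, r)

    def f(r: float) -> float:
        return 2.0 * (upper(c1, c2, r) + upper(c1, c2, -r)) - target

    if f(0.0) >= 0:
        return 0.0
    if f(RHO_CAP) <= 0:
        return RHO_CAP
    return float(optimize.brentq(f, 0.0, RHO_CAP, xtol=1e-8))


def tetrachoric_cosine(a: int, b: int, c: int, d: int) -> float:
    """Cosine approximation cos(pi / (1 + sqrt(ad/bc))) to the tetrachoric."""
    if b * c == 0:
        return RHO_CAP if a * d > 0 else 0.0
    if a * d == 0:
        return -RHO_CAP
    return float(np.cos(np.pi / (1.0 + np.sqrt((a * d) / (b * c)))))


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([h, k]))


def tetrachoric(a: int, b: int, c: int, d: int, *, estimator: str = "ml") -> float:
    """Tetrachoric correlation of a 2x2 table of dichotomized variables.

    Maximum likelihood under a latent bivariate normal: thresholds are set
    from the margins and the correlation solves
    ``Phi2(h, k; rho) = a / n`` by bisection (``a`` counts the cell below
    both thresholds).  Perfect association (b = c = 0 or a = d = 0) is
    capped at +/-0.999.  ``estimator="cosine"`` uses the closed-form
    cosine approximation instead.
    """
    counts = np.array([a, b, c, d])
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if np.count_nonzero(counts) < 2:
        raise ValueError("need at least two nonzero cells")
    n = counts.sum()
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate margin in 2x2 table")
    if estimator == "cosine":
        return tetrachoric_cosine(a, b, c, d)
    if estimator != "ml":
        raise ValueError(f"unknown estimator {estimator!r}")
    if b == 0 and c == 0:
        return RHO_CAP
    if a == 0 and d == 0:
        return -RHO_CAP
    h = stats.norm.ppf((a + b) / n)  # threshold for variable 1
    k = stats.norm.ppf((a + c) / n)
    target = a / n

    def f(rho: float) -> float:
        return _bvn_cdf(h, k, rho) - target

    lo, hi = -RHO_CAP, RHO_CAP
    if f(lo) >= 0:
        return lo
    if f(hi) <= 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def _nearest_psd_correlation(r: np.ndarray) -> tuple[np.ndarray, bool]:
    w, v = np.linalg.eigh(r)
    if w.min() >= -1e-10:
        return r, False
    w = np.clip(w, 1e-10, None)
    r2 = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return r2, True


def scan_correlation(
    scans: dict[str, pd.DataFrame],
    *,
    cut: float = 0.5,
    trim: float = 1e-4,
    estimator: str = "ml",
    two_sided: bool = True,
    marker_col: str | None = None,
) -> ScanCorrelation:
    """Pairwise between-scan null correlation over shared markers.

    ``scans`` maps scan id to a result table with a marker id column
    (``SNP`` or ``GENE``, auto-detected) and a p-value column.  Each pair is
    median-dichotomized (signal below ``trim`` removed) and the latent
    correlation recovered by maximum likelihood: on the folded-normal scale
    for the default two-sided scans (:func:`folded_normal_correlation`), or
    by the plain signed tetrachoric when ``two_sided=False``.
    ``estimator="cosine"`` uses the closed-form cosine approximation.  The
    matrix is projected to the nearest positive semidefinite correlation
    (eigenvalue clipping) if needed; the projection is recorded in the
    estimator label.
    """
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")
    ids = list(scans)
    first = next(iter(scans.values()))
    if marker_col is None:
        marker_col = "SNP" if "SNP" in first.columns else "GENE"
    pcol = "P" if "P" in first.columns else "P_CORR"
    series = {s: scans[s].set_index(marker_col)[pcol] for s in ids}
    k = len(ids)
    rho = np.eye(k)
    counts: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for i, j in itertools.combinations(range(k), 2):
        si, sj = series[ids[i]], series[ids[j]]
        shared = si.index.intersection(sj.index)
        if shared.empty:
            raise ValueError(f"scans {ids[i]!r} and {ids[j]!r} share no markers")
        a, b, c, d = dichotomize_scans(
            si.loc[shared].to_numpy(), sj.loc[shared].to_numpy(), cut=cut, trim=trim
        )
        if estimator == "ml" and two_sided:
            r = folded_normal_correlation(a, b, c, d)
        else:
            r = tetrachoric(a, b, c, d, estimator=estimator)
        rho[i, j] = rho[j, i] = r
        counts[(ids[i], ids[j])] = (a, b, c, d)
    rho, projected = _nearest_psd_correlation(rho)
    if estimator == "ml":
        label = "ml-folded" if two_sided else "ml-tetrachoric"
    else:
        label = "cosine"
    if projected:
        label += "+psd-projected"
    return ScanCorrelation(scan_ids=ids, rho=rho, counts=counts, estimator=label)


def kost_covariance(rho) -> np.ndarray:
    """Kost-McDermott covariance of (-2 ln p_i, -2 ln p_j) from correlation.

    The cubic evaluates to exactly 4 at rho = 1, which makes the
    duplicate-scan combination collapse to the single-scan p-value.
    """
    r = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    return 3.263 * r + 0.710 * r**2 + 0.027 * r**3


def _brown_parameters(R: np.ndarray) -> tuple[float, float]:
    """Brown's scale c and degrees of freedom f for correlation matrix R."""
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if np.any(np.abs(R) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    iu = np.triu_indices(k, 1)
    e = 2.0 * k
    var = 4.0 * k + 2.0 * float(np.sum(kost_covariance(R[iu])))
    if var <= 0:
        raise ValueError("correlation matrix yields nonpositive combined variance")
    f = 2.0 * e**2 / var
    c = var / (2.0 * e)
    return c, f


def brown_combine(p, R, *, marker: str = "", subset: tuple[str, ...] = ()) -> CmaRecord:
    """Combine dependent p-values by Brown's scaled chi-square.

    ``T = sum(-2 ln p_i)`` has null mean ``2k`` and variance
    ``4k + 2 sum cov_ij`` with the Kost-McDermott covariance; the combined
    p-value is the upper tail of ``chi2_f`` at ``T/c`` with
    ``f = 2 E^2 / Var`` and ``c = Var / (2 E)``.  With ``R = I`` this is
    exactly Fisher's chi-square on ``2k`` degrees of freedom.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    R = np.asarray(R, dtype=float)
    if R.shape != (p.size, p.size):
        raise ValueError("R must be k x k for k p-values")
    c, f = _brown_parameters(R)
    T = float(np.sum(-2.0 * np.log(p)))
    p_cma = float(stats.chi2.sf(T / c, f))
    p_cma = min(max(p_cma, np.finfo(float).tiny), 1.0)
    return CmaRecord(
        marker=marker,
        subset=tuple(subset) or tuple(f"scan{i + 1}" for i in range(p.size)),
        p_values=tuple(p),
        statistic=T,
        scale=c,
        dof=f,
        p_cma=p_cma,
        combiner="brown",
    )


def brown_combine_many(P: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Vectorized Brown combination of an (m x k) matrix of p-values.

    Returns ``(p_cma, c, f)``; every row shares the same correlation R.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0) or np.any(P > 1):
        raise ValueError("p-values must lie in (0, 1]")
    c, f = _brown_parameters(R)
    T = (-2.0 * np.log(P)).sum(axis=1)
    p = stats.chi2.sf(T / c, f)
    return np.clip(p, np.finfo(float).tiny, 1.0), c, f


def stouffer_combine(p, signs, R, *, marker: str = "", subset: tuple[str, ...] = ()) -> CmaRecord:
    """Correlated Stouffer combination with effect directions.

    ``Z = sum(z_i) / sqrt(1' R 1)`` with ``z_i = Phi^-1(1 - p_i/2) *
    sign_i``; two-sided p-value from the normal reference.
    """
    p = np.asarray(p, dtype=float)
    signs = np.sign(np.asarray(signs, dtype=float))
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if signs.shape != p.shape:
        raise ValueError("signs must match p-values")
    R = np.asarray(R, dtype=float)
    if np.any(np.abs(R) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = stats.norm.isf(p / 2.0) * signs
    denom = float(np.sqrt(np.ones(p.size) @ R @ np.ones(p.size)))
    Z = float(z.sum() / denom)
    p_comb = float(min(max(2.0 * stats.norm.sf(abs(Z)), np.finfo(float).tiny), 1.0))
    return CmaRecord(
        marker=marker,
        subset=tuple(subset) or tuple(f"scan{i + 1}" for i in range(p.size)),
        p_values=tuple(p),
        statistic=Z,
        scale=denom,
        dof=float("nan"),
        p_cma=p_comb,
        combiner="stouffer",
    )


def cma_scan(
    scans: dict[str, pd.DataFrame],
    correlation: ScanCorrelation,
    *,
    eligibility_cut: float = 0.01,
    combiner: str = "brown",
    marker_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine every eligible trait subset at every marker.

    For each marker, every subset S (|S| >= 2) of scans in which the marker
    has p below ``eligibility_cut`` is combined under the fitted scan
    correlation.  Returns ``(headline, long)``: the long table holds one row
    per (marker, subset); the headline table keeps, per marker, the subset
    with the smallest combined p (ties broken toward the larger subset,
    then lexicographic trait order).

    Tables carry columns ``MARKER CHR POS SUBSET P_<scan>... T C F P_CMA``
    (positions only when the scans provide them).
    """
    ids = list(scans)
    if correlation.scan_ids != ids:
        raise ValueError("correlation matrix scan order does not match scans")
    first = next(iter(scans.values()))
    if marker_col is None:
        marker_col = "SNP" if "SNP" in first.columns else "GENE"
    pcol = "P" if "P" in first.columns else "P_CORR"

    merged = pd.concat(
        [scans[s].set_index(marker_col)[pcol].rename(f"P_{s}") for s in ids],
        axis=1,
        join="outer",
    )
    # marker metadata: first scan that knows each marker's position wins
    for meta in ("CHR", "POS"):
        pieces = [
            scans[s].set_index(marker_col)[meta] for s in ids if meta in scans[s].columns
        ]
        if pieces:
            merged[meta] = pd.concat(pieces, axis=1).bfill(axis=1).iloc[:, 0]

    P = merged[[f"P_{s}" for s in ids]].to_numpy(dtype=float)
    eligible = (P < eligibility_cut) & np.isfinite(P)

    rows = []
    for size in range(2, len(ids) + 1):
        for combo in itertools.combinations(range(len(ids)), size):
            mask = eligible[:, combo].all(axis=1)
            if not mask.any():
                continue
            sub_ids = [ids[i] for i in combo]
            R = correlation.submatrix(sub_ids)
            Psub = P[np.ix_(np.flatnonzero(mask), combo)]
            if combiner == "brown":
                p_cma, c, f = brown_combine_many(Psub, R)
                T = (-2.0 * np.log(Psub)).sum(axis=1)
            elif combiner == "stouffer":
                z = stats.norm.isf(Psub / 2.0)
                denom = float(np.sqrt(np.ones(size) @ R @ np.ones(size)))
                T = z.sum(axis=1) / denom
                p_cma = np.clip(2.0 * stats.norm.sf(np.abs(T)), np.finfo(float).tiny, 1.0)
                c, f = denom, float("nan")
            else:
                raise ValueError(f"unknown combiner {combiner!r}")
            sub = pd.DataFrame(
                {
                    "MARKER": merged.index[mask],
                    "SUBSET": "_".join(sub_ids),
                    "SUBSET_SIZE": size,
                    "T": T,
                    "C": c,
                    "F": f,
                    "P_CMA": p_cma,
                }
            )
            rows.append(sub)

    cols = ["MARKER", "SUBSET", "SUBSET_SIZE", "T", "C", "F", "P_CMA"]
    long = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)
    meta_cols = [c for c in ("CHR", "POS") if c in merged.columns]
    long = long.merge(
        merged[[f"P_{s}" for s in ids] + meta_cols],
        left_on="MARKER",
        right_index=True,
        how="left",
    )
    long = long.sort_values(
        ["MARKER", "P_CMA", "SUBSET_SIZE", "SUBSET"],
        ascending=[True, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    headline = long.groupby("MARKER", sort=True).head(1).reset_index(drop=True)
    for df in (long, headline):
        df.attrs["combiner"] = combiner
        df.attrs["eligibility_cut"] = eligibility_cut
    return headline, long
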