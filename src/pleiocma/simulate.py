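"""Synthetic family cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: three traits (eGFRcr, eGFRcys, sRAGE) with residual correlations of
about +0.70 (eGFRcr-eGFRcys) and -0.25 / -0.30 (eGFR traits with sRAGE),
familial covariance through a pedigree kinship matrix, a whole-genome-style
minor-allele-frequency spectrum including rare variants (MAF < 0.5%),
optional pleiotropic and trait-specific causal variants, overlapping samples
across the per-trait scans, and an expression count matrix with cis-eQTL
effects.  Every stochastic operation takes an explicit seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kidney import egfr_creatinine, egfr_cystatin
from .pedigree import FEMALE, MALE, KinshipMatrix, Pedigree

__all__ = [
    "GenotypeMatrix",
    "EffectSpec",
    "SyntheticCohort",
    "TRAITS",
    "default_trait_correlation",
    "draw_maf_spectrum",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_expression",
]

TRAITS = ("eGFRcr", "eGFRcys", "sRAGE")

# Observed serum concentration scale of each trait's biomarker:
# creatinine 1.05 +/- 0.33 mg/dL, cystatin C 1.08 +/- 0.43 mg/L,
# sRAGE 601.8 +/- 477.3 pg/mL.
DEFAULT_BIOMARKER_MEAN = {"creatinine": 1.05, "cystatin_c": 1.08, "srage": 601.8}
DEFAULT_BIOMARKER_SD = {"creatinine": 0.33, "cystatin_c": 0.43, "srage": 477.3}

# Trait latents are oriented as the analysis traits (higher = higher eGFR,
# higher sRAGE); the biomarker concentration for the eGFR traits moves
# opposite to the latent.
_LATENT_SIGN = {"creatinine": -1.0, "cystatin_c": -1.0, "srage": +1.0}
_TRAIT_BIOMARKER = {"eGFRcr": "creatinine", "eGFRcys": "cystatin_c", "sRAGE": "srage"}


def default_trait_correlation() -> np.ndarray:
    """Residual correlation target among (eGFRcr, eGFRcys, sRAGE)."""
    return np.array(
        [
            [1.00, 0.70, -0.25],
            [0.70, 1.00, -0.30],
            [-0.25, -0.30, 1.00],
        ]
    )


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n individuals x m variants) with variant metadata."""

    dosages: np.ndarray
    ids: list[str]
    snp: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: list[str]
    alt: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        if not np.isin(d, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        self.dosages = d.astype(np.int8)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_count(self) -> np.ndarray:
        return self.dosages.astype(np.int64).sum(axis=0)

    def mac(self) -> np.ndarray:
        """Minor allele count per variant: min(AC, 2n - AC)."""
        ac = self.allele_count()
        return np.minimum(ac, 2 * self.n - ac)

    def maf(self) -> np.ndarray:
        """Empirical (folded) minor allele frequency per variant."""
        return self.mac() / (2 * self.n)


def draw_maf_spectrum(
    m: int,
    rng: np.random.Generator,
    *,
    rare_fraction: float = 0.3,
    rare_range: tuple[float, float] = (5e-4, 5e-3),
    common_range: tuple[float, float] = (5e-3, 0.5),
) -> np.ndarray:
    """MAF spectrum with a rare-variant tail.

    A ``rare_fraction`` of variants is drawn log-uniformly from
    ``rare_range`` (default straddling MAF < 0.5%, the range where
    sequencing recovers variants imputation misses); the rest log-uniformly
    from ``common_range``.
    """
    rare = rng.random(m) < rare_fraction
    lo = np.where(rare, rare_range[0], common_range[0])
    hi = np.where(rare, rare_range[1], common_range[1])
    return np.exp(rng.uniform(np.log(lo), np.log(hi)))


def simulate_genotypes(
    pedigree: Pedigree,
    m: int,
    maf,
    seed: int | np.random.Generator = 0,
    *,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Drop alleles through a pedigree at ``m`` independent diallelic sites.

    Founder haplotypes carry the alternate allele with probability ``maf``
    (scalar or length-m vector, all in (0, 0.5]); non-founders inherit one
    allele from each parent with independent Mendelian segregation per site
    (no linkage).  Reproducible under ``seed``.
    """
    if pedigree.n == 0:
        raise ValueError("empty pedigree")
    if m <= 0:
        raise ValueError("m must be positive")
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (m,)).copy()
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = pedigree.n
    order = pedigree.topological_order()
    idx = pedigree.index
    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in order:
        f, mo = pedigree.father[i], pedigree.mother[i]
        if f is None:
            hap[i] = rng.random((2, m)) < maf
        else:
            fi, mi = idx[f], idx[mo]
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            hap[i, 0] = hap[fi, pick_f, np.arange(m)]
            hap[i, 1] = hap[mi, pick_m, np.arange(m)]
    dosages = hap.sum(axis=1)

    if chrom is None:
        # Spread variants over 22 autosomes at regular spacing.
        chrom = (np.arange(m) % 22) + 1
        order_v = np.argsort(chrom, kind="stable")
        chrom = chrom[order_v]
    if pos is None:
        pos = np.zeros(m, dtype=np.int64)
        for c in np.unique(chrom):
            sel = chrom == c
            pos[sel] = 100_000 + 10_000 * np.arange(sel.sum())
    snp = [f"var{c}_{p}" for c, p in zip(chrom, pos)]
    return GenotypeMatrix(
        dosages=dosages,
        ids=list(pedigree.iid),
        snp=snp,
        chrom=np.asarray(chrom, dtype=np.int64),
        pos=np.asarray(pos, dtype=np.int64),
        ref=["A"] * m,
        alt=["G"] * m,
    )


@dataclass
class EffectSpec:
    """Genetic architecture of the three simulated traits.

    ``beta`` is an m x 3 matrix of per-dosage effects in units of latent
    (log-trait) SD, columns ordered as :data:`TRAITS`.  ``trait_corr`` is the
    3x3 residual/polygenic correlation; ``h2`` the per-trait narrow-sense
    polygenic heritability; ``overlap`` the fraction of samples shared
    between the per-trait scans (1 = the fully overlapping design).
    """

    beta: np.ndarray | None = None
    trait_corr: np.ndarray = field(default_factory=default_trait_correlation)
    h2: tuple[float, float, float] = (0.4, 0.4, 0.3)
    overlap: float = 1.0
    biomarker_mean: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKER_MEAN))
    biomarker_sd: dict = field(default_factory=lambda: dict(DEFAULT_BIOMARKER_SD))
    covariate_beta: dict = field(default_factory=dict)  # e.g. {"PC1": (0.1, 0.1, 0.0)}

    def __post_init__(self) -> None:
        C = np.asarray(self.trait_corr, dtype=float)
        if C.shape != (3, 3) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("trait_corr must be a symmetric 3x3 correlation matrix")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("trait_corr must be positive definite")
        self.trait_corr = C
        h2 = np.asarray(self.h2, dtype=float)
        if np.any(h2 < 0) or np.any(h2 >= 1):
            raise ValueError("heritabilities must lie in [0, 1)")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap fraction must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated cohort produced."""

    pedigree: Pedigree
    kinship: KinshipMatrix
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    latent: pd.DataFrame  # true standardized latent trait values


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age/sex/field-center/PC1 table shaped like the study population."""
    age = np.clip(rng.normal(70.0, 15.0, n), 24.0, 110.0)
    sex = np.where(rng.random(n) < 0.55, FEMALE, MALE)
    center = rng.choice(["BU", "CU", "PT", "DK"], size=n)
    pc1 = rng.normal(0.0, 1.0, n)
    return pd.DataFrame({"age": age, "sex": sex, "center": center, "PC1": pc1})


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    spec: EffectSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate biomarker concentrations with the configured architecture.

    The latent value of trait t is

        z_t = G beta_t + g_t + e_t

    with ``g`` a polygenic term of variance h2_t and familial covariance
    proportional to 2K, ``e`` a residual of variance 1 - h2_t, and both g
    and e correlated across traits with correlation ``trait_corr`` (so the
    total latent correlation matches the configured target at any h2).
    Latents are mapped to lognormal concentrations on each biomarker's
    observed scale (creatinine and cystatin C move opposite to their eGFR
    latents), and eGFRs are derived through the CKD-EPI equations, which
    injects the age and sex structure the association model adjusts for.

    Returns the phenotype table (one row per individual: IID, covariates,
    concentrations, derived eGFRs) and the true latent table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = genotypes.n
    if kinship.n != n:
        raise ValueError("kinship and genotype dimensions disagree")
    C = spec.trait_corr
    h2 = np.asarray(spec.h2, dtype=float)
    L_C = np.linalg.cholesky(C)

    A = kinship.relationship()
    w, U = np.linalg.eigh(A)
    w = np.clip(w, 0.0, None)
    L_A = U * np.sqrt(w)  # L_A @ L_A.T = A

    g = L_A @ rng.standard_normal((n, 3)) @ L_C.T  # rows ~ N(0, A), cols corr C
    e = rng.standard_normal((n, 3)) @ L_C.T
    z = g * np.sqrt(h2) + e * np.sqrt(1.0 - h2)

    if spec.beta is not None:
        beta = np.asarray(spec.beta, dtype=float)
        if beta.shape != (genotypes.m, 3):
            raise ValueError("beta must be m x 3")
        dos = genotypes.dosages.astype(float)
        p = dos.mean(axis=0) / 2.0
        sd = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12))
        # beta is in latent-SD units per standardized dosage
        z = z + ((dos - 2.0 * p) / sd) @ beta

    cov = _simulate_covariates(n, rng)
    for name, coefs in spec.covariate_beta.items():
        x = cov[name].to_numpy(dtype=float)
        x = (x - x.mean()) / x.std()
        z = z + np.outer(x, np.asarray(coefs, dtype=float))

    pheno = {"IID": genotypes.ids}
    pheno.update({k: cov[k].to_numpy() for k in cov.columns})
    for t, trait in enumerate(TRAITS):
        marker = _TRAIT_BIOMARKER[trait]
        mean, sd = spec.biomarker_mean[marker], spec.biomarker_sd[marker]
        # lognormal moment matching on the concentration scale
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2.0
        pheno[marker] = np.exp(mu + np.sqrt(s2) * _LATENT_SIGN[marker] * z[:, t])

    df = pd.DataFrame(pheno)
    df["eGFRcr"] = egfr_creatinine(df["creatinine"], df["age"], df["sex"])
    df["eGFRcys"] = egfr_cystatin(df["cystatin_c"], df["age"], df["sex"])
    df["sRAGE"] = df["srage"]
    latent = pd.DataFrame(z, columns=list(TRAITS))
    latent.insert(0, "IID", genotypes.ids)
    return df, latent


def simulate_expression(
    genotypes: GenotypeMatrix,
    n_genes: int,
    eqtl_spec: list[tuple[int, int, float]] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    dispersion: float = 0.1,
    mean_libsize: float = 1e7,
) -> tuple[np.ndarray, list[str]]:
    """Negative-binomial RNA-seq counts (genes x samples) with cis-eQTLs.

    ``eqtl_spec`` lists ``(gene_index, variant_index, log-fold-change per
    alternate allele)``.  Library sizes vary lognormally around
    ``mean_libsize``; per-gene baseline abundance spans ~4 orders of
    magnitude so the CPM filter has something to remove.  Reproducible under
    ``seed``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = genotypes.n
    libsize = np.exp(rng.normal(np.log(mean_libsize), 0.3, n))
    base = 10.0 ** rng.uniform(-1.5, 2.5, n_genes)  # CPM-scale abundance
    log_mu = np.log(base)[:, None] + rng.normal(0.0, 0.05, (n_genes, n))
    for gene_i, var_j, lfc in eqtl_spec or []:
        log_mu[gene_i] += lfc * genotypes.dosages[:, var_j].astype(float)
    mu = np.exp(log_mu) * (libsize / 1e6)[None, :]
    # NB with mean mu and variance mu + dispersion * mu^2, via gamma-Poisson
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    gene_ids = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    return counts, gene_ids
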