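"""Shared study configuration for the numbered analysis scripts.

One synthetic family cohort is used throughout: ~1500 individuals in
three-generation families, 6000 variants with a rare-variant tail, the
observed trait-correlation structure (+0.70 / -0.25 / -0.30), and eight
injected causal variants — five pleiotropic (shared across traits) and
three trait-specific — so the discovery scripts have something to find.
Everything is deterministic given SEED.
"""

from pathlib import Path

import numpy as np

from pleiocma.io import PipelineConfig
from pleiocma.pedigree import build_kinship, simulate_pedigree
from pleiocma.simulate import (
    EffectSpec,
    SyntheticCohort,
    draw_maf_spectrum,
    simulate_genotypes,
    simulate_phenotypes,
)

SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

CONFIG = PipelineConfig(seed=SEED, n_families=60, n_variants=6000, n_genes=1500)

# (variant rank by MAF descending, effect per trait in latent-SD units)
PLEIOTROPIC_EFFECTS = [
    (0, (0.30, 0.30, -0.30)),   # shared across all three traits
    (1, (0.28, 0.28, 0.00)),    # eGFRcr + eGFRcys
    (2, (0.26, 0.00, -0.26)),   # eGFRcr + sRAGE
    (3, (0.00, 0.26, -0.26)),   # eGFRcys + sRAGE
    (4, (0.24, 0.24, -0.24)),
]
TRAIT_SPECIFIC_EFFECTS = [
    (5, (0.30, 0.00, 0.00)),
    (6, (0.00, 0.30, 0.00)),
    (7, (0.00, 0.00, 0.35)),
]


def build_cohort(with_effects: bool = True) -> tuple[SyntheticCohort, np.ndarray]:
    """Deterministic cohort; returns it with the causal variant indices."""
    rng = np.random.default_rng(SEED)
    ped = simulate_pedigree(CONFIG.n_families, seed=rng)
    kin = build_kinship(ped)
    maf = draw_maf_spectrum(CONFIG.n_variants, rng)
    geno = simulate_genotypes(ped, CONFIG.n_variants, maf, rng)
    by_maf = np.argsort(geno.maf())[::-1]
    beta = np.zeros((geno.m, 3))
    causal = []
    if with_effects:
        for rank, effects in PLEIOTROPIC_EFFECTS + TRAIT_SPECIFIC_EFFECTS:
            beta[by_maf[rank]] = effects
            causal.append(by_maf[rank])
    spec = EffectSpec(beta=beta if with_effects else None)
    pheno, latent = simulate_phenotypes(geno, kin, spec, rng)
    cohort = SyntheticCohort(
        pedigree=ped, kinship=kin, genotypes=geno, phenotypes=pheno, latent=latent
    )
    return cohort, np.array(causal, dtype=int)
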