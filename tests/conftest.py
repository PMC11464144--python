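import numpy as np
import pytest

from pleiocma.pedigree import Pedigree, build_kinship, simulate_pedigree
from pleiocma.simulate import (
    EffectSpec,
    draw_maf_spectrum,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def trio():
    """Father, mother, one child."""
    return Pedigree(
        iid=["dad", "mom", "kid"],
        father=[None, None, "dad"],
        mother=[None, None, "mom"],
        sex=["male", "female", "female"],
    )


@pytest.fixture(scope="session")
def sib_pedigree():
    """Two founders with two full-sib children."""
    return Pedigree(
        iid=["dad", "mom", "sib1", "sib2"],
        father=[None, None, "dad", "dad"],
        mother=[None, None, "mom", "mom"],
        sex=["male", "female", "male", "female"],
    )


@pytest.fixture(scope="session")
def family_cohort():
    """A moderate multi-family cohort with kinship, genotypes, phenotypes."""
    ped = simulate_pedigree(60, seed=7)
    kin = build_kinship(ped)
    rng = np.random.default_rng(7)
    m = 2000
    maf = draw_maf_spectrum(m, rng)
    geno = simulate_genotypes(ped, m, maf, rng)
    pheno, latent = simulate_phenotypes(geno, kin, EffectSpec(), rng)
    return {"pedigree": ped, "kinship": kin, "genotypes": geno, "phenotypes": pheno,
            "latent": latent}
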