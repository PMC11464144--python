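"""Shared helpers for the test suite."""

import numpy as np

from pleiocma.simulate import GenotypeMatrix


def make_genotypes(dosages, ref=None, alt=None):
    d = np.asarray(dosages)
    n, m = d.shape
    return GenotypeMatrix(
        dosages=d,
        ids=[f"i{k}" for k in range(n)],
        snp=[f"v{j}" for j in range(m)],
        chrom=np.ones(m, dtype=int),
        pos=np.arange(1, m + 1) * 1000,
        ref=ref or ["A"] * m,
        alt=alt or ["G"] * m,
    )
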