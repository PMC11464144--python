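"""Bundled worked-example summary statistics.

Lead-variant and gene-level results from a family-based whole-genome /
whole-blood-transcriptome pleiotropy scan of eGFRcr, eGFRcys and sRAGE,
used as fixed worked examples for the pleiotropy criteria, the trait-subset
classification, and the gene-level significance threshold.  Per-scan
p-values for traits outside a record's subset are absent (None), mirroring
the blank cells of the source summary tables.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["novel_locus_table", "pleiotropic_gene_table", "N_TWAS_GENES"]

# Gene universe size behind the transcriptome-wide Bonferroni threshold.
N_TWAS_GENES = 18_304

# (subset, lead SNP, cytoband, nearest genes, p_eGFRcr, p_eGFRcys, p_sRAGE, p_CMA)
_LOCI = [
    ("eGFRcr_eGFRcys", "rs547464256", "1p34.3", "LINC01343/LINC01685", 3.02e-6, 1.68e-6, None, 1.49e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs533133043", "1p32.3", "CDKN2C/MIR4421", 5.02e-8, 4.28e-7, 4.08e-4, 3.88e-12),
    ("eGFRcr_sRAGE", "rs6656882", "1p22.3", "SH3GLB1/SELENOF", 2.34e-4, None, 2.34e-10, 1.02e-11),
    ("eGFRcr_eGFRcys", "rs74100345", "1p22.2", "ZNF326/SNORD3G", 2.98e-6, 4.74e-6, None, 3.12e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs76181979", "1p21.2", "LINC01307", 4.85e-6, 6.28e-5, 9.54e-3, 4.74e-8),
    ("eGFRcr_eGFRcys", "rs115559549", "1q24.1", "LOC440700/TMCO1", 2.20e-6, 2.61e-7, None, 3.19e-9),
    ("eGFRcr_eGFRcys", "rs139831128", "2q37.2", "ASB18/IQCA1", 1.36e-5, 9.67e-7, None, 3.12e-8),
    ("eGFRcr_eGFRcys", "rs753994697", "3p24.3", "KCNH8", 2.97e-7, 6.04e-5, None, 4.65e-8),
    ("eGFRcr_eGFRcys", "rs562793857", "3p12.1", "LINC02070/VGLL3", 1.88e-11, 3.76e-9, None, 3.51e-14),
    ("eGFRcr_eGFRcys", "rs16850353", "3q23", "CLSTN2", 1.62e-7, 2.60e-5, None, 1.58e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs151274284", "4p16.2", "STK32B", 1.60e-5, 1.93e-7, 1.36e-3, 3.71e-10),
    ("eGFRcr_eGFRcys_sRAGE", "rs749822346", "4p15.31", "LCORL/SLIT2", 8.97e-7, 1.52e-4, 6.19e-3, 2.13e-8),
    ("eGFRcr_eGFRcys", "rs554254460", "4q28.3", "PCDH10/PABPC4L", 1.63e-9, 5.58e-6, None, 2.32e-10),
    ("eGFRcr_eGFRcys", "rs72715959", "4q34.3", "LINC01098/LINC00290", 5.13e-6, 1.62e-8, None, 9.53e-10),
    ("eGFRcr_eGFRcys", "rs28003", "5p15.2", "CTNND2", 4.69e-6, 1.89e-6, None, 2.24e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs562304789", "5q14.1", "TENT2", 5.72e-4, 7.93e-6, 6.78e-4, 2.94e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs185704381", "5q22.3", "YTHDC2/KCNN2", 1.65e-5, 1.28e-4, 2.17e-3, 4.03e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs189218418", "7p15.1-p14.3", "CREB5", 9.66e-5, 2.04e-5, 1.45e-3, 2.67e-8),
    ("eGFRcys_sRAGE", "rs149174297", "7q35-q36.1", "CNTNAP2", None, 1.02e-5, 3.46e-5, 6.58e-9),
    ("eGFRcr_eGFRcys_sRAGE", "rs230222", "9q22.31", "CENPP/ECM2", 2.75e-5, 1.09e-4, 2.50e-4, 8.37e-9),
    ("eGFRcr_eGFRcys", "rs7038363", "9q22.33", "PRXL2C/LOC441455", 1.30e-7, 8.33e-5, None, 3.59e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs974573268", "10p14", "LINC00707", 1.11e-5, 1.26e-4, 2.02e-3, 2.90e-8),
    ("eGFRcys_sRAGE", "rs10905638", "10p14", "LOC101928272/LINC02670", None, 1.91e-6, 4.11e-4, 1.95e-8),
    ("eGFRcr_eGFRcys", "rs184854082", "11p14.3-p14.2", "LUZP2/ANO3", 3.41e-8, 1.53e-5, None, 3.74e-9),
    ("eGFRcr_eGFRcys", "rs116560702", "11q12.2", "MS4A6E/MS4A7", 2.40e-9, 1.25e-8, None, 2.51e-12),
    ("eGFRcr_eGFRcys_sRAGE", "rs140810086", "11q14.1", "DLG2", 6.16e-6, 8.00e-7, 1.63e-3, 5.41e-10),
    ("eGFRcys_sRAGE", "rs73535710", "11q14.3", "DISC1FP1", None, 3.56e-5, 7.25e-5, 4.14e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs184549240", "11q22.1", "LINC02737/CNTN5", 2.92e-5, 6.64e-7, 9.94e-5, 1.23e-10),
    ("eGFRcr_eGFRcys_sRAGE", "rs529684126", "11q25", "LOC283177/LINC02714", 4.06e-6, 6.29e-5, 8.70e-3, 3.87e-8),
    ("eGFRcys_sRAGE", "rs2895135", "12q24.33", "RIMBP2", None, 6.73e-4, 2.53e-6, 4.19e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs112909432", "14q12", "LOC728755/FOXG1-AS1", 1.17e-6, 2.16e-4, 8.47e-3, 4.39e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs7141142", "14q13.1", "NPAS3", 1.03e-4, 3.88e-6, 3.77e-3, 2.33e-8),
    ("eGFRcr_eGFRcys", "rs186101700", "14q24.3", "GPATCH2L/ESRRB", 1.29e-7, 3.22e-5, None, 1.62e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs147775587", "14q31.3", "LINC02301/SNORD3P3", 6.88e-5, 3.48e-5, 3.13e-4, 8.38e-9),
    ("eGFRcr_eGFRcys", "rs543176745", "15q25.3", "AGBL1", 8.14e-9, 9.12e-5, None, 6.99e-9),
    ("eGFRcr_eGFRcys_sRAGE", "rs528757227", "17q24.3", "CASC17/ROCR", 7.52e-4, 3.24e-4, 1.37e-5, 2.90e-8),
    ("eGFRcr_eGFRcys", "rs113025648", "17q25.3", "LINC01987/LINC01973", 5.77e-6, 3.50e-6, None, 4.04e-8),
    ("eGFRcr_eGFRcys", "rs146289239", "18p11.23", "PTPRM", 4.63e-8, 3.07e-7, None, 2.18e-10),
    ("eGFRcr_eGFRcys", "rs9963912", "18q21.1-q21.2", "SKA1/MAPK4", 6.89e-8, 7.46e-5, None, 2.19e-8),
    ("eGFRcr_sRAGE", "rs73030728", "19q12", "LOC100420587/LINC00906", 9.68e-5, None, 1.64e-5, 2.82e-8),
    ("eGFRcr_eGFRcys_sRAGE", "rs112684971", "21q21.1", "MIR99AHG/LINC01549", 5.24e-6, 3.03e-5, 2.49e-4, 1.05e-9),
    ("eGFRcr_eGFRcys", "rs144142100", "21q22.3", "PTTG1IP/ITGB2", 1.31e-4, 4.70e-8, None, 2.80e-8),
]

# (gene, cytoband, subset, p_eGFRcr, p_eGFRcys, p_sRAGE, p_CMA, headline,
#  single_trait_significant)
_GENES = [
    ("MTX1", "1q22", "eGFRcr_eGFRcys_sRAGE", 2.66e-5, 1.63e-3, 2.61e-4, 1.99e-7, True, False),
    ("MTX1", "1q22", "eGFRcr_sRAGE", 2.66e-5, None, 2.61e-4, 1.1e-7, False, False),
    ("PTPRC", "1q31.3-q32.1", "eGFRcr_eGFRcys_sRAGE", 1.7e-5, 2.87e-5, 3.58e-2, 6.63e-7, True, False),
    ("PTPRC", "1q31.3-q32.1", "eGFRcr_eGFRcys", 1.7e-5, 2.87e-5, None, 1.45e-6, False, False),
    ("ODC1", "2p25.1", "eGFRcr_eGFRcys", 1.47e-6, 3.54e-6, None, 7.62e-8, True, True),
    ("CALM2", "2p21", "eGFRcr_eGFRcys", 3.37e-5, 7.9e-6, None, 9.93e-7, True, False),
    ("TEC", "4p12-p11", "eGFRcr_eGFRcys_sRAGE", 2.08e-4, 3.21e-5, 1.37e-2, 1.17e-6, True, False),
    ("CCNI", "4q21.1", "eGFRcr_eGFRcys_sRAGE", 3.35e-4, 1.19e-4, 6.18e-3, 1.69e-6, True, False),
    ("ERGIC1", "5q35.1", "eGFRcr_eGFRcys", 3.31e-5, 2.34e-7, None, 1.17e-7, True, True),
    ("DAAM2", "6p21.2", "eGFRcr_eGFRcys_sRAGE", 3.69e-6, 4.59e-6, 2.85e-3, 7.28e-9, True, False),
    ("DAAM2", "6p21.2", "eGFRcr_eGFRcys", 3.69e-6, 4.59e-6, None, 1.63e-7, False, False),
    ("DAAM2", "6p21.2", "eGFRcr_sRAGE", 3.69e-6, None, 2.85e-3, 2.86e-7, False, False),
    ("DAAM2", "6p21.2", "eGFRcys_sRAGE", None, 4.59e-6, 2.85e-3, 3.40e-7, False, False),
    ("DAAM2-AS1", "6p21.2", "eGFRcr_eGFRcys_sRAGE", 2.47e-4, 1.46e-4, 6.41e-3, 1.63e-6, True, False),
    ("SNTB1", "8q24.12", "eGFRcr_eGFRcys", 2.48e-5, 1.45e-5, None, 1.19e-6, True, False),
    ("TOPORS", "9p21.1", "eGFRcr_eGFRcys", 5.92e-5, 5.21e-6, None, 1.13e-6, True, False),
    ("LSP1", "11p15.5", "eGFRcr_eGFRcys", 1.93e-4, 8.41e-7, None, 8.97e-7, True, True),
    ("ATG2A", "11q13.1", "eGFRcr_eGFRcys", 8.74e-6, 2.05e-5, None, 7.6e-7, True, False),
    ("RPL18P10", "13q14.2", "eGFRcr_eGFRcys", 1.19e-4, 7.65e-6, None, 2.31e-6, True, False),
    ("C16orf54", "16p11.2", "eGFRcr_eGFRcys_sRAGE", 1.92e-6, 3.94e-7, 1.39e-2, 5.89e-9, True, True),
    ("C16orf54", "16p11.2", "eGFRcr_eGFRcys", 1.92e-6, 3.94e-7, None, 2.2e-8, False, False),
    ("C16orf54", "16p11.2", "eGFRcr_sRAGE", 1.92e-6, None, 1.39e-2, 1.27e-6, False, False),
    ("MIR23AHG", "19p13.12", "eGFRcr_eGFRcys_sRAGE", 3.59e-5, 1.76e-3, 3.05e-3, 1.49e-6, True, False),
    ("MIR23AHG", "19p13.12", "eGFRcr_sRAGE", 3.59e-5, None, 3.05e-3, 1.81e-6, False, False),
    ("TP53INP2", "20q11.22", "eGFRcr_eGFRcys_sRAGE", 2.16e-4, 3.73e-6, 6.48e-2, 1.96e-6, True, False),
    ("TP53INP2", "20q11.22", "eGFRcr_eGFRcys", 2.16e-4, 3.73e-6, None, 2.31e-6, False, False),
]


def novel_locus_table() -> pd.DataFrame:
    """The 42 novel pleiotropic lead variants as a headline-style table."""
    df = pd.DataFrame(
        _LOCI,
        columns=["SUBSET", "MARKER", "CYTOBAND", "GENES", "P_eGFRcr", "P_eGFRcys", "P_sRAGE", "P_CMA"],
    )
    return df.astype({"P_eGFRcr": float, "P_eGFRcys": float, "P_sRAGE": float, "P_CMA": float})


def pleiotropic_gene_table(*, headline_only: bool = False) -> pd.DataFrame:
    """The 17 pleiotropic genes (all reported subset rows, or headline only)."""
    df = pd.DataFrame(
        _GENES,
        columns=[
            "GENE", "CYTOBAND", "SUBSET", "P_eGFRcr", "P_eGFRcys", "P_sRAGE",
            "P_CMA", "HEADLINE", "SINGLE_TRAIT_SIG",
        ],
    ).astype({"P_eGFRcr": float, "P_eGFRcys": float, "P_sRAGE": float, "P_CMA": float})
    return df[df["HEADLINE"]].reset_index(drop=True) if headline_only else df
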