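"""Loci, pleiotropy verdicts, and novelty annotation.

Post-processing of combined-scan records: the three pleiotropy criteria
(every contributing scan p < 0.01, combined p < 5e-8, combined p smaller
than each contributing p), greedy distance clumping into 1 Mb loci, trait-
subset classification, and novelty against a catalog of previously reported
lead variants (> 500 kb from any catalog entry, strictly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "Catalog",
    "pleiotropy_filter",
    "apply_pleiotropy_filter",
    "clump",
    "classify_trait_set",
    "annotate_novelty",
    "summarize",
]

GWAS_CUT = 0.01
CMA_CUT = 5e-8
NOVELTY_DISTANCE = 500_000
CLUMP_WINDOW = 1_000_000

_ABBREV = {"eGFRcr": "cr", "eGFRcys": "cys", "sRAGE": "sRAGE"}


@dataclass
class Locus:
    """A clumped genomic region represented by its lead marker."""

    lead: str
    chrom: object
    position: int
    region: tuple[int, int]
    p_cma: float
    subset: str
    p_values: dict = field(default_factory=dict)
    novelty: str | None = None
    nearest_hit: str | None = None
    nearest_distance: int | None = None


@dataclass
class Catalog:
    """Previously reported lead variants (chromosome, 1-based position)."""

    entries: pd.DataFrame  # columns CHR POS TRAIT SOURCE
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        need = {"CHR", "POS"}
        if not need.issubset(self.entries.columns):
            raise ValueError("catalog needs CHR and POS columns")
        if len(self.entries) and (self.entries["POS"] <= 0).any():
            raise ValueError("catalog positions must be positive")


def pleiotropy_filter(
    p_values: dict[str, float],
    p_cma: float,
    *,
    gwas_cut: float = GWAS_CUT,
    cma_cut: float = CMA_CUT,
    rule: str = "min",
) -> tuple[bool, list[str]]:
    """Apply the three pleiotropy criteria to one combined record.

    ``p_values`` maps each contributing trait to its per-scan p-value.
    Passes iff every contributing p < ``gwas_cut``, the combined p <
    ``cma_cut``, and the combined p is strictly smaller than the smallest
    contributing p (``rule="min"``, default) or than at least one
    contributing p (``rule="any"``).  Returns the verdict and the list of
    failed criteria.
    """
    if not p_values:
        raise ValueError("empty trait subset")
    reasons = []
    if any(p >= gwas_cut for p in p_values.values()):
        reasons.append(f"individual p >= {gwas_cut:g}")
    if not p_cma < cma_cut:
        reasons.append(f"combined p >= {cma_cut:g}")
    ref = min(p_values.values()) if rule == "min" else max(p_values.values())
    if not p_cma < ref:
        reasons.append(
            "combined p not smaller than best individual p"
            if rule == "min"
            else "combined p not smaller than any individual p"
        )
    return not reasons, reasons


def _record_pvalues(row: pd.Series, subset: str) -> dict[str, float]:
    return {t: float(row[f"P_{t}"]) for t in subset.split("_")}


def apply_pleiotropy_filter(
    headline: pd.DataFrame,
    *,
    gwas_cut: float = GWAS_CUT,
    cma_cut: float = CMA_CUT,
    rule: str = "min",
) -> pd.DataFrame:
    """Filter a headline combined-scan table; adds PASS and REASONS columns."""
    out = headline.copy()
    verdicts, reasons = [], []
    for _, row in out.iterrows():
        ok, why = pleiotropy_filter(
            _record_pvalues(row, row["SUBSET"]),
            float(row["P_CMA"]),
            gwas_cut=gwas_cut,
            cma_cut=cma_cut,
            rule=rule,
        )
        verdicts.append(ok)
        reasons.append("; ".join(why))
    out["PASS"] = verdicts
    out["REASONS"] = reasons
    return out


def clump(records: pd.DataFrame, *, window: int = CLUMP_WINDOW) -> list[Locus]:
    """Greedy distance clumping of passing records into loci.

    Repeatedly takes the record with the smallest combined p-value as a
    lead (ties: smaller genomic position) and absorbs every record on the
    same chromosome within ``window/2`` of it.  Deterministic; every record
    belongs to exactly one locus.
    """
    if records.empty:
        return []
    df = records.sort_values(
        ["P_CMA", "CHR", "POS"], ascending=True, kind="stable"
    ).reset_index(drop=True)
    half = window // 2
    taken = np.zeros(len(df), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(df)):
        if taken[i]:
            continue
        lead = df.iloc[i]
        same = (df["CHR"] == lead["CHR"]) & (np.abs(df["POS"] - lead["POS"]) <= half)
        members = df[same & ~taken]
        taken |= same.to_numpy() & ~taken
        pcols = [c for c in df.columns if c.startswith("P_") and c != "P_CMA"]
        pvals = {
            c[2:]: float(lead[c])
            for c in pcols
            if c[2:] in lead["SUBSET"].split("_") and np.isfinite(lead[c])
        }
        loci.append(
            Locus(
                lead=str(lead["MARKER"]),
                chrom=lead["CHR"],
                position=int(lead["POS"]),
                region=(int(members["POS"].min()), int(members["POS"].max())),
                p_cma=float(lead["P_CMA"]),
                subset=str(lead["SUBSET"]),
                p_values=pvals,
            )
        )
    loci.sort(key=lambda l: (str(l.chrom), l.position))
    return loci


def classify_trait_set(locus_or_subset) -> str:
    """Short subset label: cr_cys_sRAGE, cr_cys, cr_sRAGE or cys_sRAGE."""
    subset = locus_or_subset.subset if isinstance(locus_or_subset, Locus) else locus_or_subset
    return "_".join(_ABBREV.get(t, t) for t in subset.split("_"))


def annotate_novelty(
    loci: list[Locus],
    catalog: Catalog,
    *,
    distance: int = NOVELTY_DISTANCE,
    build: str = "GRCh38",
) -> list[Locus]:
    """Flag each locus novel iff its lead is > ``distance`` bp (strictly)
    from every catalog entry on the same chromosome.

    Raises
    ------
    ValueError
        If the catalog's genome build label differs from ``build``.
    """
    if catalog.build != build:
        raise ValueError(f"catalog build {catalog.build!r} does not match {build!r}")
    for locus in loci:
        same = catalog.entries[catalog.entries["CHR"].astype(str) == str(locus.chrom)]
        if same.empty:
            locus.novelty = "novel"
            locus.nearest_hit = None
            locus.nearest_distance = None
            continue
        dist = (same["POS"] - locus.position).abs()
        j = dist.idxmin()
        locus.nearest_distance = int(dist.loc[j])
        locus.nearest_hit = str(same.loc[j].get("SOURCE", f"{locus.chrom}:{same.loc[j]['POS']}"))
        locus.novelty = "novel" if locus.nearest_distance > distance else "known"
    return loci


def loci_to_frame(loci: list[Locus], traits: list[str] | None = None) -> pd.DataFrame:
    """Locus table shaped like the headline summary: one row per locus."""
    traits = traits or ["eGFRcr", "eGFRcys", "sRAGE"]
    rows = []
    for l in loci:
        row = {
            "LEAD": l.lead,
            "CHR": l.chrom,
            "POS": l.position,
            "START": l.region[0],
            "END": l.region[1],
            "SUBSET": classify_trait_set(l),
        }
        for t in traits:
            row[f"P_{t}"] = l.p_values.get(t, np.nan)
        row["P_CMA"] = l.p_cma
        row["NOVELTY"] = l.novelty
        row["NEAREST"] = l.nearest_hit
        row["DISTANCE"] = l.nearest_distance
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    loci: list[Locus],
    gene_results: pd.DataFrame | None = None,
    *,
    lambdas: dict[str, float] | None = None,
) -> dict:
    """Counts by trait subset, locus and gene tables, and scan lambdas."""
    locus_table = loci_to_frame(loci)
    counts: dict[str, int] = {}
    for l in loci:
        label = classify_trait_set(l)
        counts[label] = counts.get(label, 0) + 1
    novel = sum(1 for l in loci if l.novelty == "novel")
    return {
        "n_loci": len(loci),
        "n_novel": novel,
        "counts_by_subset": counts,
        "locus_table": locus_table,
        "gene_table": gene_results if gene_results is not None else pd.DataFrame(),
        "lambdas": lambdas or {},
    }
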