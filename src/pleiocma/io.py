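"""Tab-delimited file formats, configuration, and provenance.

Every writer has a paired reader that round-trips its output.  Missing
p-values (a trait outside a record's subset) are written as literal ``NA``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import SCAN_COLUMNS
from .loci import Catalog

__all__ = [
    "PipelineConfig",
    "read_scan_table",
    "write_scan_table",
    "read_gene_table",
    "write_gene_table",
    "write_cma_table",
    "read_cma_table",
    "read_catalog",
    "write_correlation_report",
    "write_provenance",
]

NA = "NA"


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default."""

    seed: int = 0
    n_families: int = 150
    n_variants: int = 8000
    n_genes: int = 2000
    gwas_cut: float = 0.01
    cma_cut: float = 5e-8
    twas_alpha: float = 0.05
    mac_threshold: int = 20
    min_cpm: float = 4.0
    max_fraction_low: float = 0.985
    novelty_distance: int = 500_000
    clump_window: int = 1_000_000
    trim: float = 1e-4
    dichotomize_cut: float = 0.5
    combiner: str = "brown"
    tetrachoric_estimator: str = "ml"
    overlap: float = 1.0
    heritability: tuple = (0.4, 0.4, 0.3)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.gwas_cut < 1 or not 0 < self.cma_cut < 1:
            raise ValueError("p-value cuts must lie in (0, 1)")
        if self.combiner not in ("brown", "stouffer"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.tetrachoric_estimator not in ("ml", "cosine"):
            raise ValueError(f"unknown tetrachoric estimator {self.tetrachoric_estimator!r}")
        if self.mac_threshold < 0 or self.novelty_distance < 0 or self.clump_window <= 0:
            raise ValueError("invalid threshold")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "heritability" in raw:
            raw["heritability"] = tuple(raw["heritability"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = asdict(self)
        d["heritability"] = list(d["heritability"])
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(d, fh, indent=2)
            else:
                yaml.safe_dump(d, fh)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_scan_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SCAN_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_scan_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-trait scan table.

    Raises
    ------
    ValueError
        Malformed header, p-values outside (0, 1], nonpositive SE, or
        duplicated marker ids — each error names the offending row.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    if list(df.columns) != SCAN_COLUMNS:
        raise ValueError(f"malformed scan header in {path}: {list(df.columns)}")
    bad_p = df.index[(df["P"] <= 0) | (df["P"] > 1) | df["P"].isna()]
    if len(bad_p):
        raise ValueError(f"p-value outside (0, 1] at row {bad_p[0] + 2} of {path}")
    bad_se = df.index[df["SE"] <= 0]
    if len(bad_se):
        raise ValueError(f"nonpositive SE at row {bad_se[0] + 2} of {path}")
    dup = df["SNP"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate marker id {df['SNP'][dup].iloc[0]!r} in {path}")
    if (df["POS"] <= 0).any():
        raise ValueError(f"nonpositive position in {path}")
    return df


GENE_TABLE_COLUMNS = ["GENE", "CHR", "CYTOBAND", "Z_RAW", "P_RAW", "Z_CORR", "P_CORR", "N"]


def write_gene_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in GENE_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    if list(df.columns) != GENE_TABLE_COLUMNS:
        raise ValueError(f"malformed gene-table header in {path}")
    return df


def write_cma_table(table: pd.DataFrame, path: str | Path, traits: list[str]) -> None:
    """Write combined records; per-trait p outside the subset printed as NA."""
    out = table.copy()
    for t in traits:
        col = f"P_{t}"
        if col in out.columns:
            in_subset = out["SUBSET"].str.split("_").map(lambda s, t=t: t in s)
            out.loc[~in_subset, col] = np.nan
    cols = ["MARKER"] + [c for c in ("CHR", "POS") if c in out.columns]
    cols += ["SUBSET"] + [f"P_{t}" for t in traits if f"P_{t}" in out.columns]
    cols += ["T", "C", "F", "P_CMA"]
    out[cols].to_csv(path, sep="\t", index=False, na_rep=NA)


def read_cma_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def read_catalog(path: str | Path, *, dialect: str = "onebased", build: str = "GRCh38") -> Catalog:
    """Read a catalog of known lead variants.

    ``dialect="onebased"`` expects columns ``CHR POS TRAIT SOURCE`` with
    1-based positions; ``dialect="bed"`` expects 4-column BED
    (chrom, 0-based start, end, name) and converts to 1-based.  The dialect
    is recorded on the catalog frame.
    """
    if dialect == "onebased":
        df = pd.read_csv(path, sep="\t")
        if not {"CHR", "POS"}.issubset(df.columns):
            raise ValueError("catalog needs CHR and POS columns")
    elif dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, names=["CHR", "START", "END", "SOURCE"])
        df["POS"] = df["START"] + 1
        df["TRAIT"] = NA
        df = df[["CHR", "POS", "TRAIT", "SOURCE"]]
    else:
        raise ValueError(f"unknown catalog dialect {dialect!r}")
    df.attrs["dialect"] = dialect
    return Catalog(entries=df, build=build)


def write_correlation_report(corr, path_prefix: str | Path) -> None:
    """Matrix + per-pair concordance counts, tab-delimited."""
    prefix = Path(path_prefix)
    pd.DataFrame(corr.rho, index=corr.scan_ids, columns=corr.scan_ids).to_csv(
        prefix.with_suffix(".matrix.tsv"), sep="\t"
    )
    rows = [
        {"SCAN1": i, "SCAN2": j, "A": a, "B": b, "C": c, "D": d, "ESTIMATOR": corr.estimator}
        for (i, j), (a, b, c, d) in corr.counts.items()
    ]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index=False)


def write_provenance(out_dir: str | Path, config: PipelineConfig, extra: dict | None = None) -> None:
    import pleiocma

    payload = {
        "package": "pleiocma",
        "version": pleiocma.__version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    payload.update(extra or {})
    with open(Path(out_dir) / "provenance.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
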