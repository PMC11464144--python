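"""End-to-end driver: simulate -> scan -> correct -> combine -> report.

Thin orchestration over the library modules; every stage writes its output
table and the run ends with a provenance block recording the configuration,
the per-scan genomic-control lambdas, the fitted scan correlation and the
counts each filter removed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cma, io, loci, simulate, twas
from .pedigree import build_kinship, simulate_pedigree
from .simulate import TRAITS

__all__ = ["simulate_cohort", "run_gwas", "run_twas", "run_pipeline"]


def simulate_cohort(config: io.PipelineConfig, seed: int | None = None) -> simulate.SyntheticCohort:
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(config.n_families, seed=rng)
    kin = build_kinship(ped)
    maf = simulate.draw_maf_spectrum(config.n_variants, rng)
    geno = simulate.simulate_genotypes(ped, config.n_variants, maf, rng)
    spec = simulate.EffectSpec(h2=tuple(config.heritability), overlap=config.overlap)
    pheno, latent = simulate.simulate_phenotypes(geno, kin, spec, rng)
    return simulate.SyntheticCohort(
        pedigree=ped, kinship=kin, genotypes=geno, phenotypes=pheno, latent=latent
    )


def _scan_subsets(n: int, overlap: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-trait analysis subsets sharing a fraction ``overlap`` of samples."""
    if overlap >= 1.0:
        return [np.arange(n)] * 3
    n_shared = int(round(overlap * n))
    perm = rng.permutation(n)
    shared = perm[:n_shared]
    rest = perm[n_shared:]
    chunks = np.array_split(rest, 3)
    return [np.sort(np.concatenate([shared, c])) for c in chunks]


def run_gwas(
    cohort: simulate.SyntheticCohort,
    config: io.PipelineConfig,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-trait kinship-LMM scans on (possibly partially) overlapping samples."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pheno = cohort.phenotypes
    keep = assoc.mac_filter(cohort.genotypes, config.mac_threshold)
    subsets = _scan_subsets(cohort.genotypes.n, config.overlap, rng)
    scans: dict[str, pd.DataFrame] = {}
    for trait, sub in zip(TRAITS, subsets):
        rows = pheno.iloc[sub]
        y = assoc.prepare_trait(
            rows[trait].to_numpy(), rows[["age", "sex", "center", "PC1"]], ids=rows["IID"]
        )
        X = assoc.build_design(rows[["age", "sex", "center", "PC1"]])
        sub_kin = type(cohort.kinship)(
            cohort.kinship.values[np.ix_(sub, sub)], [cohort.kinship.ids[i] for i in sub]
        )
        sub_geno = simulate.GenotypeMatrix(
            dosages=cohort.genotypes.dosages[sub],
            ids=[cohort.genotypes.ids[i] for i in sub],
            snp=cohort.genotypes.snp,
            chrom=cohort.genotypes.chrom,
            pos=cohort.genotypes.pos,
            ref=cohort.genotypes.ref,
            alt=cohort.genotypes.alt,
        )
        fit = assoc.lmm_reml_fit(y, X, sub_kin)
        table = assoc.lmm_association(fit, sub_geno, y, X, variant_index=keep, scan_id=trait)
        scans[trait] = table
    return scans


def run_twas(
    cohort: simulate.SyntheticCohort,
    config: io.PipelineConfig,
    seed: int | None = None,
    *,
    twas_fraction: float = 0.3,
) -> tuple[dict[str, pd.DataFrame], dict[str, twas.BaconFit]]:
    """Expression scans on a subset of the cohort, with empirical-null correction."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = cohort.genotypes.n
    sub = np.sort(rng.choice(n, size=max(int(twas_fraction * n), 50), replace=False))
    counts, gene_ids = simulate.simulate_expression(cohort.genotypes, config.n_genes, seed=rng)
    counts = counts[:, sub]
    keep = twas.cpm_filter(counts, min_cpm=config.min_cpm, max_fraction_low=config.max_fraction_low)
    expr = twas.log_cpm(counts[keep])
    cov = cohort.phenotypes.iloc[sub][["age", "sex", "center", "PC1"]].reset_index(drop=True)
    resid = twas.residualize_expression(expr, cov)
    sub_kin = type(cohort.kinship)(
        cohort.kinship.values[np.ix_(sub, sub)], [cohort.kinship.ids[i] for i in sub]
    )
    kept_ids = [gene_ids[i] for i in keep]
    results, fits = {}, {}
    for trait in TRAITS:
        rows = cohort.phenotypes.iloc[sub]
        y = assoc.prepare_trait(rows[trait].to_numpy(), cov, ids=rows["IID"])
        X = assoc.build_design(cov)
        raw = twas.twas_associate(resid, kept_ids, y, X, sub_kin)
        corrected, fit = twas.twas_scan_correct(raw)
        results[trait] = corrected
        fits[trait] = fit
    return results, fits


def run_pipeline(config: io.PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Full run; returns the report bundle and writes every stage's output."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cohort = simulate_cohort(config)
        cohort.pedigree.to_frame().to_csv(out / "pedigree.tsv", sep="\t", index=False)
        cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

        stage = "gwas"
        scans = run_gwas(cohort, config)
        lambdas = {}
        for trait, table in scans.items():
            io.write_scan_table(table, out / f"gwas_{trait}.tsv")
            lambdas[trait] = assoc.genomic_lambda(table["P"])

        stage = "twas"
        twas_results, _fits = run_twas(cohort, config)
        for trait, table in twas_results.items():
            io.write_gene_table(table, out / f"twas_{trait}.tsv")
            lambdas[f"twas_{trait}"] = table.attrs["lambda_corrected"]

        stage = "scan_correlation"
        corr = cma.scan_correlation(
            scans,
            cut=config.dichotomize_cut,
            trim=config.trim,
            estimator=config.tetrachoric_estimator,
        )
        io.write_correlation_report(corr, out / "scan_correlation")

        stage = "cma"
        headline, long = cma.cma_scan(
            scans, corr, eligibility_cut=config.gwas_cut, combiner=config.combiner
        )
        io.write_cma_table(long, out / "cma_long.tsv", list(TRAITS))
        io.write_cma_table(headline, out / "cma_headline.tsv", list(TRAITS))
        lambdas["cma"] = (
            assoc.genomic_lambda(headline["P_CMA"]) if len(headline) >= 10 else float("nan")
        )

        stage = "locus_report"
        filtered = loci.apply_pleiotropy_filter(
            headline, gwas_cut=config.gwas_cut, cma_cut=config.cma_cut
        )
        passing = filtered[filtered["PASS"]]
        locus_list = loci.clump(passing, window=config.clump_window)
        report = loci.summarize(locus_list, lambdas=lambdas)
        report["locus_table"].to_csv(out / "loci.tsv", sep="\t", index=False, na_rep=io.NA)
        summary = {
            "n_loci": report["n_loci"],
            "n_novel": report["n_novel"],
            "counts_by_subset": report["counts_by_subset"],
            "lambdas": lambdas,
            "scan_correlation": corr.rho.tolist(),
            "n_markers_tested": {t: int(len(s)) for t, s in scans.items()},
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        io.write_provenance(out, config, {"lambdas": lambdas})
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    report["summary"] = summary
    report["scans"] = scans
    report["headline"] = headline
    return report
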