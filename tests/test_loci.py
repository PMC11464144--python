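"""Pleiotropy criteria, clumping, novelty, and the worked-example tables."""

import numpy as np
import pandas as pd
import pytest

from pleiocma.examples import N_TWAS_GENES, novel_locus_table, pleiotropic_gene_table
from pleiocma.loci import (
    Catalog,
    annotate_novelty,
    classify_trait_set,
    clump,
    pleiotropy_filter,
    summarize,
)
from pleiocma.twas import bonferroni_threshold


class TestPleiotropyFilter:
    def test_lead_with_combined_below_best_individual_passes(self):
        ok, reasons = pleiotropy_filter(
            {"eGFRcr": 8.14e-9, "eGFRcys": 9.12e-5}, 6.99e-9
        )
        assert ok and not reasons

    def test_individual_p_above_cut_fails(self):
        ok, reasons = pleiotropy_filter({"a": 0.02, "b": 1e-9}, 1e-10)
        assert not ok
        assert any("individual p" in r for r in reasons)

    def test_combined_not_below_best_fails(self):
        ok, reasons = pleiotropy_filter({"a": 1e-9, "b": 1e-4}, 1e-7)
        assert not ok
        assert any("best individual" in r for r in reasons)

    def test_any_rule_requires_only_one_improvement(self):
        # combined beats the weaker scan but not the stronger one
        p = {"eGFRcr": 1.93e-4, "eGFRcys": 8.41e-7}
        ok_min, _ = pleiotropy_filter(p, 8.97e-7, cma_cut=2.73e-6, rule="min")
        ok_any, _ = pleiotropy_filter(p, 8.97e-7, cma_cut=2.73e-6, rule="any")
        assert not ok_min and ok_any

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            pleiotropy_filter({}, 1e-9)


def hits_frame(rows):
    return pd.DataFrame(
        rows, columns=["MARKER", "CHR", "POS", "SUBSET", "P_eGFRcr", "P_eGFRcys", "P_CMA"]
    )


class TestClump:
    def test_three_hits_two_loci(self):
        df = hits_frame([
            ("a", 1, 1_000_000, "eGFRcr_eGFRcys", 1e-11, 1e-4, 1e-10),
            ("b", 1, 1_400_000, "eGFRcr_eGFRcys", 1e-10, 1e-4, 1e-9),
            ("c", 1, 3_000_000, "eGFRcr_eGFRcys", 1e-10, 1e-4, 1e-9),
        ])
        loci = clump(df, window=1_000_000)
        assert [l.lead for l in loci] == ["a", "c"]
        assert loci[0].region == (1_000_000, 1_400_000)

    def test_single_hit_degenerate_region(self):
        df = hits_frame([("x", 2, 500, "eGFRcr_eGFRcys", 1e-9, 1e-9, 1e-12)])
        (locus,) = clump(df)
        assert locus.region == (500, 500)

    def test_equal_p_tie_broken_by_position(self):
        df = hits_frame([
            ("right", 1, 200_000, "eGFRcr_eGFRcys", 1e-9, 1e-9, 1e-10),
            ("left", 1, 100_000, "eGFRcr_eGFRcys", 1e-9, 1e-9, 1e-10),
        ])
        (locus,) = clump(df)
        assert locus.lead == "left"

    def test_idempotent_on_lead_records(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"m{i}", int(rng.integers(1, 4)), int(rng.integers(1, 10_000_000)),
             "eGFRcr_eGFRcys", 1e-9, 1e-9, float(10 ** -rng.uniform(8, 15)))
            for i in range(60)
        ]
        loci1 = clump(hits_frame(rows))
        leads = hits_frame(
            [(l.lead, l.chrom, l.position, "eGFRcr_eGFRcys",
              l.p_values.get("eGFRcr", 1e-9), l.p_values.get("eGFRcys", 1e-9), l.p_cma)
             for l in loci1]
        )
        loci2 = clump(leads)
        assert [l.lead for l in loci1] == [l.lead for l in loci2]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_partition_property(self, seed):
        """Every passing record lands in exactly one locus (brute force)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        rows = [
            (f"m{i}", int(rng.integers(1, 3)), int(rng.integers(1, 5_000_000)),
             "eGFRcr_eGFRcys", 1e-9, 1e-9, float(10 ** -rng.uniform(8, 15)))
            for i in range(n)
        ]
        df = hits_frame(rows)
        loci = clump(df, window=1_000_000)
        # brute force membership count for every record
        assigned = {m: 0 for m in df["MARKER"]}
        remaining = df.copy()
        while not remaining.empty:
            lead = remaining.sort_values(["P_CMA", "CHR", "POS"]).iloc[0]
            member = remaining[
                (remaining["CHR"] == lead["CHR"])
                & ((remaining["POS"] - lead["POS"]).abs() <= 500_000)
            ]
            for m in member["MARKER"]:
                assigned[m] += 1
            remaining = remaining.drop(member.index)
        assert all(v == 1 for v in assigned.values())
        assert sum(1 for _ in loci) == len(
            {(l.chrom, l.position) for l in loci}
        )

    def test_empty_input(self):
        assert clump(hits_frame([])) == []


class TestClassify:
    @pytest.mark.parametrize(
        "subset, label",
        [
            ("eGFRcr_eGFRcys", "cr_cys"),
            ("eGFRcys_sRAGE", "cys_sRAGE"),
            ("eGFRcr_sRAGE", "cr_sRAGE"),
            ("eGFRcr_eGFRcys_sRAGE", "cr_cys_sRAGE"),
        ],
    )
    def test_labels(self, subset, label):
        assert classify_trait_set(subset) == label


class TestNovelty:
    def locus(self, chrom=1, pos=1_000_000):
        df = hits_frame([("x", chrom, pos, "eGFRcr_eGFRcys", 1e-9, 1e-9, 1e-12)])
        return clump(df)

    def catalog(self, entries):
        return Catalog(entries=pd.DataFrame(entries, columns=["CHR", "POS", "TRAIT", "SOURCE"]))

    def test_within_distance_is_known(self):
        loci = annotate_novelty(self.locus(), self.catalog([(1, 1_400_000, "eGFR", "rsX")]))
        assert loci[0].novelty == "known"
        assert loci[0].nearest_distance == 400_000

    def test_exactly_500kb_is_known(self):
        loci = annotate_novelty(self.locus(), self.catalog([(1, 1_500_000, "eGFR", "rsY")]))
        assert loci[0].novelty == "known"  # "> 500 kb" is strict

    def test_just_over_500kb_is_novel(self):
        loci = annotate_novelty(self.locus(), self.catalog([(1, 1_500_001, "eGFR", "rsZ")]))
        assert loci[0].novelty == "novel"

    def test_other_chromosome_ignored(self):
        loci = annotate_novelty(self.locus(chrom=2), self.catalog([(1, 1_000_000, "eGFR", "rsW")]))
        assert loci[0].novelty == "novel"

    def test_empty_catalog_all_novel(self):
        loci = annotate_novelty(self.locus(), self.catalog([]))
        assert loci[0].novelty == "novel"

    def test_build_mismatch_rejected(self):
        cat = self.catalog([(1, 5, "t", "s")])
        cat.build = "GRCh37"
        with pytest.raises(ValueError, match="build"):
            annotate_novelty(self.locus(), cat)


class TestWorkedExampleReplay:
    def test_all_42_lead_variants_pass_the_three_criteria(self):
        table = novel_locus_table()
        assert len(table) == 42
        for _, row in table.iterrows():
            pvals = {
                t: row[f"P_{t}"]
                for t in ("eGFRcr", "eGFRcys", "sRAGE")
                if np.isfinite(row[f"P_{t}"])
            }
            assert set(row["SUBSET"].split("_")) == set(pvals)
            ok, reasons = pleiotropy_filter(pvals, row["P_CMA"])
            assert ok, f"{row['MARKER']}: {reasons}"

    def test_subset_classification_counts(self):
        counts = novel_locus_table()["SUBSET"].map(classify_trait_set).value_counts()
        assert counts["cr_cys_sRAGE"] == 17
        assert counts["cr_cys"] == 19
        assert counts["cr_sRAGE"] == 2
        assert counts["cys_sRAGE"] == 4

    def test_gene_table_thresholds(self):
        genes = pleiotropic_gene_table(headline_only=True)
        thr = bonferroni_threshold(N_TWAS_GENES)
        assert len(genes) == 17
        assert (genes["P_CMA"] < thr).all()
        assert int(genes["SINGLE_TRAIT_SIG"].sum()) == 4
        single = genes[genes["SINGLE_TRAIT_SIG"]]
        assert (
            (single[["P_eGFRcr", "P_eGFRcys"]].min(axis=1) < thr)
        ).all()

    def test_gene_rule_ambiguity_is_confined_to_one_gene(self):
        """Exactly one reported gene violates the strict-minimum rule."""
        genes = pleiotropic_gene_table(headline_only=True)
        violations = []
        for _, row in genes.iterrows():
            pvals = [row[f"P_{t}"] for t in ("eGFRcr", "eGFRcys", "sRAGE")
                     if np.isfinite(row[f"P_{t}"])]
            if not row["P_CMA"] < min(pvals):
                violations.append(row["GENE"])
        assert violations == ["LSP1"]


class TestSummarize:
    def test_counts_and_tables(self):
        df = hits_frame([
            ("a", 1, 1_000_000, "eGFRcr_eGFRcys", 1e-11, 1e-4, 1e-10),
            ("b", 2, 3_000_000, "eGFRcr_eGFRcys_sRAGE", 1e-10, 1e-4, 1e-9),
        ])
        df["P_sRAGE"] = [np.nan, 1e-3]
        loci = annotate_novelty(clump(df), Catalog(entries=pd.DataFrame(columns=["CHR", "POS"])))
        rep = summarize(loci)
        assert rep["n_loci"] == 2 and rep["n_novel"] == 2
        assert rep["counts_by_subset"] == {"cr_cys": 1, "cr_cys_sRAGE": 1}
        assert len(rep["locus_table"]) == 2

    def test_empty_inputs(self):
        rep = summarize([])
        assert rep["n_loci"] == 0 and rep["counts_by_subset"] == {}
        assert rep["locus_table"].empty
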