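"""Collapsing, the 2x2 chi-squared/OR machinery, replication, multi-hit carriers."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tinvar import burden as tb
from tinvar.classify import VariantClass
from tinvar.errors import CapabilityError, ValidationError
from tinvar.io import AnnotatedVariant, VcfCohort


def _variant(gene, csq, ac, panel_ac=0, cadd=None, pos=100):
    return AnnotatedVariant("1", pos, "A", "G", gene, csq, cadd, ac, 194,
                            {"REF": (panel_ac, 2000)})


def chi2_oracle(a, b, c, d):
    """Independent brute-force Pearson statistic: sum (O-E)^2/E over four cells."""
    obs = np.array([[a, b], [c, d]], float)
    n = obs.sum()
    exp = np.outer(obs.sum(1), obs.sum(0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


class TestCollapse:
    def test_case_alleles_summed_per_gene(self):
        variants = [
            _variant("GENE1", "stop_gained", 2, pos=100),
            _variant("GENE1", "frameshift_variant", 1, pos=200),
            _variant("GENE2", "stop_gained", 5, pos=300),
        ]
        (g1, g2) = tb.collapse(variants, 97, "REF", 2000, VariantClass.LOF)
        assert (g1.gene, g1.case_alleles, g1.case_allele_number) == ("GENE1", 3, 194)
        assert g1.n_variants == 2
        assert g2.case_alleles == 5

    def test_other_class_emits_no_row_under_lof_filter(self):
        variants = [_variant("GENE1", "intron_variant", 4)]
        assert tb.collapse(variants, 97, "REF", 2000, VariantClass.LOF) == []

    def test_sites_absent_from_panel_count_zero_against_declared_total(self):
        variants = [AnnotatedVariant("1", 1, "A", "G", "GENE1", "stop_gained",
                                     None, 2, 194, {})]
        (row,) = tb.collapse(variants, 97, "REF", 2000, VariantClass.LOF)
        assert (row.panel_alleles, row.panel_allele_number) == (0, 2000)

    def test_damaging_only_restricts_missense(self):
        variants = [
            _variant("GENE1", "missense_variant", 1, cadd=25.0, pos=100),
            _variant("GENE1", "missense_variant", 1, cadd=10.0, pos=200),
        ]
        (row,) = tb.collapse(variants, 97, "REF", 2000, VariantClass.MISSENSE,
                             damaging_only=True)
        assert row.case_alleles == 1 and row.n_variants == 1


class TestBurdenTest:
    def test_chi2_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, _ = tb.chi2_2x2(a, b, c, d)
            assert stat == pytest.approx(chi2_oracle(a, b, c, d), rel=1e-9)

    def test_chi2_matches_scipy_without_correction(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 300, size=4)
            stat, p = tb.chi2_2x2(a, b, c, d)
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_symmetric_table_gives_or_one_p_one(self):
        counts = tb.CollapsedGeneCount("G", VariantClass.LOF, 10, 200, 10, 200, 1)
        res = tb.burden_test(counts)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_haldane_anscombe_applied_only_with_zero_cell(self):
        or_, lo, hi = tb.odds_ratio_wald(0, 194, 5, 1995)
        expect = (0.5 * 1995.5) / (194.5 * 5.5)
        assert or_ == pytest.approx(expect, rel=1e-12)
        assert lo < or_ < hi
        or_plain, _, _ = tb.odds_ratio_wald(3, 191, 5, 1995)
        assert or_plain == pytest.approx((3 * 1995) / (191 * 5), rel=1e-12)

    def test_chi2_uses_raw_cells_not_corrected_ones(self):
        counts = tb.CollapsedGeneCount("G", VariantClass.LOF, 0, 194, 5, 2000, 1)
        res = tb.burden_test(counts)
        assert res.chi2 == pytest.approx(chi2_oracle(0, 194, 5, 1995), rel=1e-9)

    def test_degenerate_table_is_p_one(self):
        counts = tb.CollapsedGeneCount("G", VariantClass.LOF, 0, 194, 0, 2000, 1)
        res = tb.burden_test(counts)
        assert res.p_value == 1.0 and res.chi2 == 0.0 and not res.enriched

    def test_zero_allele_number_rejected(self):
        counts = tb.CollapsedGeneCount("G", VariantClass.LOF, 0, 0, 0, 2000, 1)
        with pytest.raises(ValidationError):
            tb.burden_test(counts)

    def test_or_strictly_increases_with_case_alleles(self):
        prev = 0.0
        for a in range(1, 40):
            counts = tb.CollapsedGeneCount("G", VariantClass.LOF, a, 194, 20, 2000, 1)
            res = tb.burden_test(counts)
            assert res.odds_ratio > prev
            prev = res.odds_ratio

    def test_fisher_and_chi2_agree_in_rank_order_on_well_filled_tables(self):
        rng = np.random.default_rng(3)
        chi2_p, fisher_p = [], []
        for _ in range(200):
            a, b, c, d = rng.integers(5, 200, size=4)
            chi2_p.append(tb.chi2_2x2(a, b, c, d)[1])
            fisher_p.append(stats.fisher_exact([[a, b], [c, d]])[1])
        rho = stats.spearmanr(chi2_p, fisher_p).statistic
        assert rho >= 0.99


class TestRunGba:
    def test_empty_variant_list_gives_empty_table(self):
        df = tb.run_gba([], n_cases=97, panels={"REF": 2000})
        assert df.empty

    def test_output_sorted_by_p_then_or_then_gene(self, study):
        df = tb.run_gba(study["cohort"].cohort, constraint=study["constraint"])
        ps = df["p"].to_numpy()
        assert (np.diff(ps) >= -1e-15).all()
        # within tied p, OR descending
        for _, grp in df.groupby("p"):
            assert (np.diff(grp["OR"].to_numpy()) <= 1e-12).all()

    def test_planted_enriched_genes_recovered(self, study):
        """Strongly planted (missense, OR >= 3.4) genes are flagged; every
        planted gene shows an odds ratio above 1 in its planted class. The
        population-level power claims are exercised in the acceptance suite."""
        df = tb.run_gba(study["cohort"].cohort, constraint=study["constraint"])
        truth = study["cohort"].ground_truth.genes
        planted = truth[truth.enriched]
        for _, row in planted.iterrows():
            hit = df[(df.gene == row.gene) & (df["class"] == row.variant_class)].iloc[0]
            assert hit.OR > 1, f"{row.gene} shows no excess"
            if row.variant_class == "MISSENSE" and row.target_or >= 3.4:
                assert bool(hit.enriched), f"{row.gene} not flagged"

    def test_intolerant_flags_attached(self, study):
        df = tb.run_gba(study["cohort"].cohort, constraint=study["constraint"])
        enriched_gene = study["config"].enriched_genes[0].gene
        row = df[df.gene == enriched_gene].iloc[0]
        assert bool(row.pli) and bool(row.loeuf)

    def test_adjusted_p_column_optional(self, study):
        df = tb.run_gba(study["cohort"].cohort, adjust="bh")
        assert "p_bh" in df.columns
        assert (df["p_bh"] >= df["p"] - 1e-15).all()


class TestReplicate:
    @staticmethod
    def _frame(rows):
        cols = ["gene", "class", "panel", "enriched"]
        return pd.DataFrame(rows, columns=cols)

    def test_one_panel_each_side_suffices(self):
        disc = self._frame([("G1", "MISSENSE", "A", True),
                            ("G1", "MISSENSE", "B", False)])
        repl = self._frame([("G1", "MISSENSE", "B", True)])
        out = tb.replicate(disc, repl)
        assert list(out.gene) == ["G1"]
        assert out.iloc[0].discovery_panels == "A"
        assert out.iloc[0].replication_panels == "B"

    def test_discovery_only_is_not_replicated(self):
        disc = self._frame([("G1", "MISSENSE", "A", True)])
        repl = self._frame([("G1", "MISSENSE", "A", False)])
        assert tb.replicate(disc, repl).empty

    def test_class_must_match(self):
        disc = self._frame([("G1", "LOF", "A", True)])
        repl = self._frame([("G1", "MISSENSE", "A", True)])
        assert tb.replicate(disc, repl).empty

    def test_disjoint_gene_sets_empty(self):
        disc = self._frame([("G1", "MISSENSE", "A", True)])
        repl = self._frame([("G2", "MISSENSE", "A", True)])
        assert tb.replicate(disc, repl).empty


class TestMultiHit:
    @staticmethod
    def _cohort():
        variants = [
            _variant("GENE1", "stop_gained", 1, pos=100),
            _variant("GENE1", "stop_gained", 2, pos=200),
            _variant("GENE2", "stop_gained", 2, pos=300),
        ]
        genotypes = np.array([
            [1, 0, 0],   # S1 het at site 1
            [1, 1, 0],   # S1 and S2 het at site 2
            [0, 2, 0],   # S2 homozygous at a single GENE2 site
        ], dtype=np.int8)
        return VcfCohort(variants, ["S1", "S2", "S3"], genotypes)

    def test_two_het_sites_in_same_gene_listed(self):
        out = tb.find_multihit_carriers(self._cohort(), ["GENE1", "GENE2"])
        assert [(m.subject, m.gene, m.n_sites) for m in out] == [("S1", "GENE1", 2)]

    def test_homozygous_single_site_does_not_qualify(self):
        out = tb.find_multihit_carriers(self._cohort(), ["GENE2"])
        assert out == []

    def test_no_listed_genes_empty(self):
        assert tb.find_multihit_carriers(self._cohort(), []) == []

    def test_requires_genotypes(self):
        cohort = VcfCohort([_variant("GENE1", "stop_gained", 1)], [], None)
        with pytest.raises(CapabilityError):
            tb.find_multihit_carriers(cohort, ["GENE1"])
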