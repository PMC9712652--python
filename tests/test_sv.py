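"""SV filters, interval math against per-base oracles, ACMG rubric, carrier burden."""
import numpy as np
import pytest

from tinvar import sv as tsv
from tinvar.errors import ConfigError, ValidationError
from tinvar.io import GeneConstraint, RegionSet, StructuralVariantCall


def _sv(start, end, sv_type="DEL", **kw):
    return StructuralVariantCall("c1", start, end, sv_type, **kw)


def covered_fraction_oracle(sv, intervals):
    """Brute-force per-base coverage of the SV by the interval union."""
    bases = np.zeros(sv.length, dtype=bool)
    for s, e in intervals:
        lo, hi = max(s, sv.start), min(e, sv.end)
        if hi > lo:
            bases[lo - sv.start:hi - sv.start] = True
    return bases.mean()


def reciprocal_oracle(a, b):
    bases_a = set(range(a.start, a.end))
    inter = len(bases_a & set(range(b.start, b.end)))
    return inter / max(a.length, b.length)


class TestSizeFilter:
    def test_window_boundaries(self):
        below = _sv(0, 999)
        at_min = _sv(0, 1000)
        at_max = _sv(0, 1_000_000)
        above = _sv(0, 2_000_000)
        kept, oversized = tsv.filter_by_size([below, at_min, at_max, above])
        assert kept == [at_min, at_max]
        assert oversized == [above]

    def test_oversized_survives_only_via_known_concordance(self):
        big = _sv(0, 2_000_000)
        kept, oversized = tsv.filter_by_size([big])
        assert kept == []
        assert tsv.filter_known(oversized, [_sv(0, 2_000_000)]) == [big]
        assert tsv.filter_known(oversized, [_sv(0, 1_500_000)]) == []

    def test_inverted_window_rejected(self):
        with pytest.raises(ConfigError):
            tsv.filter_by_size([], 1000, 1000)


class TestCoveredFraction:
    def test_identity(self):
        assert tsv.covered_fraction(_sv(100, 200), RegionSet("r", [("c1", 100, 200)])) == 1.0

    def test_adjacent_fragments_union(self):
        rs = RegionSet("r", [("c1", 0, 30), ("c1", 30, 60)])
        assert tsv.covered_fraction(_sv(0, 100), rs) == pytest.approx(0.6)

    def test_no_overlap(self):
        assert tsv.covered_fraction(_sv(0, 100), RegionSet("r", [("c1", 200, 300)])) == 0.0

    def test_overlapping_regions_not_double_counted(self):
        rs = RegionSet("r", [("c1", 0, 50), ("c1", 25, 60)])
        assert tsv.covered_fraction(_sv(0, 100), rs) == pytest.approx(0.6)

    def test_matches_per_base_oracle_on_random_configurations(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            s = int(rng.integers(0, 500))
            sv = _sv(s, s + int(rng.integers(1, 400)))
            intervals = []
            for _ in range(rng.integers(0, 8)):
                rs_ = int(rng.integers(0, 900))
                intervals.append((rs_, rs_ + int(rng.integers(1, 300))))
            rs = RegionSet("r", [("c1", a, b) for a, b in intervals])
            assert tsv.covered_fraction(sv, rs) == pytest.approx(
                covered_fraction_oracle(sv, intervals), abs=1e-12)

    def test_invariant_under_fragmentation(self):
        rng = np.random.default_rng(5)
        sv = _sv(0, 1000)
        whole = RegionSet("w", [("c1", 100, 700)])
        cuts = sorted(rng.integers(101, 700, size=4).tolist())
        pieces = RegionSet("p", [("c1", a, b) for a, b in
                                 zip([100] + cuts, cuts + [700])])
        assert tsv.covered_fraction(sv, pieces) == pytest.approx(
            tsv.covered_fraction(sv, whole), abs=1e-12)


class TestArtifactFilter:
    def test_strictly_above_threshold_dropped(self):
        rs = RegionSet("bl", [("c1", 0, 661)])
        assert tsv.filter_artifacts([_sv(0, 1000)], rs) == []

    def test_exactly_at_threshold_kept(self):
        rs = RegionSet("bl", [("c1", 0, 660)])
        sv = _sv(0, 1000)
        assert tsv.filter_artifacts([sv], rs) == [sv]

    def test_empty_blacklist_keeps_all(self):
        svs = [_sv(0, 1000), _sv(5000, 9000)]
        assert tsv.filter_artifacts(svs, RegionSet("bl")) == svs


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        assert tsv.reciprocal_overlap(_sv(0, 100), _sv(0, 100)) == 1.0

    def test_boundary_99(self):
        assert tsv.reciprocal_overlap(_sv(0, 1000), _sv(0, 990)) == pytest.approx(0.99)
        assert tsv.filter_known([_sv(0, 1000)], [_sv(0, 990)]) == [_sv(0, 1000)]
        assert tsv.filter_known([_sv(0, 1000)], [_sv(0, 989)]) == []

    def test_type_mismatch_never_matches(self):
        assert tsv.filter_known([_sv(0, 1000, "DEL")], [_sv(0, 1000, "DUP")]) == []

    def test_symmetric(self):
        a, b = _sv(0, 500), _sv(250, 900)
        assert tsv.reciprocal_overlap(a, b) == tsv.reciprocal_overlap(b, a)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            s1, s2 = rng.integers(0, 400, size=2)
            a = _sv(int(s1), int(s1) + int(rng.integers(1, 300)))
            b = _sv(int(s2), int(s2) + int(rng.integers(1, 300)))
            assert tsv.reciprocal_overlap(a, b) == pytest.approx(
                reciprocal_oracle(a, b), abs=1e-12)


class TestAcmg:
    def test_benign_overlap_dropped(self):
        sv = _sv(0, 1000, evidence={"benign_region_overlap": True})
        assert tsv.classify_acmg(sv) <= 2
        assert tsv.retain_reportable([sv]) == []

    def test_constrained_deletion_is_vus_and_kept(self):
        sv = _sv(0, 1000, evidence={"constrained_gene_overlap": True})
        assert tsv.classify_acmg(sv) == 3
        assert tsv.retain_reportable([sv]) == [sv]

    def test_dosage_sensitive_loss_is_likely_pathogenic(self):
        assert tsv.classify_acmg(_sv(0, 1000, evidence={"dosage_sensitive_loss": True})) == 4
        assert tsv.classify_acmg(
            _sv(0, 1000, evidence={"dosage_sensitive_loss_established": True})) == 5

    def test_deterministic(self):
        sv = _sv(0, 1000, evidence={"constrained_gene_overlap": True})
        assert tsv.classify_acmg(sv) == tsv.classify_acmg(sv)

    def test_unknown_evidence_key_is_config_error_naming_it(self):
        sv = _sv(0, 1000, evidence={"misspelled_flag": True})
        with pytest.raises(ConfigError, match="misspelled_flag"):
            tsv.classify_acmg(sv)


class TestConstrainedOverlap:
    GENES = {"G1": ("c1", 0, 1000), "G2": ("c1", 5000, 6000)}

    def test_high_constraint_gene_hit(self):
        cmap = {"G1": GeneConstraint("G1", 0.95, 0.2, 1)}
        assert tsv.constrained_overlap(_sv(500, 700), cmap, self.GENES) == (True, ["G1"])

    def test_bin_boundary_strict(self):
        cmap = {"G1": GeneConstraint("G1", 0.95, 0.2, 2)}
        assert tsv.constrained_overlap(_sv(500, 700), cmap, self.GENES) == (False, [])

    def test_pli_boundary_strict(self):
        cmap = {"G1": GeneConstraint("G1", 0.9, 0.2, 1)}
        assert tsv.constrained_overlap(_sv(500, 700), cmap, self.GENES) == (False, [])

    def test_no_gene_overlap(self):
        cmap = {"G1": GeneConstraint("G1", 0.95, 0.2, 1)}
        assert tsv.constrained_overlap(_sv(2000, 3000), cmap, self.GENES) == (False, [])


class TestUltraRare:
    def test_boundary_inclusive(self):
        sv = _sv(0, 1000, carriers={"reference": 1}, cohort_sizes={"reference": 1000})
        assert tsv.flag_ultra_rare(sv) is True

    def test_common_reference_sv(self):
        sv = _sv(0, 1000, carriers={"reference": 17}, cohort_sizes={"reference": 1000})
        assert tsv.flag_ultra_rare(sv) is False

    def test_absent_from_reference_is_ultra_rare(self):
        sv = _sv(0, 1000, carriers={"cases": 2}, cohort_sizes={"cases": 97})
        assert tsv.flag_ultra_rare(sv) is True


class TestSvBurden:
    @staticmethod
    def _recurrent_del():
        return _sv(129087937, 129089566,
                   carriers={"cases": 21, "severe": 8, "reference": 17},
                   cohort_sizes={"cases": 97, "severe": 34, "reference": 1000})

    def test_recurrent_deletion_frequencies_and_p(self):
        df = tsv.sv_burden([self._recurrent_del()])
        row = df.iloc[0]
        assert row.freq_case == pytest.approx(0.216)
        assert row.freq_severe == pytest.approx(0.235)
        assert row.freq_ref == pytest.approx(0.017)
        assert row.p < 0.001

    def test_degenerate_all_zero_table(self):
        sv = _sv(0, 1000, carriers={"cases": 0, "reference": 0},
                 cohort_sizes={"cases": 97, "reference": 1000})
        row = tsv.sv_burden([sv]).iloc[0]
        assert row.p == 1.0
        assert np.isnan(row.OR)

    def test_missing_cohort_size_rejected(self):
        sv = _sv(0, 1000, carriers={"cases": 1}, cohort_sizes={"cases": 97})
        with pytest.raises(ValidationError, match="reference"):
            tsv.sv_burden([sv])

    def test_grouped_burden_pools_carriers(self):
        svs = [self._recurrent_del(), self._recurrent_del()]
        df = tsv.sv_burden_grouped(svs)
        row = df.iloc[0]
        assert row.carriers_case == 42 and row.carriers_ref == 34
        assert row.n_svs == 2


class TestPipelineComposition:
    def test_sequential_equals_joint_filtering(self, study):
        """Each stage is a pure predicate: order of application cannot matter."""
        from tinvar import simulate as sim
        cfg = study["config"]
        cs = sim.generate_sv_callset(cfg)
        blacklist, known = cs.blacklist, cs.known_svs
        in_window, oversized = tsv.filter_by_size(cs.svs)
        seq = tsv.filter_known(
            tsv.filter_artifacts(in_window + tsv.filter_known(oversized, known),
                                 blacklist), known)
        joint = [sv for sv in cs.svs
                 if (1000 <= sv.length <= 1_000_000
                     or tsv.best_reciprocal_overlap(sv, known) >= 0.99)
                 and sv.length >= 1000
                 and tsv.covered_fraction(sv, blacklist) <= 0.66
                 and tsv.best_reciprocal_overlap(sv, known) >= 0.99]
        assert [s.ident for s in seq] == [s.ident for s in joint]

    def test_planted_deletion_tops_table(self, study):
        from tinvar import simulate as sim
        cfg = study["config"]
        cs = sim.generate_sv_callset(cfg)
        table, tallies = tsv.run_sv_pipeline(
            cs.svs, cs.blacklist, cs.known_svs, study["constraint"], cs.gene_intervals)
        planted = cs.ground_truth.svs.query("planted_recurrent").ident.iloc[0]
        assert table.ident.iloc[0] == planted
        assert tallies["input"] == len(cs.svs)
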