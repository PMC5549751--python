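"""Subsampling distributions, consistency/bootstrap checks, quantile and RPM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mlseq.core_io import ReadSet, exact_match
from mlseq.normalization import (
    DEFAULT_FRACTIONS,
    ConsistencyReport,
    bootstrap_fixed_total,
    incremental_consistency_check,
    needs_quantile_correction,
    quantile_normalize,
    remove_ncrna_reads,
    rpm_scale,
    subsample_with_replacement,
    subsample_without_replacement,
)


class TestSubsampleWithoutReplacement:
    def test_full_target_is_identity(self):
        rs = ReadSet({"AAAA": 3, "CCCC": 2}, 4)
        out = subsample_without_replacement(rs, rs.R, seed=0)
        assert out.counts == rs.counts

    def test_totals_sum_exactly_to_target(self):
        rs = ReadSet({"AAAA": 50, "CCCC": 30, "GGGG": 20}, 4)
        for seed in range(20):
            assert subsample_without_replacement(rs, 37, seed).R == 37

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_counts_never_exceed_originals(self, seed):
        rs = ReadSet({"AAAA": 9, "CCCC": 5, "GGGG": 1, "TTTT": 25}, 4)
        out = subsample_without_replacement(rs, 17, seed)
        assert all(out.counts[s] <= rs.counts[s] for s in out.counts)

    def test_single_draw_probability_matches_hypergeometric(self):
        """Drawing 1 read from {A x3, C x1} selects A with probability 3/4."""
        rs = ReadSet({"AAAA": 3, "CCCC": 1}, 4)
        rng = np.random.default_rng(7)
        n = 10_000
        hits = sum(
            "AAAA" in subsample_without_replacement(rs, 1, rng).counts for _ in range(n)
        )
        # 3 sigma binomial band around p = 0.75
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se

    def test_mean_and_variance_match_hypergeometric(self):
        counts = {"A" * 4: 40, "C" * 4: 25, "G" * 4: 20, "T" * 4: 15}
        rs = ReadSet(counts, 4)
        target, n_rep = 60, 1500
        rng = np.random.default_rng(11)
        draws = np.array(
            [
                [subsample_without_replacement(rs, target, rng).counts.get(s, 0)
                 for s in counts]
                for _ in range(n_rep)
            ],
            dtype=float,
        )
        R = rs.R
        for j, (seq, c) in enumerate(counts.items()):
            mean = target * c / R
            var = target * (c / R) * (1 - c / R) * (R - target) / (R - 1)
            se_mean = np.sqrt(var / n_rep)
            assert abs(draws[:, j].mean() - mean) < 3 * se_mean
            # sample variance of a bounded variable: allow a 20% band
            assert draws[:, j].var(ddof=1) == pytest.approx(var, rel=0.2)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_without_replacement(ReadSet({"AAAA": 3}, 4), 4 + 1, 0)


class TestSubsampleWithReplacement:
    def test_single_unique_read_gets_full_target(self):
        out = subsample_with_replacement(ReadSet({"ACGT": 5}, 4), 12, 0)
        assert out.counts == {"ACGT": 12}

    def test_mean_and_variance_match_multinomial(self):
        counts = {"A" * 4: 40, "C" * 4: 25, "G" * 4: 20, "T" * 4: 15}
        rs = ReadSet(counts, 4)
        target, n_rep = 60, 1500
        rng = np.random.default_rng(13)
        draws = np.array(
            [
                [subsample_with_replacement(rs, target, rng).counts.get(s, 0)
                 for s in counts]
                for _ in range(n_rep)
            ],
            dtype=float,
        )
        R = rs.R
        for j, (seq, c) in enumerate(counts.items()):
            p = c / R
            mean, var = target * p, target * p * (1 - p)
            assert abs(draws[:, j].mean() - mean) < 3 * np.sqrt(var / n_rep)
            assert draws[:, j].var(ddof=1) == pytest.approx(var, rel=0.2)

    def test_absence_probability_matches_closed_form(self):
        """P(read with count c absent) = (1 - c/R)^target."""
        rs = ReadSet({"AAAA": 2, "CCCC": 98}, 4)
        target, n_rep = 30, 4000
        rng = np.random.default_rng(17)
        absent = sum(
            "AAAA" not in subsample_with_replacement(rs, target, rng).counts
            for _ in range(n_rep)
        )
        p_absent = (1 - 2 / 100) ** target
        se = np.sqrt(p_absent * (1 - p_absent) / n_rep)
        assert abs(absent / n_rep - p_absent) < 3 * se

    def test_can_exceed_original_counts_on_skewed_sets(self):
        rs = ReadSet({"AAAA": 1, "CCCC": 99}, 4)
        rng = np.random.default_rng(19)
        exceeded = any(
            subsample_with_replacement(rs, 100, rng).counts.get("AAAA", 0) > 1
            for _ in range(200)
        )
        assert exceeded

    def test_empty_readset_rejected(self):
        with pytest.raises(ValueError):
            subsample_with_replacement(ReadSet({}, 0), 5, 0)


def test_without_replacement_variance_below_with_replacement():
    """Finite-population correction: hypergeometric variance <= binomial."""
    counts = {"A" * 4: 30, "C" * 4: 20, "G" * 4: 10}
    rs = ReadSet(counts, 4)
    target, n_rep = 30, 2000
    rng = np.random.default_rng(23)
    var = {}
    for label, fn in (("wor", subsample_without_replacement),
                      ("wr", subsample_with_replacement)):
        draws = np.array(
            [[fn(rs, target, rng).counts.get(s, 0) for s in counts]
             for _ in range(n_rep)],
            dtype=float,
        )
        var[label] = draws.var(axis=0, ddof=1)
    assert (var["wor"] < var["wr"]).all()


class TestIncrementalConsistencyCheck:
    def test_default_fractions_enumerate_95_down_to_45(self):
        assert list(DEFAULT_FRACTIONS) == pytest.approx(
            [0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55, 0.50, 0.45]
        )
        assert len(DEFAULT_FRACTIONS) == 11

    def test_fully_mapping_sample_keeps_full_matching_proportion(
        self, study, study_ann, study_alignments
    ):
        s = next(iter(study.readsets))
        rep = incremental_consistency_check(
            study.readsets[s], study_alignments[s], study_ann, seed=1
        )
        assert len(rep.table) == 11
        assert np.allclose(rep.table["pct_genome_matching"], 100.0)

    def test_complexity_increases_as_fraction_decreases(
        self, study, study_ann, study_alignments
    ):
        """Subsampling thins duplicates, so expected complexity rises; checked
        as a trend (rank correlation) rather than per-draw monotonicity."""
        from scipy.stats import spearmanr

        s = next(iter(study.readsets))
        rep = incremental_consistency_check(
            study.readsets[s], study_alignments[s], study_ann, seed=2
        )
        rho = spearmanr(rep.table["fraction"], rep.table["complexity"]).statistic
        assert rho < -0.9

    def test_verdict_applies_both_stated_criteria(self):
        table = pd.DataFrame(
            {
                "fraction": [0.95, 0.45],
                "R": [95, 45],
                "NR": [90, 44],
                "complexity": [0.95, 0.97],
                "pct_genome_matching": [90.0, 90.3],
                "mean_p2ppcc": [0.99, 0.97],
            }
        )
        ok = ConsistencyReport(table, 90.0, 0.005, 0.95)
        assert ok.passed
        drift = ConsistencyReport(table.assign(pct_genome_matching=[90.0, 91.0]),
                                  90.0, 0.005, 0.95)
        assert not drift.passed
        weak = ConsistencyReport(table.assign(mean_p2ppcc=[0.99, 0.80]),
                                 90.0, 0.005, 0.95)
        assert not weak.passed

    def test_sparse_coverage_fails_p2p_criterion(self, study_ann, study):
        """A very shallow library cannot preserve coverage shape under
        subsampling: the mean p2pPCC criterion (> 0.95) fails."""
        rng = np.random.default_rng(31)
        s = next(iter(study.readsets))
        rs = study.readsets[s]
        thin = subsample_without_replacement(rs, 300, 0)
        al = exact_match(thin, study.genome)
        rep = incremental_consistency_check(thin, al, study_ann, seed=3)
        assert not rep.passed
        assert (rep.table["mean_p2ppcc"] < 0.95).any()


class TestBootstrapFixedTotal:
    def test_draws_sum_exactly_and_pass_on_homogeneous_sample(
        self, study, study_ann, study_alignments
    ):
        s = next(iter(study.readsets))
        rs = study.readsets[s]
        res = bootstrap_fixed_total(
            rs, study_alignments[s], study_ann, int(0.8 * rs.R), n_boot=5, seed=4
        )
        assert res.readset.R == res.target
        assert res.passed and not res.requires_review
        assert (res.bootstrap_pcc > 0.95).all()

    def test_below_min_fraction_flagged_for_review(
        self, study, study_ann, study_alignments
    ):
        s = next(iter(study.readsets))
        rs = study.readsets[s]
        with pytest.warns(UserWarning, match="case-by-case"):
            res = bootstrap_fixed_total(
                rs, study_alignments[s], study_ann, int(0.4 * rs.R), n_boot=3, seed=5
            )
        assert res.requires_review

    def test_target_above_depth_rejected(self, study, study_ann, study_alignments):
        s = next(iter(study.readsets))
        with pytest.raises(ValueError):
            bootstrap_fixed_total(
                study.readsets[s], study_alignments[s], study_ann,
                study.readsets[s].R + 1, seed=6,
            )


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        expr = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        assert np.allclose(quantile_normalize(expr), expr)

    def test_two_column_mean_of_sorted(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(expr)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_matches_limma_reference_with_ties(self):
        """Frozen oracle: limma::normalizeQuantiles on the same matrix."""
        expr = pd.DataFrame(
            np.array([[5, 4, 3], [2, 1, 4], [3, 4, 6], [4, 2, 8]], dtype=float)
        )
        expected = np.array(
            [
                [5.666667, 5.166667, 2.000000],
                [2.000000, 2.000000, 3.000000],
                [3.000000, 5.166667, 4.666667],
                [4.666667, 3.000000, 5.666667],
            ]
        )
        assert np.allclose(quantile_normalize(expr), expected, atol=1e-6)

    def test_columns_share_sorted_values_and_ranks_preserved(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.lognormal(2, 1, size=(50, 4)))
        out = quantile_normalize(expr)
        ref = np.sort(out.iloc[:, 0].values)
        for j in range(1, 4):
            assert np.allclose(np.sort(out.iloc[:, j].values), ref)
            assert (out.iloc[:, j].rank() - expr.iloc[:, j].rank()).abs().max() == 0

    def test_idempotent_on_tie_free_data(self):
        """Exact idempotence holds for continuous (tie-free) data; with ties
        the reference implementation (limma) drifts identically, since tied
        entries receive rank-averaged reference values."""
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.lognormal(2, 1, size=(30, 3)))
        once = quantile_normalize(expr)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestRpmScale:
    def test_equal_depths_identity(self):
        expr = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = rpm_scale(expr, {"a": 10, "b": 10})
        assert np.allclose(out, expr)

    def test_mean_depth_scaling(self):
        expr = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 6.0]})
        out = rpm_scale(expr, {"a": 10, "b": 30})
        assert np.allclose(out["a"], [2.0, 4.0])
        assert np.allclose(out["b"], [2.0, 4.0])

    def test_column_sums_equal_when_matrix_holds_all_reads(self):
        expr = pd.DataFrame({"a": [6.0, 4.0], "b": [20.0, 10.0]})
        out = rpm_scale(expr, {"a": 10.0, "b": 30.0})
        assert out["a"].sum() == pytest.approx(out["b"].sum())

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            rpm_scale(pd.DataFrame({"a": [1.0]}), {"a": 0})


class TestNcrnaRemoval:
    def test_ncrna_incident_reads_dropped(self, study, study_ann, study_alignments):
        s = next(iter(study.readsets))
        rs = study.readsets[s]
        filtered = remove_ncrna_reads(rs, study_alignments[s], study_ann)
        assert 0 < filtered.R < rs.R  # ncRNA loci carry ~5% of the library
        # no remaining read touches an ncRNA feature
        al = study_alignments[s].restrict(filtered.counts)
        for seq, chrom, start, end in zip(
            al.records["seq"], al.records["chrom"], al.records["start"], al.records["end"]
        ):
            assert not study_ann.overlaps_class("ncRNA", chrom, start, end)


def test_needs_quantile_correction_detects_distribution_shift():
    rng = np.random.default_rng(5)
    base = rng.lognormal(3, 1, size=300)
    aligned = pd.DataFrame({"a": base, "b": base.copy()})
    assert not needs_quantile_correction(aligned)
    shifted = pd.DataFrame({"a": base, "b": base * 2})
    assert needs_quantile_correction(shifted)
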