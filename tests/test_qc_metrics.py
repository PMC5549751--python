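"""Strand bias, complexity profiles, Jaccard/correlation, p2pPCC, offset and
replicate outlier detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mlseq import qc_metrics as qc
from mlseq.core_io import ReadSet
from mlseq.qc_metrics import (
    ComplexityDiffProfile,
    P2PProfile,
    complexity_diff_profile,
    correlation_matrix,
    estimate_offset,
    flag_outlier_replicates,
    jaccard_matrix,
    jaccard_topN,
    nucleotide_composition,
    p2p_pcc,
    p2p_profile,
    sample_complexity,
    strand_bias,
)
from conftest import make_alignment


class TestStrandBias:
    def test_balanced_reads_give_zero(self, toy_ann):
        al = make_alignment([("A" * 8, 11, "+", 5), ("B" * 8, 11, "-", 5)])
        assert strand_bias(al, toy_ann) == pytest.approx(0.0)

    def test_fully_stranded_gives_one(self, toy_ann):
        al = make_alignment([("A" * 8, 11, "+", 7)])
        assert strand_bias(al, toy_ann) == pytest.approx(1.0)

    def test_thirty_plus_ten_minus_gives_half(self, toy_ann):
        al = make_alignment([("A" * 8, 11, "+", 30), ("B" * 8, 12, "-", 10)])
        assert strand_bias(al, toy_ann) == pytest.approx(0.5)

    @pytest.mark.parametrize("plus,minus", [(30, 10), (1, 9), (4, 4), (13, 2)])
    def test_identity_with_two_p_form(self, toy_ann, plus, minus):
        """|P-0.5| + |N-0.5| equals 2|P-0.5| when P + N = 1."""
        al = make_alignment([("A" * 8, 11, "+", plus), ("B" * 8, 12, "-", minus)])
        p = plus / (plus + minus)
        assert strand_bias(al, toy_ann) == pytest.approx(2 * abs(p - 0.5))

    def test_no_cds_reads_is_na_with_warning(self, toy_ann):
        al = make_alignment([("A" * 8, 0, "+", 1)])  # intergenic only
        with pytest.warns(UserWarning):
            assert np.isnan(strand_bias(al, toy_ann))


class TestNucleotideComposition:
    def test_homogeneous_reads(self):
        comp = nucleotide_composition(ReadSet({"AAAA": 3}, 4))
        assert (comp["A"] == 1.0).all()

    def test_rows_sum_to_one(self):
        comp = nucleotide_composition(ReadSet({"ACGT": 2, "AATT": 5, "NGGA": 1}, 4))
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-12)

    def test_count_weighted_frequencies(self):
        comp = nucleotide_composition(ReadSet({"ACGT": 1, "AAAA": 3}, 4))
        assert comp.loc[2, "A"] == pytest.approx(0.75)
        assert comp.loc[2, "G"] == pytest.approx(0.25)


class TestSampleComplexity:
    @pytest.mark.parametrize(
        "counts,expected",
        [({"AAAA": 3, "CCCC": 1}, 0.5), ({"AAAA": 10}, 0.1),
         ({"AAAA": 1, "CCCC": 1, "GGGG": 1}, 1.0)],
    )
    def test_nr_over_r(self, counts, expected):
        assert sample_complexity(ReadSet(counts, 4)) == pytest.approx(expected)

    def test_empty_set_is_na(self):
        assert np.isnan(sample_complexity(ReadSet({}, 0)))


class TestComplexityDiffProfile:
    def test_identical_samples_have_zero_differences(self, toy_ann):
        al = make_alignment([("A" * 8, 6, "+", 4), ("B" * 8, 10, "+", 2)])
        prof = complexity_diff_profile(al, al, toy_ann)
        assert (prof.per_gene["dC"] == 0).all()

    def test_constructed_difference_above_reference_lines(self, toy_ann):
        # G1 in A: 2 unique of 5 reads (C=0.4); in B: 1 unique of 4 (C=0.25)
        alA = make_alignment([("A" * 8, 6, "+", 3), ("B" * 8, 10, "+", 2)])
        alB = make_alignment([("C" * 8, 6, "+", 4)])
        prof = complexity_diff_profile(alA, alB, toy_ann)
        dc = prof.per_gene["dC"].iloc[0]
        assert dc == pytest.approx(0.15)
        assert dc > max(prof.reference_lines)

    def test_disjoint_expression_yields_empty_profile(self, toy_ann):
        alA = make_alignment([("A" * 8, 6, "+", 1)])   # G1 only
        alB = make_alignment([("B" * 8, 45, "+", 1)])  # G2 only
        with pytest.warns(UserWarning):
            prof = complexity_diff_profile(alA, alB, toy_ann)
        assert prof.per_gene.empty and prof.n_exclusive == 2

    def test_hump_requires_min_run_of_consecutive_bins(self):
        per_gene = pd.DataFrame(
            {"abundance": [2, 4, 8, 16, 32], "bin": [1, 2, 3, 4, 5],
             "dC": [0.01, 0.2, 0.2, 0.2, 0.01]}
        )
        prof = ComplexityDiffProfile(per_gene)
        assert prof.hump_bins(min_run=3) == [2, 3, 4]
        assert prof.hump_bins(min_run=4) == []


class TestJaccard:
    def test_sample_against_itself_is_fully_similar(self):
        expr = pd.Series([5.0, 3.0, 1.0, 0.0], index=list("abcd"))
        assert jaccard_topN(expr, expr, n=3) == 1.0

    def test_disjoint_top_sets_are_zero(self):
        a = pd.Series({"a": 9, "b": 8, "c": 0, "d": 0})
        b = pd.Series({"a": 0, "b": 0, "c": 9, "d": 8})
        assert jaccard_topN(a, b, n=2) == 0.0

    def test_partial_overlap(self):
        a = pd.Series({"g1": 9, "g2": 8, "g3": 7, "g4": 1})
        b = pd.Series({"g1": 1, "g2": 9, "g3": 8, "g4": 7})
        assert jaccard_topN(a, b, n=3) == pytest.approx(0.5)

    def test_symmetry_and_tie_inclusion(self):
        a = pd.Series({"g1": 9, "g2": 5, "g3": 5, "g4": 1})
        b = pd.Series({"g1": 9, "g2": 5, "g3": 2, "g4": 1})
        assert jaccard_topN(a, b, 2) == jaccard_topN(b, a, 2)
        # ties at rank 2 in sample a include both g2 and g3
        assert jaccard_topN(a, b, 2) == pytest.approx(2 / 3)

    def test_fewer_expressed_than_n_warns(self):
        a = pd.Series({"g1": 1.0, "g2": 0.0})
        with pytest.warns(UserWarning, match="expressed"):
            assert jaccard_topN(a, a, n=5) == 1.0

    def test_matrix_symmetric_with_unit_diagonal(self, study, study_ann, study_alignments):
        from mlseq.core_io import gene_expression

        samples = list(study.readsets)[:4]
        expr = gene_expression({s: study_alignments[s] for s in samples}, study_ann)
        mat = jaccard_matrix(expr, n=10)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)


class TestCorrelationMatrix:
    @pytest.fixture
    def expr(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(rng.lognormal(3, 1, size=(30, 3)), columns=list("xyz"))

    def test_duplicated_sample_fully_correlated(self, expr):
        expr = expr.assign(w=expr["x"])
        for method in ("PCC", "SCC", "KCC"):
            mat = correlation_matrix(expr, method)
            assert mat.loc["x", "w"] == pytest.approx(1.0)

    def test_pcc_scale_invariance(self, expr):
        doubled = expr.assign(x2=2 * expr["x"])
        assert correlation_matrix(doubled, "PCC").loc["x", "x2"] == pytest.approx(1.0)

    def test_reversed_vector_perfectly_anticorrelated(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        assert correlation_matrix(expr, "PCC").loc["a", "b"] == pytest.approx(-1.0)

    def test_kcc_is_tau_b(self):
        from scipy.stats import kendalltau

        expr = pd.DataFrame({"a": [1.0, 2.0, 2.0, 4.0], "b": [1.0, 3.0, 2.0, 2.0]})
        expected = kendalltau(expr["a"], expr["b"]).statistic
        assert correlation_matrix(expr, "KCC").loc["a", "b"] == pytest.approx(expected)

    def test_unknown_method_rejected(self, expr):
        with pytest.raises(ValueError):
            correlation_matrix(expr, "cosine")


class TestP2PPcc:
    def test_identical_nonconstant_vectors(self):
        y = np.array([1.0, 5.0, 2.0, 0.0])
        assert p2p_pcc(y, y) == pytest.approx(1.0)

    def test_anticorrelated_exon_pattern(self):
        assert p2p_pcc(np.array([5, 5, 0, 0.0]), np.array([0, 0, 5, 5.0])) == pytest.approx(-1.0)

    def test_constant_or_zero_vector_is_na(self):
        assert np.isnan(p2p_pcc(np.zeros(4), np.array([1, 2, 3, 4.0])))
        assert np.isnan(p2p_pcc(np.full(4, 7.0), np.array([1, 2, 3, 4.0])))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p2p_pcc(np.zeros(4), np.zeros(5))

    @given(st.floats(0.1, 50), st.floats(0.0, 100))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_positive_affine_scaling(self, scale, shift):
        rng = np.random.default_rng(1)
        a, b = rng.random(20), rng.random(20)
        assert p2p_pcc(scale * a + shift, b) == pytest.approx(p2p_pcc(a, b), abs=1e-9)


class TestP2PProfile:
    def test_identical_samples_give_unit_correlations(self, toy_ann):
        al = make_alignment([("A" * 8, 6, "+", 4), ("B" * 8, 12, "+", 2)])
        prof = p2p_profile(al, al, toy_ann)
        defined = prof.per_gene["p2ppcc"].dropna()
        assert len(defined) > 0 and np.allclose(defined, 1.0)

    def test_high_depth_replicates_correlate_better_than_sparse(self, study_ann, study):
        """Coverage reproducibility grows with abundance: deep uniformly
        covered genes approach p2pPCC 1, one-read genes stay low/undefined."""
        from mlseq.core_io import exact_match

        rng = np.random.default_rng(5)
        samples = list(study.readsets)[:2]
        als = {s: exact_match(study.readsets[s], study.genome) for s in samples}
        prof = p2p_profile(als[samples[0]], als[samples[1]], study_ann)
        med = prof.bin_medians()
        assert med[med.index >= 8].min() > 0.8


def profile_from_bins(bins_to_median):
    per_gene = pd.DataFrame(
        {
            "abundance": [2.0 ** b for b in bins_to_median],
            "bin": list(bins_to_median),
            "p2ppcc": list(bins_to_median.values()),
        }
    )
    return P2PProfile(per_gene)


class TestEstimateOffset:
    def test_all_bins_passing_gives_lowest_edge(self):
        prof = profile_from_bins({2: 0.9, 3: 0.95, 4: 0.99})
        assert estimate_offset([prof], 0.7) == pytest.approx(4.0)

    def test_constructed_floor_near_twenty(self):
        """Bins below ~20 fail, bins above pass -> offset at the 2^4 edge."""
        prof1 = profile_from_bins({1: 0.3, 2: 0.5, 3: 0.6, 4: 0.8, 5: 0.9, 6: 0.95})
        prof2 = profile_from_bins({1: 0.2, 2: 0.4, 3: 0.65, 4: 0.75, 5: 0.85, 6: 0.9})
        assert estimate_offset([prof1, prof2], 0.7) == pytest.approx(16.0)

    def test_worst_pair_rule(self):
        good = profile_from_bins({3: 0.9, 4: 0.9, 5: 0.9})
        bad = profile_from_bins({3: 0.2, 4: 0.9, 5: 0.9})
        assert estimate_offset([good, bad], 0.7) == pytest.approx(16.0)

    def test_impossible_threshold_is_na(self):
        prof = profile_from_bins({2: 1.0, 3: 1.0})
        assert np.isnan(estimate_offset([prof], threshold=1.01))

    def test_monotone_non_decreasing_in_threshold(self):
        prof = profile_from_bins({1: 0.4, 2: 0.55, 3: 0.75, 4: 0.85, 5: 0.95})
        offsets = [estimate_offset([prof], t) for t in (0.3, 0.5, 0.7, 0.8, 0.9)]
        numeric = [o for o in offsets if not np.isnan(o)]
        assert numeric == sorted(numeric)
        assert np.isnan(estimate_offset([prof], 0.99))


class TestOutlierFlagging:
    def make_inputs(self, sim, n=3):
        """Three replicates in one condition, three in another; `sim` gives
        the pairwise similarity used for both jaccard and p2p sources."""
        design = pd.DataFrame(
            {
                "condition": ["c1"] * n + ["c2"] * n,
                "replicate": list(range(1, n + 1)) * 2,
            },
            index=[f"c1_r{i}" for i in range(1, n + 1)]
            + [f"c2_r{i}" for i in range(1, n + 1)],
        )
        samples = list(design.index)
        jac = pd.DataFrame(1.0, index=samples, columns=samples)
        for (a, b), v in sim.items():
            jac.loc[a, b] = jac.loc[b, a] = v
        return design, jac

    @staticmethod
    def flat_profile(dc=0.0):
        per_gene = pd.DataFrame(
            {"abundance": [8.0, 16, 32, 64, 128], "bin": [3, 4, 5, 6, 7],
             "dC": [dc] * 5}
        )
        return ComplexityDiffProfile(per_gene)

    def test_identical_replicates_not_flagged(self):
        design, jac = self.make_inputs({})
        profiles = {}
        for a in design.index:
            for b in design.index:
                profiles[(a, b)] = self.flat_profile(0.0)
        flags = flag_outlier_replicates(design, profiles, jac)
        assert not flags["flagged"].any()

    def test_perturbed_replicate_flagged(self):
        design, jac = self.make_inputs(
            {("c1_r3", "c1_r1"): 0.6, ("c1_r3", "c1_r2"): 0.6}
        )
        profiles = {}
        for a in design.index:
            for b in design.index:
                bad = "c1_r3" in (a, b) and a != b and {a, b} <= set(design.index[:3])
                profiles[(a, b)] = self.flat_profile(0.2 if bad else 0.01)
        flags = flag_outlier_replicates(design, profiles, jac).set_index("sample")
        assert flags.loc["c1_r3", "flagged"]
        assert not flags.drop(index="c1_r3")["flagged"].any()

    def test_equidistant_replicates_not_flagged(self):
        # humps everywhere but no similarity asymmetry: criterion (b) fails
        design, jac = self.make_inputs({})
        profiles = {}
        for a in design.index:
            for b in design.index:
                profiles[(a, b)] = self.flat_profile(0.2)
        flags = flag_outlier_replicates(design, profiles, jac)
        assert not flags["flagged"].any()

    def test_simulated_outlier_detected(self, study, study_ann, study_alignments):
        from mlseq.core_io import gene_expression

        samples = [s for s in study.readsets if s.startswith("HT_plus")]
        als = {s: study_alignments[s] for s in samples}
        expr = gene_expression(als, study_ann)
        jac = jaccard_matrix(expr, n=10)
        design = study.design.loc[samples]
        profiles, p2p = {}, pd.DataFrame(1.0, index=samples, columns=samples)
        for i, a in enumerate(samples):
            for b in samples[i + 1 :]:
                profiles[(a, b)] = complexity_diff_profile(als[a], als[b], study_ann)
                prof = p2p_profile(als[a], als[b], study_ann)
                med = float(prof.per_gene["p2ppcc"].dropna().median())
                p2p.loc[a, b] = p2p.loc[b, a] = med
        flags = flag_outlier_replicates(
            design, profiles, jac, p2p_similarity=p2p
        ).set_index("sample")
        assert flags.loc["HT_plus_r3", "flagged"]
        assert not flags.drop(index="HT_plus_r3")["flagged"].any()
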