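"""The four stability algorithms against hand computations and brute force."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.datamodel import CtMatrix, collapse_technical_replicates
from refstab.simulate import GeneDesign, SampleDesign, CtSimulationDesign, simulate_ct_dataset
from refstab.stability import (
    bestkeeper,
    ct_to_relative_quantity,
    delta_ct_method,
    genorm,
    genorm_pairwise_variation,
    normfinder,
    reffinder_aggregate,
    run_all_methods,
)

from _oracles import (
    brute_bestkeeper,
    brute_delta_ct,
    brute_genorm,
    brute_normfinder_grouped,
    brute_normfinder_ungrouped,
    brute_pairwise_variation,
    brute_rank,
    brute_reffinder,
)
from conftest import as_rows, random_ct_matrix


def matrix(rows: dict[str, list[float]]) -> CtMatrix:
    return CtMatrix(pd.DataFrame(rows).T)


class TestRelativeQuantity:
    def test_powers_of_two(self):
        rq = ct_to_relative_quantity(matrix({"a": [20, 21, 22], "b": [20, 20, 20], "c": [25, 25, 25]}))
        assert list(rq.values.loc["a"]) == [1.0, 0.5, 0.25]
        assert list(rq.values.loc["b"]) == [1.0, 1.0, 1.0]

    def test_custom_efficiency(self):
        rq = ct_to_relative_quantity(
            matrix({"a": [20.0, 21.0], "b": [20, 20], "c": [20, 20]}), 1.9
        )
        assert rq.values.loc["a"].iloc[1] == pytest.approx(1 / 1.9)

    def test_row_max_is_one_and_positive(self, small_matrix):
        rq = ct_to_relative_quantity(small_matrix)
        assert np.allclose(rq.values.max(axis=1), 1.0)
        assert (rq.values.to_numpy() > 0).all()

    def test_efficiency_out_of_range(self, small_matrix):
        with pytest.raises(ValueError, match="efficiency"):
            ct_to_relative_quantity(small_matrix, 2.5)

    def test_missing_cells_rejected(self):
        cm = matrix({"a": [20, np.nan], "b": [20, 21], "c": [22, 23]})
        with pytest.raises(ValueError, match="missing"):
            ct_to_relative_quantity(cm)


class TestGeNorm:
    def test_proportional_genes_have_zero_m(self):
        # constant log ratios between all pairs => V == 0 => M == 0
        cm = matrix({"a": [20, 21, 22], "b": [25, 26, 27], "c": [18, 19, 20]})
        res = genorm(ct_to_relative_quantity(cm))
        assert np.allclose(res.scores, 0.0)

    def test_hand_computed_three_gene_case(self):
        # a,b proportional; c drifts: log2 ratio to a is (0,1,2) across units
        cm = matrix({"a": [20, 20, 20], "b": [22, 22, 22], "c": [20, 19, 18]})
        res = genorm(ct_to_relative_quantity(cm))
        # V_ab=0, V_ac=V_bc=sd(0,1,2)=1 => M_a=M_b=0.5, M_c=1; c excluded first
        assert res.metadata["exclusion_order"] == ["c"]
        assert res.scores["c"] == pytest.approx(1.0)
        # a,b survive; their final-pair score is their mutual pair SD (0)
        assert res.scores["a"] == pytest.approx(0.0)
        assert res.ranks["a"] == res.ranks["b"] == 1.5
        assert res.ranks["c"] == 3.0

    def test_loading_shift_leaves_m_unchanged(self, small_matrix):
        res1 = genorm(ct_to_relative_quantity(small_matrix))
        shifted = CtMatrix(small_matrix.values + np.array([3.0, -1.0, 0.5, 2.0, 0.0, -2.0]))
        res2 = genorm(ct_to_relative_quantity(shifted))
        assert np.allclose(res1.scores, res2.scores, atol=1e-10)

    def test_degenerate_all_zero_variance(self):
        cm = matrix({"a": [20, 20], "b": [21, 21], "c": [22, 22]})
        res = genorm(ct_to_relative_quantity(cm))
        assert np.allclose(res.scores, 0.0)
        # deterministic lexicographic tie-break: largest id excluded first
        assert res.metadata["exclusion_order"] == ["c"]

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            cm = random_ct_matrix(rng, 5, 6)
            res = genorm(ct_to_relative_quantity(cm))
            scores, ranks, order = brute_genorm(as_rows(cm))
            for g in cm.genes:
                assert res.scores[g] == pytest.approx(scores[g], abs=1e-12)
                assert res.ranks[g] == ranks[g]
            assert res.metadata["exclusion_order"] == order


class TestPairwiseVariation:
    def test_proportional_genes_give_zero_v(self):
        cm = matrix({"a": [20, 21, 22], "b": [25, 26, 27], "c": [18, 19, 20], "d": [30, 31, 32]})
        rq = ct_to_relative_quantity(cm)
        v = genorm_pairwise_variation(rq, ["a", "b", "c", "d"])
        assert np.allclose(v, 0.0)

    def test_nonnegative_and_matches_brute(self, rng):
        cm = random_ct_matrix(rng, 4, 6)
        rq = ct_to_relative_quantity(cm)
        ranked = list(genorm(rq).to_frame()["gene"])
        v = genorm_pairwise_variation(rq, ranked)
        assert (v >= 0).all()
        brute = brute_pairwise_variation(as_rows(cm), ranked)
        for k in brute:
            assert v[k] == pytest.approx(brute[k], abs=1e-12)

    def test_noisy_fourth_gene_raises_v34(self, rng):
        base = rng.uniform(18, 25, size=3)
        tight = base[:, None] + rng.normal(0, 0.05, size=(3, 8))
        noisy = 27.0 + rng.normal(0, 1.5, size=(1, 8))
        cm = CtMatrix(pd.DataFrame(np.vstack([tight, noisy]), index=list("abcd")))
        rq = ct_to_relative_quantity(cm)
        ranked = list(genorm(rq).to_frame()["gene"])
        v = genorm_pairwise_variation(rq, ranked)
        assert v["V3/4"] > v["V2/3"]


class TestNormFinder:
    def test_pure_loading_noise_scores_zero(self):
        # all variation is shared per-unit loading: z is constant per gene
        cm = matrix({"a": [20, 23, 21], "b": [25, 28, 26], "c": [18, 21, 19]})
        res = normfinder(ct_to_relative_quantity(cm))
        assert np.allclose(res.scores, 0.0, atol=1e-12)

    def test_ungrouped_score_is_sd_of_centered_log_expression(self):
        # flat partners: z_a = 2*y_a/3 = (-2,-1,0), sample SD exactly 1
        cm = matrix({"a": [23.0, 21.5, 20.0], "b": [25, 25, 25],
                     "c": [19, 19, 19]})
        res = normfinder(ct_to_relative_quantity(cm))
        assert res.scores["a"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_ungrouped(self, rng):
        for _ in range(20):
            cm = random_ct_matrix(rng, 5, 6)
            res = normfinder(ct_to_relative_quantity(cm))
            brute = brute_normfinder_ungrouped(as_rows(cm))
            for g in cm.genes:
                assert res.scores[g] == pytest.approx(brute[g], abs=1e-12)

    def test_matches_brute_force_grouped(self, rng):
        groups = ["ctl"] * 3 + ["trt"] * 3
        for _ in range(10):
            cm = random_ct_matrix(rng, 5, 6)
            gmap = dict(zip(cm.units, groups))
            res = normfinder(ct_to_relative_quantity(cm), gmap)
            brute = brute_normfinder_grouped(as_rows(cm), groups)
            for g in cm.genes:
                assert res.scores[g] == pytest.approx(brute[g], abs=1e-12)

    def test_group_of_one_rejected(self, rng):
        cm = random_ct_matrix(rng, 4, 5)
        gmap = dict(zip(cm.units, ["a", "a", "a", "a", "b"]))
        with pytest.raises(ValueError, match="fewer than 2"):
            normfinder(ct_to_relative_quantity(cm), gmap)

    def test_condition_shifted_gene_tops_grouped_scores(self):
        # one gene carries a designed treated-vs-control shift; same sigma
        hits = 0
        for seed in range(100):
            genes = tuple(
                GeneDesign(f"g{i}", 20.0 + i, 0.15,
                           {"trt": 0.8} if i == 2 else {})
                for i in range(6)
            )
            samples = tuple(
                SampleDesign(f"s{j}", n_bio=1, n_tech=1, condition=c)
                for j, c in enumerate(["ctl"] * 4 + ["trt"] * 4)
            )
            ds, _ = simulate_ct_dataset(
                CtSimulationDesign(genes, samples, 0.3, 0.0, seed)
            )
            cm = collapse_technical_replicates(ds)
            res = normfinder(
                ct_to_relative_quantity(cm), cm.group_of_unit
            )
            hits += res.scores.idxmax() == "g2"
        assert hits >= 90


class TestDeltaCt:
    def test_constant_difference_pair(self):
        cm = matrix({"a": [20, 21, 22], "b": [25, 26, 27], "c": [20, 20, 20]})
        res = delta_ct_method(cm)
        # SD_ab = 0; SD_ac = SD_bc = sd(0,1,2) = 1
        assert res.scores["a"] == pytest.approx(0.5)
        assert res.scores["b"] == pytest.approx(0.5)
        assert res.scores["c"] == pytest.approx(1.0)

    def test_loading_shift_invariance(self, small_matrix):
        shift = np.array([1.0, -2.0, 0.3, 4.0, -1.1, 0.0])
        shifted = CtMatrix(small_matrix.values + shift)
        assert np.allclose(
            delta_ct_method(small_matrix).scores,
            delta_ct_method(shifted).scores,
            atol=1e-10,
        )

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            cm = random_ct_matrix(rng, 5, 6)
            res = delta_ct_method(cm)
            brute = brute_delta_ct(as_rows(cm))
            for g in cm.genes:
                assert res.scores[g] == pytest.approx(brute[g], abs=1e-12)

    def test_equals_genorm_v_at_efficiency_two(self, rng):
        # log2 of quantity ratios differ from Ct differences only by a
        # constant per pair, so the pairwise SDs are identical
        for _ in range(10):
            cm = random_ct_matrix(rng, 4, 7)
            rq = ct_to_relative_quantity(cm, 2.0)
            log_q = rq.log2()
            vals = cm.values.to_numpy()
            for j in range(4):
                for k in range(j + 1, 4):
                    v_jk = np.std(log_q[j] - log_q[k], ddof=1)
                    sd_jk = np.std(vals[j] - vals[k], ddof=1)
                    assert v_jk == pytest.approx(sd_jk, abs=1e-10)


class TestBestKeeper:
    def test_mad_of_simple_row(self):
        cm = matrix({"a": [20, 21, 22], "b": [25, 25, 25], "c": [30, 30, 30]})
        stats_bk, res = bestkeeper(cm)
        assert res.scores["a"] == pytest.approx(2.0 / 3.0)
        assert res.scores["b"] == 0.0
        assert bool(stats_bk.table.loc["a", "consistent"])

    def test_constant_gene_best_rank_and_nan_correlation(self):
        cm = matrix({"a": [20, 21, 22], "b": [25, 25, 25], "c": [28, 29, 31]})
        stats_bk, res = bestkeeper(cm)
        assert res.ranks["b"] == 1.0
        assert np.isnan(stats_bk.table.loc["b", "r_vs_index"])

    def test_not_invariant_to_loading_shift(self):
        cm = matrix({"a": [20, 20, 20], "b": [25, 25, 25], "c": [30, 30, 30]})
        shifted = CtMatrix(cm.values + np.array([1.0, 0.0, 0.0]))
        before = bestkeeper(cm)[1].scores
        after = bestkeeper(shifted)[1].scores
        assert (before != after).any()

    def test_geo_mean_between_min_and_max(self, small_matrix):
        table = bestkeeper(small_matrix)[0].table
        assert (table["min_ct"] <= table["geo_mean_ct"]).all()
        assert (table["geo_mean_ct"] <= table["max_ct"]).all()

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            cm = random_ct_matrix(rng, 5, 6)
            res = bestkeeper(cm)[1]
            brute = brute_bestkeeper(as_rows(cm))
            for g in cm.genes:
                assert res.scores[g] == pytest.approx(brute[g], abs=1e-12)


class TestRefFinder:
    def test_geometric_mean_of_ranks(self, small_matrix):
        results = run_all_methods(small_matrix)
        ref = results["reffinder"]
        g = ref.genes[0]
        prod = math.prod(
            results[m].ranks[g]
            for m in ("genorm", "normfinder", "delta_ct", "bestkeeper")
        )
        assert ref.scores[g] == pytest.approx(prod ** 0.25, abs=1e-12)

    def test_closed_form_1234(self):
        ranks = [
            pd.Series({"a": r, "b": 1.0, "c": 2.0})
            for r in (1.0, 2.0, 3.0, 4.0)
        ]
        from refstab.stability import StabilityResult

        results = [
            StabilityResult(f"m{i}", rs.astype(float), rs) for i, rs in enumerate(ranks)
        ]
        agg = reffinder_aggregate(results)
        assert agg.scores["a"] == pytest.approx(24.0 ** 0.25, abs=1e-12)

    def test_rank_one_everywhere_wins(self, small_matrix):
        results = run_all_methods(small_matrix)
        ref = results["reffinder"]
        assert ref.scores.min() >= 1.0
        assert ref.scores.max() <= len(ref.genes)

    def test_permuted_identical_rank_multisets_tie(self):
        from refstab.stability import StabilityResult

        r1 = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        r2 = pd.Series({"a": 2.0, "b": 1.0, "c": 3.0})
        results = [
            StabilityResult("m1", r1.astype(float), r1),
            StabilityResult("m2", r2.astype(float), r2),
        ]
        agg = reffinder_aggregate(results)
        assert agg.scores["a"] == agg.scores["b"]
        assert agg.ranks["a"] == agg.ranks["b"] == 1.5

    def test_gene_set_mismatch_is_hard_error(self, small_matrix, rng):
        results = run_all_methods(small_matrix)
        other = random_ct_matrix(rng, 4, 6)
        mismatched = run_all_methods(other)
        with pytest.raises(ValueError, match="mismatch"):
            reffinder_aggregate(
                [results["genorm"], mismatched["delta_ct"]]
            )

    def test_matches_brute_force(self, rng):
        cm = random_ct_matrix(rng, 5, 6)
        results = run_all_methods(cm)
        rank_sets = [
            {g: float(results[m].ranks[g]) for g in cm.genes}
            for m in ("genorm", "normfinder", "delta_ct", "bestkeeper")
        ]
        brute_scores = brute_reffinder(rank_sets)
        brute_ranks = brute_rank(brute_scores)
        for g in cm.genes:
            assert results["reffinder"].scores[g] == pytest.approx(
                brute_scores[g], abs=1e-12
            )
            assert results["reffinder"].ranks[g] == brute_ranks[g]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    shifts=st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=6, max_size=6
    ),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_ratio_methods_invariant_under_any_loading_shift(shifts, seed):
    """geNorm, NormFinder and deltaCt ignore arbitrary per-unit constants."""
    cm = random_ct_matrix(np.random.default_rng(seed), 4, 6)
    shifted = CtMatrix(cm.values + np.array(shifts))
    rq, rq_s = ct_to_relative_quantity(cm), ct_to_relative_quantity(shifted)
    assert np.allclose(genorm(rq).scores, genorm(rq_s).scores, atol=1e-10)
    assert np.allclose(normfinder(rq).scores, normfinder(rq_s).scores, atol=1e-10)
    assert np.allclose(
        delta_ct_method(cm).scores, delta_ct_method(shifted).scores, atol=1e-10
    )
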