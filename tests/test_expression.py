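"""Pfaffl quantification, regulation calls and profile clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqpkit import expression, simulate
from ._oracles import naive_average_linkage


def _matrix_from_values(values: pd.DataFrame) -> expression.ExpressionMatrix:
    return expression.ExpressionMatrix(
        values=values, mask=values.isna(), calibrator=values.columns[0]
    )


class TestPfafflRatio:
    def test_calibrator_self_ratio_is_one(self):
        assert expression.pfaffl_ratio(2.0, 0.0, 2.0, 0.0) == 1.0

    def test_one_cycle_doubling(self):
        assert expression.pfaffl_ratio(2.0, 1.0, 2.0, 0.0) == 2.0

    def test_reduces_to_ddct_at_equal_efficiencies(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            dt, dr = rng.normal(0, 3, size=2)
            e = float(rng.uniform(1.5, 2.0))
            assert expression.pfaffl_ratio(e, dt, e, dr) == pytest.approx(
                e ** (dt - dr)
            )
            assert expression.pfaffl_ratio(2.0, dt, 2.0, dr) == pytest.approx(
                2.0 ** (dt - dr)
            )

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            expression.pfaffl_ratio(2.0, np.nan, 2.0, 0.0)


class TestBuildMatrix:
    def test_uniform_table_gives_all_zero_matrix(self):
        fc = pd.DataFrame(0.0, index=["g1", "g2"],
                          columns=["cal", "s1", "s2"])
        table, _ = simulate.generate_ct_table(fc, "cal", seed=0, noise_sd=0.0)
        m = expression.build_matrix(table, "cal")
        assert np.allclose(m.values.to_numpy(), 0.0)
        assert not m.mask.to_numpy().any()

    def test_noise_free_fold_changes_recovered_exactly(self):
        fc = pd.DataFrame(
            [[0.0, 2.0, -1.5, 4.0], [0.0, -3.0, 0.5, 0.0]],
            index=["g1", "g2"], columns=["cal", "a", "b", "c"],
        )
        table, _ = simulate.generate_ct_table(fc, "cal", seed=1, noise_sd=0.0)
        m = expression.build_matrix(table, "cal")
        assert np.allclose(m.values[fc.columns].to_numpy(), fc.to_numpy(),
                           atol=1e-12)

    def test_non_doubling_efficiency_round_trips(self):
        fc = pd.DataFrame([[0.0, 3.0]], index=["g1"], columns=["cal", "s"])
        table, _ = simulate.generate_ct_table(
            fc, "cal", seed=2, noise_sd=0.0, efficiencies={"g1": 1.8}
        )
        m = expression.build_matrix(table, "cal")
        assert m.values.loc["g1", "s"] == pytest.approx(3.0, abs=1e-10)

    def test_replicate_and_column_order_invariance(self):
        fc = pd.DataFrame([[0.0, 2.0], [0.0, -1.0]],
                          index=["g1", "g2"], columns=["cal", "s"])
        table, _ = simulate.generate_ct_table(fc, "cal", seed=3, noise_sd=0.3)
        m1 = expression.build_matrix(table, "cal")
        shuffled = expression.CtTable(
            data=table.data.sample(frac=1.0, random_state=0),
            reference_gene=table.reference_gene,
            efficiencies=table.efficiencies,
        )
        m2 = expression.build_matrix(shuffled, "cal")
        assert np.allclose(m1.values.to_numpy(), m2.values.to_numpy())

    def test_noisy_recovery_within_three_standard_errors(self):
        # log2 value = difference of 4 independent mean Ct values, each a
        # mean of n_bio*n_tech noisy cycles -> se = sd * sqrt(4 / 6).
        sd = 0.2
        se = sd * np.sqrt(4 / 6)
        fc = pd.DataFrame(
            [[0.0, 2.0, -2.0], [0.0, 1.0, -0.5],
             [0.0, 0.0, 3.0], [0.0, -1.0, 1.5]],
            index=list("abcd"), columns=["cal", "s1", "s2"],
        )
        within = total = 0
        for seed in range(200):
            table, _ = simulate.generate_ct_table(fc, "cal", seed=seed,
                                                  noise_sd=sd)
            m = expression.build_matrix(table, "cal")
            err = (m.values - fc)[["s1", "s2"]].to_numpy()
            within += int((np.abs(err) <= 3 * se).sum())
            total += err.size
        assert within / total >= 0.95

    def test_bias_shrinks_with_replication(self):
        fc = pd.DataFrame([[0.0, 2.0]], index=["g"], columns=["cal", "s"])
        bias = {}
        for n_bio in (3, 10, 30):
            errs = []
            for seed in range(60):
                table, _ = simulate.generate_ct_table(
                    fc, "cal", seed=seed, noise_sd=0.4, n_bio=n_bio
                )
                m = expression.build_matrix(table, "cal")
                errs.append(m.values.loc["g", "s"] - 2.0)
            bias[n_bio] = abs(np.mean(errs))
        assert bias[30] < bias[3] + 0.05  # noise shrinks, no systematic drift

    def test_undetected_cells_are_masked_not_zero(self):
        fc = pd.DataFrame([[0.0, 2.0]], index=["g"], columns=["cal", "s"])
        table, _ = simulate.generate_ct_table(
            fc, "cal", seed=4, noise_sd=0.0, not_detected=[("g", "s")]
        )
        m = expression.build_matrix(table, "cal")
        assert m.mask.loc["g", "s"]
        assert np.isnan(m.values.loc["g", "s"])

    def test_gene_missing_in_calibrator_warns_and_masks(self):
        fc = pd.DataFrame([[0.0, 2.0]], index=["g"], columns=["cal", "s"])
        table, _ = simulate.generate_ct_table(
            fc, "cal", seed=5, noise_sd=0.0, not_detected=[("g", "cal")]
        )
        with pytest.warns(UserWarning, match="calibrator"):
            m = expression.build_matrix(table, "cal")
        assert m.mask.loc["g"].all()


class TestCallRegulation:
    def test_boundary_and_basic_calls(self):
        values = pd.DataFrame(
            [[0.0, 1.0, -1.0, 0.5, np.nan]],
            index=["g"], columns=list("abcde"),
        )
        calls = expression.call_regulation(_matrix_from_values(values), 1.0)
        assert list(calls.loc["g"]) == ["nc", "up", "down", "nc", "nd"]

    def test_planted_two_fold_calls_recovered(self):
        fc = pd.DataFrame(
            [[0.0, 2.0, -2.0], [0.0, 0.0, 2.0]],
            index=["g1", "g2"], columns=["cal", "s1", "s2"],
        )
        table, _ = simulate.generate_ct_table(fc, "cal", seed=6, noise_sd=0.0)
        m = expression.build_matrix(table, "cal")
        calls = expression.call_regulation(m, threshold=1.0)
        assert list(calls.loc["g1"]) == ["nc", "up", "down"]
        assert list(calls.loc["g2"]) == ["nc", "nc", "up"]

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_counts_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.normal(0, 2, size=(5, 6)))
        m = _matrix_from_values(values)
        prev_up = prev_down = None
        for thr in (0.5, 1.0, 2.0, 4.0):
            calls = expression.call_regulation(m, thr)
            up = int((calls == "up").to_numpy().sum())
            down = int((calls == "down").to_numpy().sum())
            if prev_up is not None:
                assert up <= prev_up and down <= prev_down
            prev_up, prev_down = up, down


class TestHierarchicalCluster:
    def test_identical_profiles_merge_at_zero(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                               [9.0, 9.0, 9.0]], index=list("abc"))
        Z, order, kept = expression.hierarchical_cluster(
            _matrix_from_values(values)
        )
        assert Z[0, 2] == 0.0
        assert kept == list("abc")

    def test_close_pair_merges_first(self):
        values = pd.DataFrame([[0.0, 0.0], [0.0, 1.0], [0.0, 10.0]],
                              index=list("abc"))
        Z, order, _ = expression.hierarchical_cluster(
            _matrix_from_values(values)
        )
        assert sorted(Z[0, :2].astype(int)) == [0, 1]  # a and b first

    def test_merge_heights_match_naive_agglomeration(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.normal(size=(20, 6)))
        m = _matrix_from_values(values)
        Z, _, _ = expression.hierarchical_cluster(m)
        d = expression._pairwise_complete_distances(values.to_numpy())
        expected = naive_average_linkage(d)
        assert np.allclose(Z[:, 2], expected)

    def test_profile_without_shared_cells_is_excluded(self):
        values = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan],
             [1.5, 2.5, np.nan, np.nan],
             [1.1, 2.1, 0.5, np.nan],
             [np.nan, np.nan, np.nan, 4.0]],
            index=list("abcd"),
        )
        with pytest.warns(UserWarning, match="excluded"):
            Z, order, kept = expression.hierarchical_cluster(
                _matrix_from_values(values)
            )
        assert kept == list("abc")

    def test_newick_export_contains_all_leaves(self):
        values = pd.DataFrame(np.arange(12.0).reshape(4, 3),
                              index=list("abcd"))
        Z, _, kept = expression.hierarchical_cluster(
            _matrix_from_values(values)
        )
        nwk = expression.linkage_to_newick(Z, kept)
        assert nwk.endswith(";")
        for leaf in kept:
            assert leaf in nwk
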