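"""Rank-product engine: hand-computed examples, oracles, symmetries."""

import numpy as np
import pandas as pd
import pytest

from pesignet.rankprod import (
    DEResult,
    PairingScheme,
    call_de,
    fold_change_ranks,
    permutation_pfp,
    rank_product,
    residualize,
)

from conftest import make_two_group_study


class TestResidualize:
    def test_no_covariates_is_identity(self):
        study = make_two_group_study(np.arange(12.0).reshape(3, 4), 2)
        out = residualize(study, [])
        pd.testing.assert_frame_equal(out.values, study.values)

    def test_projection_removes_covariate(self):
        rng = np.random.default_rng(0)
        cov = rng.random(20)
        vals = np.outer(np.array([2.0, -1.0, 0.5]), cov)
        study = make_two_group_study(vals, 10)
        study.phenotypes["x"] = cov
        out = residualize(study, ["x"])
        # noiseless case: residuals vanish entirely
        assert np.abs(out.values.to_numpy()).max() < 1e-10

    def test_hand_computed_three_sample_case(self):
        # values (1,2,3), binary covariate (0,0,1): group means 1.5 and 3
        study = make_two_group_study(np.array([[1.0, 2.0, 3.0]]), 1)
        study.phenotypes["z"] = [0, 0, 1]
        out = residualize(study, ["z"])
        assert out.values.iloc[0].tolist() == pytest.approx([-0.5, 0.5, 0.0])

    def test_constant_covariate_rejected(self):
        study = make_two_group_study(np.ones((2, 4)), 2)
        study.phenotypes["c"] = 1
        with pytest.raises(ValueError, match="constant"):
            residualize(study, ["c"])


class TestFoldChangeRanks:
    def test_single_comparison_ranks(self):
        # diffs (+2, 0, -1) -> up-ranks (1, 2, 3)
        vals = np.array([[5.0, 3.0], [4.0, 4.0], [2.0, 3.0]])
        study = make_two_group_study(vals, 1)
        ranks = fold_change_ranks(study, "PE")
        assert ranks[:, 0].tolist() == [1.0, 2.0, 3.0]

    def test_tied_differences_get_average_rank(self):
        vals = np.array([[5.0, 3.0], [6.0, 4.0], [1.0, 3.0]])  # diffs 2, 2, -2
        study = make_two_group_study(vals, 1)
        ranks = fold_change_ranks(study, "PE")
        assert sorted(ranks[:2, 0]) == [1.5, 1.5]
        assert ranks[2, 0] == 3.0

    def test_all_pairs_2v2_against_sort_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(6, 4))
        study = make_two_group_study(vals, 2)
        ranks = fold_change_ranks(study, "PE")
        assert ranks.shape == (6, 4)
        # oracle: rank each case-control difference column by explicit sort
        k = 0
        for i in range(2):
            for j in range(2, 4):
                diffs = vals[:, i] - vals[:, j]
                order = np.argsort(-diffs)
                expected = np.empty(6)
                expected[order] = np.arange(1, 7)
                assert ranks[:, k].tolist() == expected.tolist()
                k += 1

    def test_empty_class_rejected(self):
        study = make_two_group_study(np.ones((2, 3)), 0)
        with pytest.raises(ValueError, match="empty class"):
            fold_change_ranks(study, "PE")


class TestRankProduct:
    @pytest.mark.parametrize(
        "ranks,expected",
        [
            ([[1, 1, 1]], 1.0),
            ([[1, 4]], 2.0),
            ([[2, 8, 1]], 16 ** (1 / 3)),
        ],
    )
    def test_hand_examples(self, ranks, expected):
        assert rank_product(np.array(ranks, float))[0] == pytest.approx(expected)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_product(np.empty((0, 0)))

    def test_monotone_in_each_rank_entry(self):
        rng = np.random.default_rng(1)
        ranks = rng.integers(1, 50, size=(1, 6)).astype(float)
        base = rank_product(ranks)[0]
        for k in range(6):
            if ranks[0, k] > 1:
                lowered = ranks.copy()
                lowered[0, k] -= 1
                assert rank_product(lowered)[0] <= base


def _exhaustive_null(X, n_case):
    """All C(n, n_case) label splits: pooled RP_up values, one row per split."""
    import itertools

    G, n = X.shape
    out = []
    for case in itertools.combinations(range(n), n_case):
        ctrl = [i for i in range(n) if i not in case]
        diffs = np.array(
            [[X[g, i] - X[g, j] for i in case for j in ctrl] for g in range(G)]
        )
        ranks = np.empty_like(diffs)
        for col in range(diffs.shape[1]):
            order = np.argsort(-diffs[:, col])
            ranks[order, col] = np.arange(1, G + 1)
        out.append(np.exp(np.mean(np.log(ranks), axis=1)))
    return np.array(out)


class TestPermutationPfp:
    def test_zero_permutations_rejected(self):
        study = make_two_group_study(np.random.default_rng(0).normal(size=(4, 6)), 3)
        with pytest.raises(ValueError, match="B must be"):
            permutation_pfp(study, "PE", B=0)

    def test_strong_gene_tops_ranking_under_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(6, 6))
        X[0, :3] += 10.0  # one gene shifted by 10 SD in the three cases
        study = make_two_group_study(X, 3)
        res = permutation_pfp(study, "PE", B=400, seed=2)
        tab = res.table
        assert tab["RP_up"].idxmin() == "g0"
        assert tab.loc["g0", "pfp_up"] == tab["pfp_up"].min()
        # oracle: under all C(6,3)=20 splits the observed labeling yields
        # the single smallest RP for g0
        null = _exhaustive_null(X, 3)
        assert tab.loc["g0", "RP_up"] <= null[:, 0].min()

    def test_permutation_p_converges_to_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 6))
        X[1, :3] += 2.0
        study = make_two_group_study(X, 3)
        null = _exhaustive_null(X, 3)  # 20 splits x 5 genes
        res = permutation_pfp(study, "PE", B=3000, seed=3)
        obs_rp = res.table["RP_up"].to_numpy()
        for g in range(5):
            exact = (null <= obs_rp[g]).mean()
            approx = res.table["p_up"].iloc[g]
            assert approx == pytest.approx(exact, abs=0.04)

    def test_label_swap_exchanges_up_and_down_on_balanced_design(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 8))
        a = make_two_group_study(X, 4)
        b = make_two_group_study(X, 4)
        b.phenotypes["PE"] = 1 - b.phenotypes["PE"]  # swap class labels in place
        ra = permutation_pfp(a, "PE", B=50, seed=7).table
        rb = permutation_pfp(b, "PE", B=50, seed=7).table
        np.testing.assert_allclose(ra["RP_up"], rb["RP_down"])
        np.testing.assert_allclose(ra["pfp_up"], rb["pfp_down"])
        np.testing.assert_allclose(ra["p_down"], rb["p_up"])

    def test_pfp_near_one_for_top_gene_on_null_data(self):
        # on pure-noise cohorts the best gene's pfp should hover around 1
        tops = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            study = make_two_group_study(rng.normal(size=(50, 12)), 6)
            res = permutation_pfp(study, "PE", B=60, seed=seed)
            tops.append(res.table["pfp_up"].iloc[res.table["rank_up"].argmin()])
        assert 0.5 < np.mean(tops) < 1.6


class TestCallDe:
    def _result(self, pfp_up, pfp_down):
        genes = [f"g{i}" for i in range(len(pfp_up))]
        tab = pd.DataFrame({
            "RP_up": 1.0, "rank_up": 1.0, "p_up": 0.5, "pfp_up": pfp_up,
            "RP_down": 1.0, "rank_down": 1.0, "p_down": 0.5, "pfp_down": pfp_down,
            "mean_log2_diff": 0.0,
        }, index=pd.Index(genes, name="gene"))
        return DEResult("PE", tab, 1, 1)

    def test_all_pfp_one_gives_empty_signature(self):
        assert len(call_de(self._result([1.0, 1.0], [1.0, 1.0]))) == 0

    def test_direction_assignment(self):
        sig = call_de(self._result([0.01, 0.9], [0.9, 0.01]))
        assert sig.entries == {"g0": "up", "g1": "down"}

    def test_gene_passing_both_directions_excluded(self):
        sig = call_de(self._result([0.01], [0.01]))
        assert len(sig) == 0

    def test_planted_cohort_recovery(self, balanced_spec):
        from pesignet.simulate import simulate_cohort

        study, truth = simulate_cohort(balanced_spec)
        res = permutation_pfp(study, "PE", B=60, seed=1)
        sig = call_de(res, 0.05)
        planted = set(truth.index[truth["PE"]])
        recovered = len(sig.genes & planted) / len(planted)
        assert recovered >= 0.9
        # called directions agree with the planted signs
        for g in sig.genes & planted:
            want = "up" if truth.loc[g, "direction"] > 0 else "down"
            assert sig.direction(g) == want
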