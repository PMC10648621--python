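import numpy as np
import pytest

from pathsurv import (
    OccurrenceEnsemble,
    PathwayMask,
    TrainConfig,
    occurrence_probability,
    ranked_gene_lists,
    run_ensemble,
    run_two_phase,
    select_expanded,
    supplement_genes,
)
from pathsurv.expansion import (
    write_expanded_gmt,
    write_probability_tsv,
    write_rnk,
    write_supplement_tsv,
)


def _ens(occ, wts=None):
    runs, g, p = occ.shape
    return OccurrenceEnsemble(
        occ,
        occ.astype(float) if wts is None else wts,
        list(range(runs)),
        [f"g{i}" for i in range(g)],
        [f"P{j}" for j in range(p)],
    )


def _mask(values):
    g, p = values.shape
    return PathwayMask(values, [f"g{i}" for i in range(g)], [f"P{j}" for j in range(p)])


class TestOccurrenceProbability:
    def test_identical_runs_equal_single_run(self):
        o = np.tile((np.arange(6).reshape(3, 2) % 2).astype(float), (4, 1, 1))
        assert np.array_equal(occurrence_probability(_ens(o)), o[0])

    def test_simple_fraction(self):
        o = np.zeros((5, 2, 1))
        o[:3, 0, 0] = 1.0
        assert occurrence_probability(_ens(o))[0, 0] == pytest.approx(0.6)

    def test_matches_direct_mean_oracle(self, rng):
        o = (rng.uniform(size=(5, 4, 2)) < 0.5).astype(float)
        S = occurrence_probability(_ens(o))
        for i in range(4):
            for j in range(2):
                assert S[i, j] == pytest.approx(sum(o[k, i, j] for k in range(5)) / 5)


class TestSelectExpanded:
    def test_keeps_exactly_the_rounded_count(self, rng):
        mask = _mask((rng.uniform(size=(20, 3)) < 0.3).astype(float) + 0.0)
        mask.values[0, :] = 1.0
        mask = _mask(mask.values)
        S = rng.uniform(size=(20, 3))
        K = mask.n_pairs
        exp = select_expanded(S, mask, alpha=0.2)
        assert exp.values.sum() == int(np.floor(1.2 * K + 0.5))
        assert exp.selected_count == exp.values.sum()

    def test_glioma_prior_sizes_yield_eighty_three(self, rng):
        # five prior sets of sizes 19,13,15,13,9 => K=69; alpha=0.2 => 83 pairs
        sizes = [19, 13, 15, 13, 9]
        g = 120
        values = np.zeros((g, 5))
        k = 0
        for j, s in enumerate(sizes):
            values[k : k + s, j] = 1.0
            k += s
        mask = _mask(values)
        S = np.where(values == 1, 1.0, rng.uniform(0.0, 0.99, size=(g, 5)))
        exp = select_expanded(S, mask, alpha=0.2)
        assert mask.n_pairs == 69
        assert exp.values.sum() == 83
        assert exp.supplement_mask(mask).sum() == 83 - 69

    def test_alpha_zero_with_saturated_prior_recovers_the_mask(self, rng):
        values = np.zeros((8, 2))
        values[:3, 0] = 1.0
        values[3:5, 1] = 1.0
        mask = _mask(values)
        S = np.where(values == 1, 1.0, rng.uniform(0.0, 0.9, size=(8, 2)))
        exp = select_expanded(S, mask, alpha=0.0)
        assert np.array_equal(exp.values, mask.values)

    def test_matches_brute_force_sort_and_cut(self, rng):
        values = np.zeros((6, 2))
        values[[0, 1, 2, 3, 4], [0, 0, 1, 1, 0]] = 1.0  # K = 5
        mask = _mask(values)
        S = rng.uniform(size=(6, 2))
        exp = select_expanded(S, mask, alpha=0.2)
        n_star = int(np.floor(1.2 * 5 + 0.5))
        order = sorted(
            ((S[i, j], -i, -j) for i in range(6) for j in range(2)), reverse=True
        )
        kept = {(-gi, -pj) for _, gi, pj in order[:n_star]}
        got = {tuple(ij) for ij in np.argwhere(exp.values == 1)}
        assert got == kept

    @pytest.mark.parametrize("alphas", [(0.0, 0.2), (0.2, 0.4), (0.4, 0.6)])
    def test_selection_nested_in_alpha(self, rng, alphas):
        values = (rng.uniform(size=(15, 2)) < 0.4).astype(float)
        values[0, :] = 1.0
        mask = _mask(values)
        S = rng.uniform(size=(15, 2))
        lo = select_expanded(S, mask, alpha=alphas[0])
        hi = select_expanded(S, mask, alpha=alphas[1])
        assert np.all(hi.values >= lo.values)

    def test_overflow_is_an_error(self):
        mask = _mask(np.ones((2, 2)))
        with pytest.raises(ValueError, match="cannot select"):
            select_expanded(np.ones((2, 2)), mask, alpha=10.0)

    def test_tie_break_prefers_higher_mean_weight(self):
        values = np.array([[1.0], [0.0], [0.0]])
        mask = _mask(values)
        S = np.array([[1.0], [0.5], [0.5]])  # tie at the cut for one slot
        mw = np.array([[1.0], [0.1], [0.9]])
        exp = select_expanded(S, mask, alpha=0.2)  # n* = floor(1.2+0.5) = 1
        assert exp.values.sum() == 1
        exp2 = select_expanded(np.array([[1.0], [0.5], [0.5]]), mask, alpha=1.0, mean_weight=mw)
        # n* = floor(2.5) = 2: prior pair + the tied pair with larger mean weight
        assert exp2.values[2, 0] == 1.0 and exp2.values[1, 0] == 0.0


class TestSupplementAndRankings:
    def test_no_expansion_means_empty_lists(self):
        values = np.eye(3)
        mask = _mask(values)
        exp = select_expanded(np.eye(3), mask, alpha=0.0)
        lists = supplement_genes(exp, mask)
        assert all(v == [] for v in lists.values())

    def test_single_extra_pair_is_a_singleton_list(self, rng):
        values = np.zeros((5, 2))
        values[:2, 0] = 1.0
        values[2:4, 1] = 1.0  # K=4, alpha=0.2 -> n*=5: one supplement slot
        mask = _mask(values)
        S = np.where(values == 1, 1.0, 0.0)
        S[4, 1] = 0.8
        exp = select_expanded(S, mask, alpha=0.2)
        lists = supplement_genes(exp, mask)
        assert lists == {"P0": [], "P1": ["g4"]}

    def test_single_run_ranking_equals_that_runs_order(self):
        w = np.array([[[0.5], [0.1], [0.9]]])
        ens = _ens(np.ones_like(w), w)
        ranked = ranked_gene_lists(ens)["P0"]
        assert ranked["gene"].tolist() == ["g2", "g0", "g1"]

    def test_zero_weight_ranks_below_positive(self):
        w = np.array([[[0.0], [0.2]]])
        ens = _ens((w > 0).astype(float), w)
        assert ranked_gene_lists(ens)["P0"]["gene"].tolist() == ["g1", "g0"]

    def test_mean_then_sort_oracle(self, rng):
        w = rng.uniform(size=(3, 5, 2))
        ens = _ens(np.ones_like(w), w)
        ranked = ranked_gene_lists(ens)
        for j, name in enumerate(["P0", "P1"]):
            means = w[:, :, j].mean(axis=0)
            oracle = [f"g{i}" for i in np.argsort(-means, kind="stable")]
            assert ranked[name]["gene"].tolist() == oracle
            assert ranked[name]["score"].tolist() == sorted(means, reverse=True)


class TestRunEnsemble:
    def test_degenerate_single_full_sample_run(self, small_scenario, fast_config):
        data, prior, _ = small_scenario
        ens = run_ensemble(data, prior, fast_config, runs=1, subsample=1.0)
        w, _ = run_two_phase(data, prior, fast_config)
        assert np.array_equal(ens.occurrences[0], (w.w1 > 0).astype(float))

    def test_three_runs_reproducible_with_distinct_seeds(self, small_scenario, fast_config):
        data, prior, _ = small_scenario
        e1 = run_ensemble(data, prior, fast_config, runs=3)
        e2 = run_ensemble(data, prior, fast_config, runs=3)
        assert e1.run_seeds == [0, 1, 2]
        assert np.array_equal(e1.occurrences, e2.occurrences)
        assert np.array_equal(e1.weights, e2.weights)

    def test_invalid_subsample_rejected(self, small_scenario, fast_config):
        data, prior, _ = small_scenario
        with pytest.raises(ValueError, match="subsample"):
            run_ensemble(data, prior, fast_config, runs=1, subsample=1.5)


class TestExports:
    def test_files_round_trip(self, tmp_path, rng):
        from pathsurv import read_gmt

        values = np.zeros((6, 2))
        values[:2, 0] = 1.0
        values[2:4, 1] = 1.0
        mask = _mask(values)
        occ = (rng.uniform(size=(4, 6, 2)) < 0.7).astype(float)
        ens = _ens(occ, occ * rng.uniform(size=(4, 6, 2)))
        S = occurrence_probability(ens)
        exp = select_expanded(S, mask, alpha=0.2, mean_weight=ens.mean_weights())

        write_probability_tsv(S, ens, tmp_path / "S.tsv")
        import pandas as pd

        S_back = pd.read_csv(tmp_path / "S.tsv", sep="\t", index_col=0)
        assert np.allclose(S_back.to_numpy(), S)

        write_expanded_gmt(exp, tmp_path / "exp.gmt")
        coll = read_gmt(tmp_path / "exp.gmt")
        assert coll.names == ["P0", "P1"]
        assert sum(len(m) for m in coll.members) == exp.values.sum()

        write_supplement_tsv(exp, mask, ens, tmp_path / "supp.tsv")
        supp = pd.read_csv(tmp_path / "supp.tsv", sep="\t")
        assert list(supp.columns) == [
            "pathway", "gene", "occurrence_probability", "mean_weight",
        ]

        paths = write_rnk(ranked_gene_lists(ens), tmp_path / "rnk")
        assert len(paths) == 2
        rnk = pd.read_csv(paths[0], sep="\t", header=None)
        assert rnk.shape == (6, 2)
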