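import numpy as np
import pytest
from scipy import stats

from causanet.data_io import ExpressionMatrix, Interactome, PhenotypeLabels
from causanet.discovery import (
    InteractionScore,
    ModuleParams,
    bonding_scores,
    discover_modules,
    expand_module,
    hotelling_t2,
    interaction_correlations,
    percentile_rank,
)
from conftest import exact_corr_pair


def _expr(genes, values, n):
    return ExpressionMatrix(genes, [f"s{i:03d}" for i in range(n)], np.asarray(values))


class TestInteractionCorrelations:
    def test_perfect_scaling_gives_r1_one(self, balanced_labels):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        expr = _expr(["a", "b"], [x, 2 * x], 12)
        scores = interaction_correlations(
            expr, balanced_labels(6), Interactome.from_pairs([("a", "b")])
        )
        assert scores[0].r1 == pytest.approx(1.0)

    def test_opposite_group_correlations_sum(self, balanced_labels):
        # corr = +0.8 in group 1 and -0.8 in group 2, built exactly
        rng = np.random.default_rng(1)
        x1, y1 = exact_corr_pair(rng, 30, 0.8)
        x2, y2 = exact_corr_pair(rng, 30, -0.8)
        expr = _expr(["a", "b"], [np.r_[x1, x2], np.r_[y1, y2]], 60)
        scores = interaction_correlations(
            expr, balanced_labels(30), Interactome.from_pairs([("a", "b")])
        )
        assert scores[0].r2 == pytest.approx(1.6, abs=1e-12)

    def test_independent_noise_has_small_r1(self, balanced_labels):
        rng = np.random.default_rng(2)
        expr = _expr(["a", "b"], rng.normal(size=(2, 1000)), 1000)
        scores = interaction_correlations(
            expr, balanced_labels(500), Interactome.from_pairs([("a", "b")])
        )
        assert scores[0].r1 < 0.1

    def test_constant_gene_skipped(self, balanced_labels):
        expr = _expr(["a", "b"], [np.ones(12), np.arange(12.0)], 12)
        scores = interaction_correlations(
            expr, balanced_labels(6), Interactome.from_pairs([("a", "b")])
        )
        assert scores == []


class TestPercentileRank:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4], [0.25, 0.5, 0.75, 1.0]),
            ([5, 5, 5], [1.0, 1.0, 1.0]),
            ([2, 1, 2], [1.0, 1 / 3, 1.0]),
        ],
    )
    def test_counting_rule(self, values, expected):
        assert percentile_rank(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank([])


class TestBondingScores:
    def test_max_rule_and_extremes(self):
        scores = [
            InteractionScore(("a", "b"), r1=0.9, r2=0.1),
            InteractionScore(("b", "c"), r1=0.2, r2=1.5),
            InteractionScore(("c", "d"), r1=0.5, r2=0.3),
        ]
        bonding_scores(scores)
        assert scores[0].bonding == 1.0  # largest r1
        assert scores[1].bonding == 1.0  # largest r2
        assert scores[2].bonding == pytest.approx(2 / 3)

    def test_single_interaction_degenerate(self):
        scores = bonding_scores([InteractionScore(("a", "b"), 0.1, 0.05)])
        assert scores[0].bonding == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        r1 = rng.uniform(size=20)
        r2 = rng.uniform(size=20)
        plain = bonding_scores(
            [InteractionScore(("g", str(i)), a, b) for i, (a, b) in enumerate(zip(r1, r2))]
        )
        warped = bonding_scores(
            [
                InteractionScore(("g", str(i)), np.exp(3 * a), b**3)
                for i, (a, b) in enumerate(zip(r1, r2))
            ]
        )
        assert [s.bonding for s in plain] == pytest.approx([s.bonding for s in warped])


class TestHotellingT2:
    def test_identical_groups_zero_statistic(self, balanced_labels):
        block = np.tile(np.arange(5.0) + 1, (3, 2))  # both groups identical
        t2, p = hotelling_t2(block, balanced_labels(5))
        assert t2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_univariate_reduces_to_squared_t(self, balanced_labels):
        rng = np.random.default_rng(4)
        x = rng.normal(size=24)
        t2, p = hotelling_t2(x.reshape(1, -1), balanced_labels(12))
        t, pt = stats.ttest_ind(x[:12], x[12:])
        assert t2 == pytest.approx(t**2)
        assert p == pytest.approx(pt)

    def test_matches_explicit_matrix_inversion(self, balanced_labels):
        rng = np.random.default_rng(5)
        labels = balanced_labels(10)
        for _ in range(5):
            X = rng.normal(size=(3, 20))
            t2, _ = hotelling_t2(X, labels)
            X1, X2 = X[:, :10], X[:, 10:]
            d = X1.mean(axis=1) - X2.mean(axis=1)
            S = (9 * np.cov(X1) + 9 * np.cov(X2)) / 18
            oracle = (10 * 10 / 20) * d @ np.linalg.inv(S) @ d
            assert t2 == pytest.approx(oracle, abs=1e-10)

    def test_dimension_guard(self, balanced_labels):
        with pytest.raises(ValueError):
            hotelling_t2(np.zeros((7, 8)), balanced_labels(4))


def _clique_fixture(seed=0, n=60, shift=2.0):
    """Six-gene clique with a strong shared group shift, plus noise genes
    and decoy edges so the clique edges occupy the top bonding decile."""
    rng = np.random.default_rng(seed)
    clique = [f"c{k}" for k in range(6)]
    noise = [f"n{k:02d}" for k in range(40)]
    base = rng.normal(size=n)
    half = n // 2
    grp = np.r_[np.ones(half), np.zeros(n - half)]
    values = {}
    for g in clique:
        values[g] = base + shift * grp + rng.normal(0, 0.4, n)
    for g in noise:
        values[g] = rng.normal(size=n)
    genes = clique + noise
    expr = ExpressionMatrix(genes, [f"s{i:03d}" for i in range(n)],
                            np.vstack([values[g] for g in genes]))
    labels = PhenotypeLabels(expr.sample_ids, ["A"] * half + ["B"] * (n - half))
    pairs = [(a, b) for i, a in enumerate(clique) for b in clique[i + 1:]]
    decoys = []
    while len(decoys) < 120:
        a, b = rng.choice(noise, size=2, replace=False)
        if a != b and (a, b) not in decoys:
            decoys.append((a, b))
    net = Interactome.from_pairs(pairs + decoys)
    return expr, labels, net, clique


class TestExpandModule:
    def test_missing_seed_rejected(self, balanced_labels):
        expr = _expr(["a", "b"], np.random.default_rng(0).normal(size=(2, 12)), 12)
        scores = bonding_scores([InteractionScore(("a", "b"), 0.5, 0.1)])
        with pytest.raises(ValueError):
            expand_module("zz", scores, expr, balanced_labels(6))

    def test_seed_without_scored_neighbors_is_singleton(self, balanced_labels):
        rng = np.random.default_rng(1)
        expr = _expr(["a", "b", "c"], rng.normal(size=(3, 12)), 12)
        scores = bonding_scores([InteractionScore(("a", "b"), 0.5, 0.1)])
        mod = expand_module("c", scores, expr, balanced_labels(6))
        assert mod.members == ["c"]

    def test_all_bondings_below_cutoff_stop(self, balanced_labels):
        rng = np.random.default_rng(2)
        expr = _expr(["a", "b", "c"], rng.normal(size=(3, 12)), 12)
        scores = bonding_scores(
            [InteractionScore(("a", "b"), 0.5, 0.1), InteractionScore(("b", "c"), 0.6, 0.2)]
        )
        mod = expand_module("a", scores, expr, balanced_labels(6), ModuleParams(r_cut=0.99))
        assert mod.members == ["a"]

    @pytest.mark.parametrize("seed_gene", ["c0", "c3", "c5"])
    def test_shifted_clique_recovered_from_any_seed(self, seed_gene):
        expr, labels, net, clique = _clique_fixture()
        scores = bonding_scores(interaction_correlations(expr, labels, net))
        mod = expand_module(seed_gene, scores, expr, labels)
        assert set(clique) <= set(mod.members)
        assert mod.pvalue < 0.05


class TestDiscoverModules:
    def test_clique_modules_deduplicated(self):
        expr, labels, net, clique = _clique_fixture()
        mods = discover_modules(expr, labels, net)
        clique_mods = [m for m in mods if set(clique) <= set(m.members)]
        member_sets = {m.member_set() for m in clique_mods}
        assert len(clique_mods) >= 1
        assert len(member_sets) == len(clique_mods)  # identical sets collapsed

    def test_null_data_yields_few_modules(self, balanced_labels):
        rng = np.random.default_rng(7)
        n_genes, n = 200, 40
        genes = [f"g{k:03d}" for k in range(n_genes)]
        expr = _expr(genes, rng.normal(size=(n_genes, n)), n)
        pairs = set()
        while len(pairs) < 400:
            a, b = rng.choice(n_genes, size=2, replace=False)
            pairs.add((genes[a], genes[b]))
        net = Interactome.from_pairs(sorted(pairs))
        mods = discover_modules(expr, balanced_labels(20), net)
        covered = {g for m in mods for g in m.members}
        assert len(covered) / n_genes <= 0.15
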