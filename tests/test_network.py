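import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from biogasnet.association import COPRESENCE, EXCLUSION, MethodScore
from biogasnet.network import (
    CooccurrenceNetwork,
    bh_adjust,
    bootstrap_pvalue,
    brown_merge,
    select_candidates,
    support_filter,
)
from biogasnet.simulate import recovery_report
from conftest import make_frame


def _scores(method, entries):
    return [MethodScore(pair=p, method=method, score=s, direction=d)
            for p, s, d in entries]


class TestSelectCandidates:
    def test_counts_per_direction(self):
        entries = [((f"a{i}", "z"), 0.1 * (i + 1), COPRESENCE) for i in range(6)]
        entries += [((f"b{i}", "z"), -0.1 * (i + 1), EXCLUSION) for i in range(4)]
        out = select_candidates(_scores("pearson", entries), n_top=3, n_bottom=3)
        picked = out["pearson"]
        assert sum(d == COPRESENCE for _, d in picked) == 3
        assert sum(d == EXCLUSION for _, d in picked) == 3
        # strongest copresence = largest correlation
        assert (("a5", "z"), COPRESENCE) in picked
        assert (("a0", "z"), COPRESENCE) not in picked

    def test_tie_at_boundary_prefers_lexicographic_pair(self):
        entries = [(("a", "b"), 0.5, COPRESENCE), (("a", "c"), 0.5, COPRESENCE)]
        out = select_candidates(_scores("pearson", entries), n_top=1, n_bottom=1)
        assert out["pearson"] == [(("a", "b"), COPRESENCE)]

    def test_overflow_returns_all(self):
        entries = [(("a", "b"), 0.5, COPRESENCE)]
        out = select_candidates(_scores("pearson", entries), n_top=2500, n_bottom=2500)
        assert len(out["pearson"]) == 1

    def test_dissimilarity_ranks_reversed(self):
        entries = [(("a", "b"), 0.1, COPRESENCE), (("a", "c"), 0.3, COPRESENCE)]
        out = select_candidates(_scores("braycurtis", entries), n_top=1, n_bottom=1)
        assert out["braycurtis"] == [(("a", "b"), COPRESENCE)]  # smaller = stronger


class TestSupportFilter:
    def test_majority_direction_wins(self):
        cands = {
            "pearson": [(("a", "b"), COPRESENCE)],
            "spearman": [(("a", "b"), COPRESENCE)],
            "kendall": [(("a", "b"), COPRESENCE)],
            "braycurtis": [(("a", "b"), EXCLUSION)],
            "kl": [(("a", "b"), EXCLUSION)],
        }
        edges = support_filter(cands, min_support=3)
        assert len(edges) == 1
        assert edges[0].direction == COPRESENCE
        assert edges[0].support == 3

    def test_two_methods_insufficient(self):
        cands = {"pearson": [(("a", "b"), COPRESENCE)],
                 "kl": [(("a", "b"), COPRESENCE)]}
        assert support_filter(cands, min_support=3) == []

    def test_unanimous_support_five(self):
        cands = {m: [(("a", "b"), EXCLUSION)]
                 for m in ("pearson", "spearman", "kendall", "braycurtis", "kl")}
        edges = support_filter(cands, min_support=3)
        assert edges[0].support == 5
        assert edges[0].sign == -1

    def test_direction_tie_drops_edge(self):
        cands = {
            "pearson": [(("a", "b"), COPRESENCE)],
            "spearman": [(("a", "b"), COPRESENCE)],
            "braycurtis": [(("a", "b"), EXCLUSION)],
            "kl": [(("a", "b"), EXCLUSION)],
        }
        assert support_filter(cands, min_support=2) == []


class TestBootstrapPvalue:
    def test_degenerate_perfect_pair_gives_zero(self):
        x = np.arange(1.0, 9.0)
        X = make_frame(np.column_stack([x, 2 * x]), features=["a", "b"])
        assert bootstrap_pvalue(X, ("a", "b"), "pearson", seed=0) == 0.0

    def test_same_seed_reproducible(self, rng):
        X = make_frame(rng.random((12, 2)), features=["a", "b"])
        p1 = bootstrap_pvalue(X, ("a", "b"), "kl", seed=42)
        p2 = bootstrap_pvalue(X, ("a", "b"), "kl", seed=42)
        assert p1 == p2
        assert bootstrap_pvalue(X, ("a", "b"), "kl", seed=43) != p1

    def test_type_one_error_near_nominal_under_null(self):
        # 200 independent null pairs; empirical rejection at alpha = 0.1 must
        # sit inside the exact binomial 99% interval [0.047, 0.158]
        rng = np.random.default_rng(0)
        rejections = 0
        for k in range(200):
            X = make_frame(np.exp(rng.normal(0, 1, (40, 2))), features=["a", "b"])
            p = bootstrap_pvalue(X, ("a", "b"), "pearson", seed=k)
            rejections += p < 0.1
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.1) / 200
        assert lo <= rejections / 200 <= hi

    def test_strong_signal_small_p(self, rng):
        x = np.sort(rng.random(30))
        X = make_frame(np.column_stack([x, x + rng.normal(0, 0.01, 30)]),
                       features=["a", "b"])
        assert bootstrap_pvalue(X, ("a", "b"), "spearman", seed=0) < 1e-6


class TestBrownMerge:
    def test_reduces_to_fisher_at_zero_covariance(self, rng):
        for _ in range(20):
            p = rng.uniform(0.001, 1.0, rng.integers(2, 6))
            X = -2 * np.log(p).sum()
            fisher = stats.chi2.sf(X, 2 * len(p))
            assert brown_merge(p, cov=np.zeros((len(p), len(p)))) == pytest.approx(fisher)
            assert brown_merge(p) == pytest.approx(fisher)

    def test_total_dependence_returns_shared_p(self):
        for shared in (0.001, 0.05, 0.5, 0.99):
            k = 4
            cov = np.full((k, k), 4.0)
            np.fill_diagonal(cov, 0.0)
            assert brown_merge([shared] * k, cov=cov) == pytest.approx(shared, rel=1e-9)

    def test_single_p_identity(self):
        assert brown_merge([0.37]) == pytest.approx(0.37)

    def test_zero_p_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            p = brown_merge([0.0, 0.5])
        assert 0 < p < 1e-100
        assert any("clamped" in r.message for r in caplog.records)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            brown_merge([1.5])
        with pytest.raises(ValueError):
            brown_merge([0.1, 0.2], cov=np.zeros((3, 3)))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q, keep = bh_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert keep.all()

    def test_single_p(self):
        q, _ = bh_adjust([0.2])
        assert q[0] == pytest.approx(0.2)

    @given(st.floats(min_value=0.001, max_value=0.2))
    def test_shrinking_alpha_never_enlarges_keep_set(self, alpha):
        p = [0.001, 0.01, 0.04, 0.2, 0.6]
        _, keep_hi = bh_adjust(p, alpha=alpha)
        _, keep_lo = bh_adjust(p, alpha=alpha / 2)
        assert (keep_lo <= keep_hi).all()


class TestInferNetwork:
    def test_planted_structure_recovery(self, benchmark_dataset, benchmark_network):
        *_, truth = benchmark_dataset
        report = recovery_report(truth, graph=benchmark_network.graph_)
        assert report["edge_recall"] >= 0.9
        assert report["edge_precision"] >= 0.9

    def test_retained_edges_satisfy_contracts(self, benchmark_network):
        est = benchmark_network
        kept = est.edges_[est.edges_["kept"]]
        assert (kept["q"] < est.alpha).all()
        assert (kept["support"] >= est.min_support).all()
        tested_pairs = set(map(tuple, est.edges_[["species_a", "species_b"]].to_numpy()))
        for a, b in est.graph_.edges:
            assert tuple(sorted((a, b))) in tested_pairs
            assert a != b

    def test_null_table_retains_few_edges(self, benchmark_species_table):
        rng = np.random.default_rng(7)
        Xn = benchmark_species_table.copy()
        for c in Xn.columns:
            Xn[c] = rng.permutation(Xn[c].to_numpy())
        est = CooccurrenceNetwork(seed=11).fit(Xn)
        assert est.n_candidates_tested_ > 100
        frac = est.graph_.number_of_edges() / est.n_candidates_tested_
        assert frac <= 0.05

    def test_same_seed_same_network(self, benchmark_species_table, benchmark_network):
        sub = benchmark_species_table.iloc[:, :12]
        a = CooccurrenceNetwork(seed=5).fit(sub)
        b = CooccurrenceNetwork(seed=5).fit(sub)
        assert list(a.graph_.edges(data=True)) == list(b.graph_.edges(data=True))
        assert a.edges_.equals(b.edges_)

    def test_too_few_samples_rejected(self):
        X = make_frame(np.random.default_rng(0).random((2, 5)))
        with pytest.raises(ValueError, match="at least 3"):
            CooccurrenceNetwork().fit(X)
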