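import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, rankdata
from sklearn.metrics import adjusted_rand_score

import srfusion as sf
from srfusion.evaluation import ContingencyTable, similarity_to_distance
from srfusion.integrate import SubtypeLabels
from srfusion.omics_io import SurvivalTable
from srfusion.similarity import SimilarityMatrix

from conftest import make_view


def brute_force_logrank(time, event, group):
    """Independent G-sample log-rank oracle: loop over distinct event times,
    accumulate observed-minus-expected per group and the hypergeometric
    covariance, invert on G-1 groups."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    gids = np.unique(group)
    G = len(gids)
    OmE = np.zeros(G)
    V = np.zeros((G, G))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        for a, ga in enumerate(gids):
            na = (at_risk & (group == ga)).sum()
            da = ((time == t) & (event == 1) & (group == ga)).sum()
            OmE[a] += da - d * na / n
            for b, gb in enumerate(gids):
                nb = (at_risk & (group == gb)).sum()
                same = 1.0 if a == b else 0.0
                if n > 1:
                    V[a, b] += d * (na / n) * (same - nb / n) * (n - d) / (n - 1)
    stat = OmE[:-1] @ np.linalg.solve(V[:-1, :-1], OmE[:-1])
    return stat, chi2.sf(stat, G - 1)


def _surv(ids, times, events):
    return SurvivalTable(list(ids), np.array(times, float), np.array(events, int))


def _labels(ids, labs):
    return SubtypeLabels(list(ids), np.array(labs, int))


class TestLogrank:
    def test_identical_groups_give_null(self):
        ids = [f"s{i}" for i in range(8)]
        surv = _surv(ids, [1, 2, 3, 4, 1, 2, 3, 4], [1, 1, 0, 1, 1, 1, 0, 1])
        res = sf.logrank_test(surv, _labels(ids, [1, 1, 1, 1, 2, 2, 2, 2]))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)
        assert res.df == 1

    def test_matches_brute_force_oracle_two_groups(self):
        ids = ["a", "b", "c", "d"]
        surv = _surv(ids, [1, 2, 10, 12], [1, 1, 1, 1])
        labels = _labels(ids, [1, 1, 2, 2])
        res = sf.logrank_test(surv, labels)
        stat, p = brute_force_logrank(surv.time, surv.event, labels.labels)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_with_ties_and_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        ids = [f"s{i}" for i in range(n)]
        time = rng.integers(1, 5, n).astype(float)  # forced ties
        event = rng.integers(0, 2, n)
        group = rng.integers(1, 3, n)
        if event.sum() == 0 or len(np.unique(group)) < 2:
            pytest.skip("degenerate draw")
        group = SubtypeLabels(ids, np.searchsorted(np.unique(group), group) + 1).labels
        res = sf.logrank_test(_surv(ids, time, event), _labels(ids, group))
        stat, p = brute_force_logrank(time, event, group)
        assert res.statistic == pytest.approx(stat, abs=1e-10)

    def test_group_name_and_row_order_invariance(self):
        ids = [f"s{i}" for i in range(6)]
        surv = _surv(ids, [3, 1, 4, 1, 5, 9], [1, 1, 0, 1, 1, 1])
        a = sf.logrank_test(surv, _labels(ids, [1, 1, 1, 2, 2, 2]))
        # relabel groups (2<->1) and permute rows of the survival table
        perm = [4, 2, 0, 5, 3, 1]
        surv_p = _surv([ids[i] for i in perm], surv.time[perm], surv.event[perm])
        b = sf.logrank_test(surv_p, _labels(ids, [2, 2, 2, 1, 1, 1]))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_single_group_and_zero_events_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError, match="2 groups"):
            sf.logrank_test(_surv(ids, [1, 2, 3], [1, 1, 1]), _labels(ids, [1, 1, 1]))
        with pytest.raises(ValueError, match="events"):
            sf.logrank_test(_surv(ids, [1, 2, 3], [0, 0, 0]), _labels(ids, [1, 1, 2]))

    def test_samples_without_survival_dropped(self):
        ids = ["a", "b", "c", "d"]
        surv = _surv(["a", "b", "c"], [1, 2, 3], [1, 1, 1])
        res = sf.logrank_test(surv, _labels(ids, [1, 1, 2, 2]))
        assert res.df == 1  # ran on the 3 covered samples

    def test_type_one_error_calibrated(self):
        """3 equal-hazard exponential groups: rejection rate at alpha=0.05
        stays inside the binomial 99% interval over 500 replications.  100
        subjects per group, where the chi-square reference is accurate (the
        log-rank test is mildly anti-conservative below ~50 per group)."""
        rng = np.random.default_rng(2025)
        alpha, reps, n = 0.05, 500, 300
        rejections = 0
        ids = [f"s{i}" for i in range(n)]
        group = np.repeat([1, 2, 3], n // 3)
        for _ in range(reps):
            time = rng.exponential(100.0, n)
            res = sf.logrank_test(_surv(ids, time, np.ones(n)), _labels(ids, group))
            rejections += res.p < alpha
        half_width = 2.576 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < half_width


class TestKMCurve:
    def test_product_limit_by_hand(self):
        curve = sf.km_curve([1.0, 2.0], [1, 1])
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)

    def test_censoring_reduces_risk_set_without_step(self):
        # death at 1 (n=3 at risk) -> 2/3; censor at 2; death at 3 (1 at risk) -> 0
        curve = sf.km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = sf.km_curve([1.0, 5.0, 9.0], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_monotone_non_increasing(self, rng):
        curve = sf.km_curve(rng.exponential(5, 30), rng.integers(0, 2, 30))
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sf.km_curve([], [])


def brute_force_silhouette(D, labels):
    labels = np.asarray(labels)
    n = len(labels)
    scores = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = D[i, same].mean() if same.any() else 0.0
        b = min(
            D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        scores[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return scores.mean()


class TestSilhouette:
    def _sim(self, W):
        return SimilarityMatrix([f"s{i}" for i in range(len(W))], W, "fused")

    def test_two_tight_blocks_score_high(self):
        groups = np.repeat([1, 2], 4)
        W = np.where(groups[:, None] == groups[None, :], 0.9, 0.1)
        np.fill_diagonal(W, 0.9)
        score, coherent = sf.silhouette_from_similarity(
            self._sim(W), _labels([f"s{i}" for i in range(8)], groups)
        )
        assert score > 0.7 and coherent

    def test_uniform_similarity_scores_zero(self):
        W = np.full((6, 6), 0.4)
        score, coherent = sf.silhouette_from_similarity(
            self._sim(W), _labels([f"s{i}" for i in range(6)], [1, 1, 1, 2, 2, 2])
        )
        assert score == 0.0 and not coherent

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_matches_brute_force_oracle(self, seed, rng):
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.1, 0.9, (7, 7))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        labels = np.array([1, 1, 2, 2, 2, 1, 2])
        score, _ = sf.silhouette_from_similarity(
            self._sim(W), _labels([f"s{i}" for i in range(7)], labels)
        )
        D = similarity_to_distance(W)
        assert score == pytest.approx(brute_force_silhouette(D, labels), abs=1e-12)

    def test_single_cluster_rejected(self):
        W = np.full((4, 4), 0.5)
        with pytest.raises(ValueError):
            sf.silhouette_from_similarity(
                self._sim(W), _labels([f"s{i}" for i in range(4)], [1, 1, 1, 1])
            )

    def test_distance_conversion_properties(self, rng):
        W = rng.uniform(0, 1, (5, 5))
        W = (W + W.T) / 2
        D = similarity_to_distance(W)
        assert (np.diag(D) == 0).all() and (D >= 0).all()
        off = ~np.eye(5, dtype=bool)
        # ordering preserved: larger similarity -> smaller distance
        order_w = np.argsort(W[off])
        order_d = np.argsort(-D[off])
        np.testing.assert_array_equal(order_w, order_d)


# Printed overlap tables: found clusters vs external subtype labels.
PAM50_TABLE = np.array(
    [[0, 1, 0, 18, 4],
     [0, 2, 0, 3, 6],
     [17, 6, 16, 0, 16],
     [4, 6, 0, 0, 2],
     [0, 0, 1, 1, 0]]
)
GBM_TABLE = np.array(
    [[2, 44, 12],
     [0, 28, 38],
     [3, 25, 6],
     [37, 15, 5]]
)


class TestARI:
    def test_identical_labelings(self):
        labs = {f"s{i}": v for i, v in enumerate([1, 1, 2, 2, 3, 3])}
        assert sf.adjusted_rand_index(labs, labs) == pytest.approx(1.0)

    def test_breast_pam50_overlap_table(self):
        ct = ContingencyTable(
            ["Basal", "Her2", "LumA", "LumB", "Normal"],
            ["C1", "C2", "C3", "C4", "C5"],
            PAM50_TABLE,
        )
        assert ct.counts.sum() == 103
        assert sf.ari_from_contingency(ct) == pytest.approx(0.20, abs=0.005)

    def test_gbm_overlap_table(self):
        ct = ContingencyTable(
            ["Classical", "Mesenchymal", "Neural", "Proneural"],
            ["C1", "C2", "C3"],
            GBM_TABLE,
        )
        assert ct.counts.sum() == 215
        assert sf.ari_from_contingency(ct) == pytest.approx(0.173, abs=0.0005)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_sklearn_on_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 40)
        b = rng.integers(0, 3, 40)
        ids = [f"s{i}" for i in range(40)]
        ours = sf.adjusted_rand_index(dict(zip(ids, a)), dict(zip(ids, b)))
        assert ours == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)

    def test_symmetric_and_permutation_invariant(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        ids = [f"s{i}" for i in range(30)]
        la, lb = dict(zip(ids, a)), dict(zip(ids, b))
        assert sf.adjusted_rand_index(la, lb) == pytest.approx(
            sf.adjusted_rand_index(lb, la), abs=1e-15
        )
        relabeled = {k: {0: "x", 1: "y", 2: "z"}[v] for k, v in lb.items()}
        assert sf.adjusted_rand_index(la, relabeled) == pytest.approx(
            sf.adjusted_rand_index(la, lb), abs=1e-15
        )

    def test_against_single_cluster_is_zero(self):
        ids = [f"s{i}" for i in range(10)]
        a = dict(zip(ids, [1, 1, 2, 2, 3, 3, 1, 2, 3, 1]))
        ones = dict(zip(ids, [1] * 10))
        assert sf.adjusted_rand_index(a, ones) == 0.0

    def test_partial_overlap_uses_labeled_subset(self):
        a = {f"s{i}": i % 2 for i in range(10)}
        b = {f"s{i}": i % 2 for i in range(8)}  # two samples unlabeled
        assert sf.adjusted_rand_index(a, b) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="shared"):
            sf.adjusted_rand_index({"x": 1, "y": 2}, {"z": 1, "w": 2})


def kw_by_hand(groups):
    """Direct rank-sum formula with tie correction."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = rankdata(all_vals)
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
    return H / tie


class TestKruskalWallisDE:
    def _fixture(self):
        rng = np.random.default_rng(61)
        n = 12
        labels = np.repeat([1, 2, 3], 4)
        vals = rng.normal(size=(n, 4))
        vals[:, 0] += labels * 5.0       # strongly differential
        vals[:, 1] = 2.5                  # all tied
        view = make_view(vals)
        return view, SubtypeLabels(view.samples, labels)

    def test_h_matches_rank_formula(self):
        view, labels = self._fixture()
        table = sf.kruskal_wallis_de(view, labels, fdr_threshold=0.05)
        col = view.values[:, 0]
        groups = [col[labels.labels == c] for c in (1, 2, 3)]
        assert table["H"].iloc[0] == pytest.approx(kw_by_hand(groups), abs=1e-10)

    def test_constant_feature_convention(self):
        view, labels = self._fixture()
        table = sf.kruskal_wallis_de(view, labels, fdr_threshold=0.05)
        assert table["H"].iloc[1] == 0.0 and table["p"].iloc[1] == 1.0

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_q_monotone_and_significant_set(self):
        view, labels = self._fixture()
        table = sf.kruskal_wallis_de(view, labels, fdr_threshold=0.05)
        srt = table.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-15).all()
        m = len(table)
        passing = [
            (i, p) for i, p in enumerate(np.sort(table["p"]), start=1)
            if p <= 0.05 * i / m
        ]
        k = max([i for i, _ in passing], default=0)
        assert table["significant"].sum() == k

    def test_small_cluster_rejected(self):
        view, _ = self._fixture()
        labels = SubtypeLabels(view.samples, np.r_[[1] * 11, [2]])
        with pytest.raises(ValueError, match="< 2 members"):
            sf.kruskal_wallis_de(view, labels)
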