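"""The six post-hoc validation strategies."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from featmatch import (MissingDataError, PoorMatchConfig, SimulationParams,
                       ThresholdSpec, annotation_agreement, covariate_agreement,
                       fi_correlation, generate_pair, match_pair, match_summary,
                       npeaks_delta, pattern_score)

from conftest import make_featureset, make_match_df


def _status_df(pairs, status="unique"):
    df = make_match_df([{"ref": r, "target": t} for r, t in pairs])
    df["status"] = status
    return df


class TestAnnotationAgreement:
    def _sets(self, ref_ann, tgt_ann):
        n_r, n_t = len(ref_ann), len(tgt_ann)
        ref = make_featureset([f"r{i}" for i in range(n_r)],
                              np.arange(1, n_r + 1), 100 + np.arange(n_r),
                              annotation=ref_ann)
        tgt = make_featureset([f"t{i}" for i in range(n_t)],
                              np.arange(1, n_t + 1), 100 + np.arange(n_t),
                              annotation=tgt_ann)
        return ref, tgt

    def test_correct_matching_counted(self):
        ref, tgt = self._sets(["A", "B"], ["A", "B"])
        out = annotation_agreement(_status_df([("r0", "t0"), ("r1", "t1")]),
                                   ref, tgt)
        assert out == {"common": 2, "correct": 2, "wrong": 0, "not_matched": 0}

    def test_cross_matching_counts_both_wrong(self):
        ref, tgt = self._sets(["A", "B"], ["B", "A"])
        out = annotation_agreement(_status_df([("r0", "t0"), ("r1", "t1")]),
                                   ref, tgt)
        assert out["common"] == 2 and out["correct"] == 0 and out["wrong"] == 2

    def test_label_in_one_set_only_excluded(self):
        ref, tgt = self._sets(["A", "C"], ["A", ""])
        out = annotation_agreement(_status_df([("r0", "t0")]), ref, tgt)
        assert out["common"] == 1 and out["correct"] == 1

    def test_unmatched_common_label_counted(self):
        ref, tgt = self._sets(["A", "B"], ["A", "B"])
        out = annotation_agreement(_status_df([("r0", "t0")]), ref, tgt)
        assert out["not_matched"] == 1

    def test_requires_annotations(self):
        ref, _ = self._sets(["A"], ["A"])
        bare = make_featureset(["t0"], [1.0], [100.0])
        with pytest.raises(MissingDataError):
            annotation_agreement(_status_df([("r0", "t0")]), ref, bare)


class TestFICorrelation:
    def test_proportional_fi_gives_spearman_one(self):
        fi = np.array([1e4, 1e5, 1e6, 1e7])
        ref = make_featureset([f"r{i}" for i in range(4)], np.arange(1, 5),
                              100 + np.arange(4), fi)
        tgt = make_featureset([f"t{i}" for i in range(4)], np.arange(1, 5),
                              100 + np.arange(4), 3.7 * fi)
        m = _status_df([(f"r{i}", f"t{i}") for i in range(4)])
        m["ref_index"] = range(4)
        m["target_index"] = range(4)
        out = fi_correlation(m, ref, tgt)
        assert out["spearman"] == pytest.approx(1.0)
        assert out["pearson"] == pytest.approx(1.0)

    def test_constant_fi_reported_undefined(self):
        ref = make_featureset(["r0", "r1"], [1, 2], [100, 200], [1e5, 1e6])
        tgt = make_featureset(["t0", "t1"], [1, 2], [100, 200], [1e4, 1e4])
        m = _status_df([("r0", "t0"), ("r1", "t1")])
        m["ref_index"] = [0, 1]
        m["target_index"] = [0, 1]
        out = fi_correlation(m, ref, tgt)
        assert np.isnan(out["spearman"]) and "undefined" in out["note"]

    def test_matches_independent_rank_oracle(self, rng):
        sim = generate_pair(SimulationParams(n_ref=120, n_shared=100, seed=3))
        res = match_pair(sim.ref, sim.target,
                         ThresholdSpec.symmetric(rt=0.5, mz=0.01, fi=1.0))
        out = fi_correlation(res.matches, sim.ref, sim.target)
        rho = stats.spearmanr(out["ref_log10fi"], out["target_log10fi"]).statistic
        assert out["spearman"] == pytest.approx(rho)
        assert out["spearman"] > 0.9  # FI noise sd 0.05 barely perturbs ranks


def _dataset_with_slopes(ids, slopes, covariate, noise_sd=0.02, seed=0):
    """Sample matrix where feature j = 5 + slopes[j] * z(covariate) + noise."""
    r = np.random.default_rng(seed)
    z = (covariate - covariate.mean()) / covariate.std()
    logx = 5.0 + np.outer(z, slopes) + r.normal(0, noise_sd, (len(z), len(slopes)))
    fs = make_featureset(ids, np.arange(1, len(ids) + 1),
                         100 + np.arange(len(ids)),
                         fi=10 ** np.full(len(ids), 5.0),
                         sample_intensities=pd.DataFrame(10.0 ** logx))
    return fs


class TestCovariateAgreement:
    def _matched(self, n):
        m = _status_df([(f"r{i}", f"t{i}") for i in range(n)])
        m["ref_index"] = range(n)
        m["target_index"] = range(n)
        return m

    def test_identical_positive_slopes_agree_everywhere(self):
        n, ns = 8, 40
        cov_r = pd.DataFrame({"age": np.linspace(30, 70, ns)})
        cov_t = pd.DataFrame({"age": np.linspace(35, 80, ns)})
        slopes = np.full(n, 0.5)
        ref = _dataset_with_slopes([f"r{i}" for i in range(n)], slopes,
                                   cov_r["age"].to_numpy(), seed=1)
        tgt = _dataset_with_slopes([f"t{i}" for i in range(n)], slopes,
                                   cov_t["age"].to_numpy(), seed=2)
        for flt in ("all", "nominal", "fdr", "bonferroni"):
            out = covariate_agreement(self._matched(n), ref, tgt, cov_r, cov_t,
                                      binary=(), filter=flt)
            assert out["age"]["agreement"] == 1.0 and out["age"]["n"] == n

    def test_null_covariate_agreement_near_half(self):
        n, ns = 200, 30
        r = np.random.default_rng(5)
        cov_r = pd.DataFrame({"age": r.normal(50, 10, ns)})
        cov_t = pd.DataFrame({"age": r.normal(50, 10, ns)})
        ref = _dataset_with_slopes([f"r{i}" for i in range(n)], np.zeros(n),
                                   cov_r["age"].to_numpy(), noise_sd=1.0, seed=6)
        tgt = _dataset_with_slopes([f"t{i}" for i in range(n)], np.zeros(n),
                                   cov_t["age"].to_numpy(), noise_sd=1.0, seed=7)
        out = covariate_agreement(self._matched(n), ref, tgt, cov_r, cov_t,
                                  binary=(), filter="all")
        tol = 3 * np.sqrt(0.25 / n)
        assert abs(out["age"]["agreement"] - 0.5) <= tol

    def test_opposite_slope_disagrees_at_every_filter(self):
        n, ns = 5, 40
        cov = pd.DataFrame({"age": np.linspace(30, 70, ns)})
        s_ref = np.full(n, 0.5)
        s_tgt = s_ref.copy()
        s_tgt[2] = -0.5  # one feature simulated with the opposite association
        ref = _dataset_with_slopes([f"r{i}" for i in range(n)], s_ref,
                                   cov["age"].to_numpy(), seed=1)
        tgt = _dataset_with_slopes([f"t{i}" for i in range(n)], s_tgt,
                                   cov["age"].to_numpy(), seed=2)
        for flt in ("all", "nominal", "fdr", "bonferroni"):
            out = covariate_agreement(self._matched(n), ref, tgt, cov, cov,
                                      binary=(), filter=flt)
            assert out["age"]["n"] == n
            assert out["age"]["agreement"] == pytest.approx((n - 1) / n)

    def test_binary_covariate_median_fold_change(self):
        n, ns = 6, 60
        sex = np.array([0.0, 1.0] * (ns // 2))
        cov = pd.DataFrame({"sex": sex})
        slopes = np.array([0.6, -0.6, 0.6, 0.6, -0.6, 0.6])
        ref = _dataset_with_slopes([f"r{i}" for i in range(n)], slopes, sex, seed=3)
        tgt = _dataset_with_slopes([f"t{i}" for i in range(n)], slopes, sex, seed=4)
        out = covariate_agreement(self._matched(n), ref, tgt, cov, cov,
                                  binary=("sex",), filter="nominal")
        assert out["sex"]["agreement"] == 1.0

    def test_constant_covariate_excluded(self, caplog):
        n, ns = 3, 20
        cov = pd.DataFrame({"flat": np.ones(ns)})
        ref = _dataset_with_slopes([f"r{i}" for i in range(n)], np.zeros(n),
                                   np.arange(ns, dtype=float), seed=1)
        tgt = _dataset_with_slopes([f"t{i}" for i in range(n)], np.zeros(n),
                                   np.arange(ns, dtype=float), seed=2)
        with caplog.at_level("WARNING"):
            out = covariate_agreement(self._matched(n), ref, tgt, cov, cov,
                                      binary=(), filter="all")
        assert out == {} and "constant" in caplog.text


class TestNpeaksDelta:
    def _cluster_fixture(self):
        ref = make_featureset(["r0", "r1"], [1, 2], [100, 200],
                              npeaks=[900, 100])
        tgt = make_featureset(["t0", "t1", "t2"], [1, 2, 3], [100, 200, 300],
                              npeaks=[300, 800, 50])
        # cluster: r0-t0 (selected), r0-t1 (discarded, shares ref -> target delta)
        #          r1-t0 (discarded, shares target with r0-t0 -> ref delta)
        m = make_match_df([
            {"ref": "r0", "target": "t0", "ref_index": 0, "target_index": 0},
            {"ref": "r0", "target": "t1", "ref_index": 0, "target_index": 1},
            {"ref": "r1", "target": "t0", "ref_index": 1, "target_index": 0}])
        m["status"] = ["unique", "discarded_in_cluster", "discarded_in_cluster"]
        return ref, tgt, m

    def test_hand_checked_deltas(self):
        ref, tgt, m = self._cluster_fixture()
        out = npeaks_delta(m, ref, tgt)
        assert out["target_deltas"] == [300 - 800]
        assert out["ref_deltas"] == [900 - 100]
        assert out["fraction_positive"] == 0.5

    def test_selected_minus_discarded_sign(self):
        ref = make_featureset(["r0"], [1], [100], npeaks=[900])
        tgt = make_featureset(["t0", "t1"], [1, 1.01], [100, 100.001],
                              npeaks=[900, 300])
        m = make_match_df([
            {"ref": "r0", "target": "t0", "ref_index": 0, "target_index": 0},
            {"ref": "r0", "target": "t1", "ref_index": 0, "target_index": 1}])
        m["status"] = ["unique", "discarded_in_cluster"]
        out = npeaks_delta(m, ref, tgt)
        assert out["target_deltas"] == [600] and out["fraction_positive"] == 1.0

    def test_no_multi_edge_clusters_empty(self):
        ref = make_featureset(["r0"], [1], [100], npeaks=[10])
        tgt = make_featureset(["t0"], [1], [100], npeaks=[10])
        m = make_match_df([{"ref": "r0", "target": "t0", "ref_index": 0,
                            "target_index": 0, "is_unique": True}])
        m["status"] = "unique"
        out = npeaks_delta(m, ref, tgt)
        assert out["ref_deltas"] == [] and out["target_deltas"] == []

    def test_requires_npeaks(self):
        ref, tgt, m = self._cluster_fixture()
        bare = make_featureset(["t0", "t1", "t2"], [1, 2, 3], [100, 200, 300])
        with pytest.raises(MissingDataError):
            npeaks_delta(m, ref, bare)


def _correlated_sets(n_block, n_far=1, n_samples=30, seed=0):
    """Two feature sets whose first n_block features co-elute (RT ~5 min,
    within a sub-second window) and share one latent intensity factor."""
    r = np.random.default_rng(seed)
    n = n_block + n_far

    def build(prefix):
        rt = np.concatenate([5.0 + np.linspace(0, 0.001, n_block),
                             7.0 + np.arange(n_far)])
        u = r.normal(0, 1, n_samples)
        logx = np.empty((n_samples, n))
        for j in range(n):
            if j < n_block:
                logx[:, j] = 5 + u + r.normal(0, 0.05, n_samples)
            else:
                logx[:, j] = 5 + r.normal(0, 1.0, n_samples)
        return make_featureset([f"{prefix}{i}" for i in range(n)], rt,
                               100 + np.arange(n) * 10.0,
                               fi=np.full(n, 1e5),
                               sample_intensities=pd.DataFrame(10.0 ** logx))

    return build("r"), build("t")


class TestPatternScore:
    def _matches(self, pairs):
        m = _status_df(pairs)
        m["ref_index"] = [int(r[1:]) for r, _ in pairs]
        m["target_index"] = [int(t[1:]) for _, t in pairs]
        return m

    def test_ratio_arithmetic(self):
        # |R|=2, |T|=3 correlated neighbors; both R members matched into T
        ref, tgt = _correlated_sets(n_block=3, seed=1)
        ref4, tgt4 = _correlated_sets(n_block=4, seed=1)
        m = self._matches([("r0", "t0"), ("r1", "t1"), ("r2", "t2")])
        out = pattern_score(m, ref, tgt4, rt_window=0.25, corr_threshold=0.7)
        row = out[out["ref_id"] == "r0"].iloc[0]
        assert (row["n_R"], row["n_T"], row["n_common"]) == (2, 3, 2)
        assert row["pattern_score"] == pytest.approx(2 / 3)

    def test_empty_neighbor_set_scores_zero(self):
        ref, tgt = _correlated_sets(n_block=1, n_far=2, seed=2)
        m = self._matches([("r0", "t0")])
        out = pattern_score(m, ref, tgt)
        assert out["pattern_score"].iloc[0] == 0.0

    def test_fully_matched_block_of_four(self):
        ref, tgt = _correlated_sets(n_block=4, seed=3)
        m = self._matches([(f"r{i}", f"t{i}") for i in range(4)])
        out = pattern_score(m, ref, tgt)
        np.testing.assert_allclose(out["pattern_score"], 3 / 4)
        assert (out["n_common"] == 3).all()

    def test_bounds(self):
        ref, tgt = _correlated_sets(n_block=4, seed=4)
        m = self._matches([(f"r{i}", f"t{i}") for i in range(4)])
        out = pattern_score(m, ref, tgt)
        mn = np.minimum(out["n_R"], out["n_T"])
        assert ((out["pattern_score"] >= 0)
                & (out["pattern_score"] <= mn / (mn + 1))).all()

    def test_correct_matches_outscore_corrupted(self):
        sim = generate_pair(SimulationParams(
            n_ref=240, n_shared=180, n_samples=40, adduct_block_size=3, seed=8))
        res = match_pair(sim.ref, sim.target,
                         ThresholdSpec.symmetric(rt=0.5, mz=0.01, fi=1.0))
        good = pattern_score(res.matches, sim.ref, sim.target)
        corrupted = res.matches.copy()
        sel = corrupted.index[corrupted["status"] == "unique"]
        t = corrupted.loc[sel, ["target_index", "target_id"]].to_numpy()
        corrupted.loc[sel, ["target_index", "target_id"]] = np.roll(t, 1, axis=0)
        bad = pattern_score(corrupted, sim.ref, sim.target)
        assert good["pattern_score"].mean() > bad["pattern_score"].mean()
        assert good["pattern_score"].mean() > 0.3

    def test_requires_sample_matrices(self):
        ref = make_featureset(["r0"], [1], [100], [1e5])
        tgt = make_featureset(["t0"], [1], [100], [1e5])
        with pytest.raises(MissingDataError):
            pattern_score(self._matches([("r0", "t0")]), ref, tgt)


class TestMatchSummary:
    def test_grid_fixture_counts(self):
        from featmatch import label_clusters
        m = label_clusters(make_match_df(
            [{"ref": f"r{i}", "target": f"t{j}", "ref_index": i, "target_index": j}
             for i in range(3) for j in range(3)]))
        s = match_summary(m)
        assert s["candidates"] == 9 and s["multi_match_clusters"] == 1
        assert s["step1_unique"] == 0

    def test_accounting_identity_on_pipeline_run(self, small_sim,
                                                 default_thresholds):
        res = match_pair(small_sim.ref, small_sim.target, default_thresholds,
                         poor=PoorMatchConfig())
        s = res.summary
        assert s["candidates"] == s["selected_unique"] + s["discarded_in_cluster"]
        assert s["selected_unique"] == s["final_unique"] + s["poor"]
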