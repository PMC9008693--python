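"""Post-hoc validation strategies for a matching result.

Without exhaustive annotations there is no absolute truth for a real-data
matching, but several orthogonal lines of evidence can be checked:

1. agreement of manual annotations present in both datasets;
2. correlation of matched features' log10 intensities;
3. agreement of the direction of association with known sample covariates
   (age/BMI by per-feature linear regression, sex by median log10 fold
   change + t-test), at increasingly stringent significance filters;
4. npeaks difference between selected and discarded features in resolved
   multi-match clusters (detected-in-more-samples as a quality proxy);
5. the ratio of unique matches to multi-match clusters;
6. the patternScore: each metabolite usually carries a block of highly
   correlated adduct/isotopologue features co-eluting within a sub-second
   window; matched features should have matching blocks.  For a match,
   R (resp. T) is the set of other features of the reference (target)
   within the RT window and Spearman-correlated above the threshold with
   the matched feature, and

       patternScore = |common| / (min(|R|, |T|) + 1)

   where *common* counts pairs from R and T that are themselves joined by a
   selected match (the +1 avoids division by zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MissingDataError, ValidationError
from .io import FeatureSet
from .pipeline import summarize

logger = logging.getLogger(__name__)

_STAGES = {"selected": ("unique", "poor"), "final": ("unique",)}


def _stage_matches(matches: pd.DataFrame, stage: str) -> pd.DataFrame:
    if stage not in _STAGES:
        raise ValueError(f"stage must be one of {sorted(_STAGES)}")
    return matches[matches["status"].isin(_STAGES[stage])]


def annotation_agreement(matches: pd.DataFrame, ref: FeatureSet,
                         target: FeatureSet, stage: str = "final") -> dict:
    """Strategy 1 — tally annotations shared by both sets and how they fared.

    For every annotation label present (non-empty) in both datasets:
    *correct* if a match of the requested stage joins two features with that
    label, *wrong* if a labeled feature was matched to a feature without the
    same label, *not_matched* otherwise (outside thresholds or removed).
    """
    if ref.annotation is None or target.annotation is None:
        raise MissingDataError("annotation agreement requires annotations in both sets")
    sel = _stage_matches(matches, stage)
    ref_ann = dict(zip(ref.feature_id, ref.annotation))
    tgt_ann = dict(zip(target.feature_id, target.annotation))
    common = ({a for a in ref.annotation if a} & {a for a in target.annotation if a})

    matched_pairs = [(ref_ann.get(r, ""), tgt_ann.get(t, ""))
                     for r, t in zip(sel["ref_id"], sel["target_id"])]
    correct_labels = {a for a, b in matched_pairs if a and a == b and a in common}
    touched = ({a for a, _ in matched_pairs if a in common}
               | {b for _, b in matched_pairs if b in common})
    wrong_labels = touched - correct_labels
    return {
        "common": len(common),
        "correct": len(correct_labels),
        "wrong": len(wrong_labels),
        "not_matched": len(common) - len(correct_labels) - len(wrong_labels),
    }


def fi_correlation(matches: pd.DataFrame, ref: FeatureSet, target: FeatureSet,
                   stage: str = "final") -> dict:
    """Strategy 2 — correlation of matched log10FI values across the datasets."""
    if not ref.has_fi or not target.has_fi:
        raise MissingDataError("fi correlation requires FI in both sets")
    sel = _stage_matches(matches, stage)
    x = ref.log10fi[sel["ref_index"].to_numpy()]
    y = target.log10fi[sel["target_index"].to_numpy()]
    out = {"n": len(sel), "ref_log10fi": x, "target_log10fi": y}
    if len(sel) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        out.update(pearson=float("nan"), spearman=float("nan"),
                   note="correlation undefined (fewer than 2 pairs or constant FI)")
        return out
    out["pearson"] = float(stats.pearsonr(x, y).statistic)
    out["spearman"] = float(stats.spearmanr(x, y).statistic)
    return out


def _continuous_assoc(log_mat: np.ndarray, covariate: np.ndarray):
    """Per-feature simple linear regression of log10 intensity on the
    covariate: slope sign and (Pearson-equivalent) p-value, vectorized."""
    n = len(covariate)
    xc = covariate - covariate.mean()
    yc = log_mat - log_mat.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(np.nan_to_num(r), -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.sign(r), p


def _binary_assoc(log_mat: np.ndarray, covariate: np.ndarray):
    """Per-feature median log10 fold change between the two groups plus a
    two-sample t-test p-value."""
    g1 = covariate == covariate.max()
    g0 = ~g1
    med_fc = np.median(log_mat[g1], axis=0) - np.median(log_mat[g0], axis=0)
    p = stats.ttest_ind(log_mat[g1], log_mat[g0], axis=0).pvalue
    return np.sign(med_fc), p


def covariate_agreement(
    matches: pd.DataFrame,
    ref: FeatureSet,
    target: FeatureSet,
    ref_covariates: pd.DataFrame,
    target_covariates: pd.DataFrame,
    binary: tuple[str, ...] = ("sex",),
    filter: str = "all",
    alpha: float = 0.05,
    stage: str = "final",
) -> dict:
    """Strategy 3 — fraction of matches whose covariate association has the
    same sign in both datasets.

    ``filter`` restricts the tally to matches whose association is
    significant in BOTH datasets: ``"all"`` (no filter), ``"nominal"``
    (p <= alpha), ``"fdr"`` (Benjamini-Hochberg at alpha) or
    ``"bonferroni"``.  Covariates constant across samples are excluded with
    a warning.
    """
    if ref.sample_intensities is None or target.sample_intensities is None:
        raise MissingDataError("covariate agreement requires sample matrices")
    if filter not in ("all", "nominal", "fdr", "bonferroni"):
        raise ValueError(f"unknown filter {filter!r}")
    sel = _stage_matches(matches, stage)
    logs = {
        "ref": np.log10(ref.sample_intensities.to_numpy()
                        [:, sel["ref_index"].to_numpy()]),
        "target": np.log10(target.sample_intensities.to_numpy()
                           [:, sel["target_index"].to_numpy()]),
    }
    covs = {"ref": ref_covariates, "target": target_covariates}
    out: dict = {}
    for cov in ref_covariates.columns:
        if cov not in target_covariates.columns:
            continue
        signs, pvals = {}, {}
        skip = False
        for side in ("ref", "target"):
            c = covs[side][cov].to_numpy(dtype=float)
            if np.ptp(c) == 0:
                logger.warning("covariate %r constant in %s samples; excluded",
                               cov, side)
                skip = True
                break
            assoc = _binary_assoc if cov in binary else _continuous_assoc
            signs[side], pvals[side] = assoc(logs[side], c)
        if skip:
            continue
        keep = np.ones(len(sel), dtype=bool)
        if filter != "all":
            for side in ("ref", "target"):
                p = np.nan_to_num(pvals[side], nan=1.0)
                if filter == "nominal":
                    keep &= p <= alpha
                elif filter == "fdr":
                    keep &= multipletests(p, alpha=alpha, method="fdr_bh")[0]
                else:
                    keep &= multipletests(p, alpha=alpha, method="bonferroni")[0]
        n = int(keep.sum())
        agree = int((signs["ref"][keep] == signs["target"][keep]).sum())
        out[cov] = {"n": n, "agreement": agree / n if n else float("nan")}
    return out


def npeaks_delta(matches: pd.DataFrame, ref: FeatureSet,
                 target: FeatureSet) -> dict:
    """Strategy 4 — npeaks(selected) − npeaks(discarded) within resolved clusters.

    For every discarded edge that conflicts with a selected edge of its
    cluster, the difference is taken on the side where the two edges involve
    different features.  Positive deltas support the greedy choice (the
    retained feature was detected in more samples).
    """
    if ref.npeaks is None or target.npeaks is None:
        raise MissingDataError("npeaks delta requires npeaks in both sets")
    if "status" not in matches.columns:
        raise ValidationError("run cluster resolution first")
    ref_deltas: list[int] = []
    tgt_deltas: list[int] = []
    multi = matches[~matches["is_unique"]]
    for _, cluster in multi.groupby("cluster_id", sort=False):
        chosen = cluster[cluster["status"].isin(("unique", "poor"))]
        dropped = cluster[cluster["status"] == "discarded_in_cluster"]
        for _, s in chosen.iterrows():
            for _, d in dropped.iterrows():
                if d["ref_index"] == s["ref_index"] and d["target_index"] != s["target_index"]:
                    tgt_deltas.append(int(target.npeaks[s["target_index"]]
                                          - target.npeaks[d["target_index"]]))
                elif d["target_index"] == s["target_index"] and d["ref_index"] != s["ref_index"]:
                    ref_deltas.append(int(ref.npeaks[s["ref_index"]]
                                          - ref.npeaks[d["ref_index"]]))
    deltas = ref_deltas + tgt_deltas

    def _frac_pos(v):
        return float(np.mean(np.asarray(v) > 0)) if v else float("nan")

    return {"ref_deltas": ref_deltas, "target_deltas": tgt_deltas,
            "fraction_positive_ref": _frac_pos(ref_deltas),
            "fraction_positive_target": _frac_pos(tgt_deltas),
            "fraction_positive": _frac_pos(deltas)}


def _correlated_neighbors(fs: FeatureSet, ranks: np.ndarray, idx: int,
                          window_min: float, corr_threshold: float) -> set[int]:
    """Indices of other features co-eluting within the RT window and
    Spearman-correlated above the threshold with feature ``idx``."""
    near = np.flatnonzero(np.abs(fs.rt - fs.rt[idx]) < window_min)
    near = near[near != idx]
    if len(near) == 0:
        return set()
    a = ranks[:, idx]
    b = ranks[:, near]
    ac = a - a.mean()
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac ** 2).sum()) * np.sqrt((bc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ac @ bc) / denom
    return set(near[np.nan_to_num(rho) > corr_threshold].tolist())


def pattern_score(
    matches: pd.DataFrame,
    ref: FeatureSet,
    target: FeatureSet,
    rt_window: float = 0.25,
    corr_threshold: float = 0.7,
    stage: str = "final",
) -> pd.DataFrame:
    """Strategy 6 — per-match patternScore of correlated-neighbor agreement.

    ``rt_window`` is in **seconds** (converted to minutes internally);
    Spearman correlations use average ranks for ties.  Returns one row per
    match of the requested stage with |R|, |T|, |common| and the score.
    """
    if ref.sample_intensities is None or target.sample_intensities is None:
        raise MissingDataError("pattern score requires sample matrices in both sets")
    sel = _stage_matches(matches, stage)
    window_min = rt_window / 60.0
    ranks_r = stats.rankdata(ref.sample_intensities.to_numpy(), axis=0)
    ranks_t = stats.rankdata(target.sample_intensities.to_numpy(), axis=0)

    sel_pairs = set(zip(sel["ref_index"].astype(int), sel["target_index"].astype(int)))
    tgt_of_ref = dict(sel_pairs)

    rows = []
    for r_idx, t_idx, r_id, t_id in zip(sel["ref_index"].astype(int),
                                        sel["target_index"].astype(int),
                                        sel["ref_id"], sel["target_id"]):
        R = _correlated_neighbors(ref, ranks_r, r_idx, window_min, corr_threshold)
        T = _correlated_neighbors(target, ranks_t, t_idx, window_min, corr_threshold)
        common = sum(1 for r2 in R if tgt_of_ref.get(r2) in T
                     and tgt_of_ref.get(r2) is not None)
        score = common / (min(len(R), len(T)) + 1)
        rows.append((r_id, t_id, len(R), len(T), common, score))
    return pd.DataFrame(rows, columns=["ref_id", "target_id", "n_R", "n_T",
                                       "n_common", "pattern_score"])


def match_summary(matches: pd.DataFrame) -> dict:
    """Strategy 5 — cluster statistics (candidates M, multi-match clusters,
    Step-1 unique, selected U, final U*)."""
    return summarize(matches)


@dataclass
class ValidationReport:
    """Container of whichever validation sections could be computed."""

    sections: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.sections[key]

    def __contains__(self, key):
        return key in self.sections


def validate_all(
    matches: pd.DataFrame,
    ref: FeatureSet,
    target: FeatureSet,
    ref_covariates: pd.DataFrame | None = None,
    target_covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    rt_window: float = 0.25,
    corr_threshold: float = 0.7,
    stage: str = "final",
) -> ValidationReport:
    """Run every validation strategy whose inputs are available; record an
    explicit notice for the ones that had to be skipped."""
    report = ValidationReport()
    report.sections["cluster_stats"] = match_summary(matches)
    runners = {
        "annotation_agreement": lambda: annotation_agreement(matches, ref, target,
                                                             stage=stage),
        "fi_correlation": lambda: fi_correlation(matches, ref, target, stage=stage),
        "npeaks_deltas": lambda: npeaks_delta(matches, ref, target),
        "pattern_scores": lambda: pattern_score(matches, ref, target,
                                                rt_window=rt_window,
                                                corr_threshold=corr_threshold,
                                                stage=stage),
    }
    if ref_covariates is not None and target_covariates is not None:
        runners["covariate_agreement"] = lambda: {
            flt: covariate_agreement(matches, ref, target, ref_covariates,
                                     target_covariates, filter=flt, alpha=alpha,
                                     stage=stage)
            for flt in ("all", "nominal", "fdr", "bonferroni")}
    else:
        report.skipped["covariate_agreement"] = "requires sample covariates"
    for name, fn in runners.items():
        try:
            report.sections[name] = fn()
        except MissingDataError as exc:
            report.skipped[name] = str(exc)
            logger.info("validation strategy %s skipped: %s", name, exc)
    return report
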