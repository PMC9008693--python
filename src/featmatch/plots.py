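"""Static diagnostic plots of the matching workflow.

The threshold choice is plot-guided, so every stage has a visual
counterpart: a six-row grid of distance-vs-reference panels (one column per
dimension) showing, from top to bottom, the raw inter-dataset distances with
the linear threshold bands, the modeled expected shifts, the residuals, the
normalized residuals with the ±1 limits, the penalization-score coloring,
and the final match statuses.  Separate figures cover the FI agreement
scatter and the patternScore views.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .candidates import ThresholdSpec
from .io import FeatureSet

_DIMLAB = {"rt": ("RT_ref (min)", "RTdist (min)"),
           "mz": ("MZ_ref (Da)", "MZdist (Da)"),
           "fi": ("log10FI_ref", "log10FIdist")}


def _ref_axis(matches: pd.DataFrame, ref: FeatureSet, dim: str) -> np.ndarray:
    idx = matches["ref_index"].to_numpy()
    return {"rt": ref.rt, "mz": ref.mz, "fi": ref.log10fi}[dim][idx]


def _dims(matches: pd.DataFrame) -> list[str]:
    dims = ["rt", "mz"]
    if "log10fidist" in matches.columns and matches["log10fidist"].notna().all():
        dims.append("fi")
    return dims


def workflow_figure(matches: pd.DataFrame, ref: FeatureSet,
                    thresholds: ThresholdSpec | None = None) -> plt.Figure:
    """Six-row diagnostic grid for a completed (or partial) matching run."""
    dims = _dims(matches)
    dist_col = {"rt": "rtdist", "mz": "mzdist", "fi": "log10fidist"}
    fig, axes = plt.subplots(6, len(dims), figsize=(4.2 * len(dims), 16),
                             squeeze=False)
    unique = matches["is_unique"].to_numpy()
    for j, d in enumerate(dims):
        x = _ref_axis(matches, ref, d)
        y = matches[dist_col[d]].to_numpy()
        xs = np.linspace(x.min(), x.max(), 100)

        ax = axes[0, j]
        ax.plot(x[unique], y[unique], "k.", ms=3, label="unique")
        ax.plot(x[~unique], y[~unique], "o", mfc="none", mec="tab:blue",
                ms=4, label="in cluster")
        band = getattr(thresholds, d, None) if thresholds else None
        if band is not None:
            lo, hi = band.bounds(xs)
            ax.plot(xs, lo, "r--", lw=1)
            ax.plot(xs, hi, "r--", lw=1)
        ax.set_title(f"Step 1: distances ({d.upper()})", fontsize=9)
        if j == 0:
            ax.legend(fontsize=7)

        ax = axes[1, j]
        ax.plot(x, y, "k.", ms=3)
        if f"{d}_expected" in matches.columns:
            ax.plot(x, matches[f"{d}_expected"], "o", mfc="none", mec="red", ms=3)
        ax.set_title("Step 2a: expected shift", fontsize=9)

        ax = axes[2, j]
        if f"{d}_residual" in matches.columns:
            ax.plot(x, matches[f"{d}_residual"], "k.", ms=3)
        ax.set_title("Step 2b: residuals", fontsize=9)

        ax = axes[3, j]
        if f"{d}_norm" in matches.columns:
            ax.plot(x, matches[f"{d}_norm"], "k.", ms=3)
            ax.axhline(1.0, color="r", ls="--", lw=1)
            ax.axhline(-1.0, color="r", ls="--", lw=1)
        ax.set_title("Step 2b: normalized residuals", fontsize=9)

        ax = axes[4, j]
        if "score" in matches.columns:
            sc = ax.scatter(x, y, c=matches["score"], s=6, cmap="viridis")
            fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_title("Step 2d: penalization scores", fontsize=9)

        ax = axes[5, j]
        if "status" in matches.columns:
            st = matches["status"]
            for label, color in (("discarded_in_cluster", "tab:blue"),
                                 ("poor", "red"), ("unique", "black")):
                m = (st == label).to_numpy()
                ax.plot(x[m], y[m], ".", color=color, ms=3, label=label)
            if j == 0:
                ax.legend(fontsize=7)
        ax.set_title("Step 3: final statuses", fontsize=9)

        for i in range(6):
            axes[i, j].set_xlabel(_DIMLAB[d][0], fontsize=8)
            axes[i, j].set_ylabel(_DIMLAB[d][1], fontsize=8)
    fig.tight_layout()
    return fig


def fi_agreement_figure(fi_corr: dict) -> plt.Figure:
    """Scatter of matched log10FI values with the correlation in the title."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fi_corr["ref_log10fi"], fi_corr["target_log10fi"], "k.", ms=3)
    lims = [min(ax.get_xlim()[0], ax.get_ylim()[0]),
            max(ax.get_xlim()[1], ax.get_ylim()[1])]
    ax.plot(lims, lims, "r--", lw=1)
    ax.set_xlabel("log10FI reference")
    ax.set_ylabel("log10FI target")
    ax.set_title(f"FI agreement (n={fi_corr['n']}, "
                 f"Spearman={fi_corr.get('spearman', float('nan')):.3f})")
    fig.tight_layout()
    return fig


def pattern_score_figure(scores: pd.DataFrame,
                         matches: pd.DataFrame | None = None) -> plt.Figure:
    """patternScore views: score vs penalization score (when available),
    |T| vs |R|, and common vs min(|R|,|T|)."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    if matches is not None and "score" in matches.columns:
        merged = scores.merge(matches[["ref_id", "target_id", "score"]],
                              on=["ref_id", "target_id"], how="left")
        axes[0].scatter(merged["score"], merged["n_common"],
                        c=merged["pattern_score"], s=8, cmap="viridis")
        axes[0].set_xlabel("penalization score")
        axes[0].set_ylabel("|common|")
    minRT = np.minimum(scores["n_R"], scores["n_T"])
    axes[1].scatter(scores["n_R"], scores["n_T"], c=scores["pattern_score"],
                    s=8, cmap="viridis")
    axes[1].set_xlabel("|R|")
    axes[1].set_ylabel("|T|")
    axes[2].scatter(minRT, scores["n_common"], c=scores["pattern_score"],
                    s=8, cmap="viridis")
    axes[2].set_xlabel("min(|R|, |T|)")
    axes[2].set_ylabel("|common|")
    for ax in axes:
        ax.set_title("patternScore", fontsize=9)
    fig.tight_layout()
    return fig
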