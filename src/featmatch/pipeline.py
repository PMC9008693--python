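"""High-level matching pipeline: Steps 1 → 2 → 3 in one call.

``match_pair`` composes candidate matching, shift modeling, residual
normalization, scoring, cluster resolution and (optionally) poor-match
filtering, and returns a :class:`MatchResult` carrying the full per-match
table plus the summary counts used throughout: M candidates, multi-match
clusters, Step-1 unique matches, U selected unique matches and U* survivors
of the poor-match filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .candidates import ThresholdSpec, find_candidates
from .filtering import PoorMatchConfig, flag_poor_matches
from .io import FeatureSet, matches_to_output
from .scoring import WeightVector, penalization_scores, resolve_clusters
from .shift import ShiftModel, compute_residuals, fit_shift, normalize_residuals


@dataclass
class MatchResult:
    """Everything produced by a matching run."""

    matches: pd.DataFrame
    shift_model: ShiftModel
    thresholds: ThresholdSpec
    summary: dict = field(default_factory=dict)

    @property
    def selected(self) -> pd.DataFrame:
        """Matches selected by cluster resolution (unique + poor)."""
        return self.matches[self.matches["status"].isin(("unique", "poor"))]

    @property
    def final(self) -> pd.DataFrame:
        """Matches surviving the whole workflow (status 'unique')."""
        return self.matches[self.matches["status"] == "unique"]

    def to_output(self) -> pd.DataFrame:
        """Public matched-pairs table (see :func:`featmatch.io.write_matches`)."""
        return matches_to_output(self.matches)


def summarize(matches: pd.DataFrame) -> dict:
    """Accounting of a match table: every candidate is selected or discarded,
    and every selected match is either final or poor."""
    status = matches["status"] if "status" in matches.columns else pd.Series(dtype=str)
    m = len(matches)
    step1_unique = int(matches["is_unique"].sum()) if m else 0
    n_clusters_multi = int(matches.loc[~matches["is_unique"], "cluster_id"].nunique()) if m else 0
    discarded = int((status == "discarded_in_cluster").sum())
    poor = int((status == "poor").sum())
    final = int((status == "unique").sum())
    return {
        "candidates": m,
        "step1_unique": step1_unique,
        "multi_match_clusters": n_clusters_multi,
        "selected_unique": final + poor,     # U
        "poor": poor,
        "final_unique": final,               # U*
        "discarded_in_cluster": discarded,
        "unique_to_cluster_ratio": (step1_unique / n_clusters_multi
                                    if n_clusters_multi else float("inf")),
    }


def match_pair(
    ref: FeatureSet,
    target: FeatureSet,
    thresholds: ThresholdSpec,
    neighbor_method: str = "cross",
    k: int | None = None,
    F: float = 3.0,
    weights: WeightVector | tuple[float, float, float] = (1.0, 1.0, 1.0),
    centered: bool = True,
    poor: PoorMatchConfig | None = None,
    max_candidates_factor: float = 50.0,
) -> MatchResult:
    """Run the full matching workflow between a reference and a target set.

    Parameters mirror the individual steps; ``poor=None`` (the library
    default) skips Step 3, ``poor=PoorMatchConfig()`` applies the "scores"
    method at median + 3 x MAD.
    """
    matches = find_candidates(ref, target, thresholds,
                              max_candidates_factor=max_candidates_factor)
    model = fit_shift(matches, ref, method=neighbor_method, k=k)
    matches = compute_residuals(matches, model)
    matches = normalize_residuals(matches, F=F, centered=centered)
    matches = penalization_scores(matches, weights)
    matches = resolve_clusters(matches)
    if poor is not None:
        matches = flag_poor_matches(matches, poor)
    result = MatchResult(matches=matches, shift_model=model, thresholds=thresholds)
    result.summary = summarize(matches)
    assert result.summary["candidates"] == (result.summary["selected_unique"]
                                            + result.summary["discarded_in_cluster"])
    return result
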