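"""Step 1 — candidate matching inside linear threshold bands.

A candidate match is a (reference, target) feature pair whose inter-dataset
distances ``dist_d = value_target − value_reference`` fall inside a per-
dimension band.  Each band is linear in the *reference* feature's value::

    lower_intercept + lower_slope * v_ref  <=  dist_d  <=  upper_intercept + upper_slope * v_ref

so absolute tolerances (horizontal lines in a distance-vs-reference plot) and
relative ones (diagonal lines, e.g. ppm bands in MZ) — possibly noncentered
and asymmetric — are both expressible.  Inequalities are non-strict.

Candidate matches form a bipartite graph (features = nodes, matches = edges);
its connected components are the *clusters* whose multi-edge members are
resolved later by penalization score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, ValidationError
from .io import FeatureSet

logger = logging.getLogger(__name__)

DIMS = ("rt", "mz", "fi")


@dataclass(frozen=True)
class Band:
    """One dimension's asymmetric linear threshold band on the distance."""

    lower_intercept: float
    upper_intercept: float
    lower_slope: float = 0.0
    upper_slope: float = 0.0

    def bounds(self, v_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = self.lower_intercept + self.lower_slope * v_ref
        hi = self.upper_intercept + self.upper_slope * v_ref
        return lo, hi

    def validate(self, v_min: float, v_max: float) -> None:
        # linear bounds: checking the endpoints of the observed range suffices
        for v in (v_min, v_max):
            lo, hi = self.bounds(np.asarray(v, dtype=float))
            if lo > hi:
                raise ConfigError(
                    f"threshold band inverted at reference value {v}: "
                    f"lower {lo} > upper {hi}")

    @classmethod
    def absolute(cls, half_width: float) -> "Band":
        """Symmetric absolute band ±half_width."""
        return cls(-abs(half_width), abs(half_width))

    @classmethod
    def ppm(cls, ppm: float) -> "Band":
        """Symmetric relative band ±ppm parts-per-million of the reference value."""
        s = abs(ppm) * 1e-6
        return cls(0.0, 0.0, -s, s)


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-dimension candidate-matching bands; FI participates only if enabled."""

    rt: Band
    mz: Band
    fi: Band | None = None
    fi_enabled: bool = field(default=True)

    def __post_init__(self):
        if self.fi_enabled and self.fi is None:
            object.__setattr__(self, "fi_enabled", False)

    @classmethod
    def symmetric(cls, rt: float, mz: float, fi: float | None = None) -> "ThresholdSpec":
        """Symmetric absolute half-widths per dimension (minutes, Daltons, log10 units)."""
        return cls(rt=Band.absolute(rt), mz=Band.absolute(mz),
                   fi=Band.absolute(fi) if fi is not None else None,
                   fi_enabled=fi is not None)


#: Wide exploratory bands for a first overview plot of the inter-dataset
#: shifts (RT ±1 min, MZ ±0.025 Da); intended for plotting, not for a final run.
OVERVIEW_THRESHOLDS = ThresholdSpec.symmetric(rt=1.0, mz=0.025)

#: Internal match-table columns created by this module.
BASE_COLUMNS = ("ref_index", "target_index", "ref_id", "target_id",
                "rtdist", "mzdist", "log10fidist", "cluster_id", "is_unique")


def find_candidates(
    ref: FeatureSet,
    target: FeatureSet,
    thresholds: ThresholdSpec,
    max_candidates_factor: float = 50.0,
) -> pd.DataFrame:
    """Find all reference-target pairs inside the threshold bands (Step 1).

    Returns the match table with one row per candidate pair, distances
    ``rtdist``, ``mzdist`` and (when FI is available) ``log10fidist`` computed
    as target − reference, and cluster labels (see :func:`label_clusters`).

    The search sorts the target set on MZ and scans a window per reference
    feature, which is equivalent to the brute-force double loop over all
    pairs.  If the number of candidates would exceed
    ``max_candidates_factor x min(len(ref), len(target))`` the run aborts
    with guidance to tighten the thresholds.
    """
    if len(ref) == 0 or len(target) == 0:
        raise ValidationError("both feature sets must be nonempty")
    if thresholds.fi_enabled and (not ref.has_fi or not target.has_fi):
        raise ConfigError("fi_enabled thresholds require FI in both feature sets")
    thresholds.rt.validate(ref.rt.min(), ref.rt.max())
    thresholds.mz.validate(ref.mz.min(), ref.mz.max())
    if thresholds.fi_enabled:
        thresholds.fi.validate(ref.log10fi.min(), ref.log10fi.max())

    cap = max_candidates_factor * min(len(ref), len(target))

    order = np.argsort(target.mz, kind="stable")
    tmz = target.mz[order]
    lo, hi = thresholds.mz.bounds(ref.mz)
    left = np.searchsorted(tmz, ref.mz + lo, side="left")
    right = np.searchsorted(tmz, ref.mz + hi, side="right")
    counts = right - left
    total = int(counts.sum())
    if total > cap:
        raise ConfigError(
            f"MZ window admits {total} pairs (> cap {int(cap)}); "
            "tighten the thresholds or raise max_candidates_factor")

    ref_idx = np.repeat(np.arange(len(ref)), counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    tgt_idx = order[np.repeat(left, counts) + offs]

    rtdist = target.rt[tgt_idx] - ref.rt[ref_idx]
    rlo, rhi = thresholds.rt.bounds(ref.rt[ref_idx])
    keep = (rtdist >= rlo) & (rtdist <= rhi)

    have_fi = ref.has_fi and target.has_fi
    if have_fi:
        fidist_all = target.log10fi[tgt_idx] - ref.log10fi[ref_idx]
        if thresholds.fi_enabled:
            flo, fhi = thresholds.fi.bounds(ref.log10fi[ref_idx])
            keep &= (fidist_all >= flo) & (fidist_all <= fhi)

    ref_idx, tgt_idx = ref_idx[keep], tgt_idx[keep]
    if len(ref_idx) > cap:
        raise ConfigError(
            f"{len(ref_idx)} candidate matches exceed the cap of {int(cap)} "
            f"({max_candidates_factor}x the smaller set); tighten the thresholds")

    matches = pd.DataFrame({
        "ref_index": ref_idx,
        "target_index": tgt_idx,
        "ref_id": ref.feature_id[ref_idx],
        "target_id": target.feature_id[tgt_idx],
        "rtdist": target.rt[tgt_idx] - ref.rt[ref_idx],
        "mzdist": target.mz[tgt_idx] - ref.mz[ref_idx],
        "log10fidist": fidist_all[keep] if have_fi else np.nan,
    })
    matches = label_clusters(matches)
    logger.info("found %d candidate matches (%d unique, %d multi-match clusters)",
                len(matches), int(matches["is_unique"].sum()),
                int(matches.loc[~matches["is_unique"], "cluster_id"].nunique()))
    return matches


def label_clusters(matches: pd.DataFrame) -> pd.DataFrame:
    """Label connected components of the bipartite match graph.

    Adds/overwrites ``cluster_id`` (0-based component label, deterministic in
    row order) and ``is_unique`` (the match's two features each appear in
    exactly one candidate match, i.e. its cluster has a single edge).
    """
    matches = matches.copy()
    if len(matches) == 0:
        matches["cluster_id"] = np.array([], dtype=int)
        matches["is_unique"] = np.array([], dtype=bool)
        return matches
    r = matches["ref_index"].to_numpy()
    t = matches["target_index"].to_numpy()
    ruq, rinv = np.unique(r, return_inverse=True)
    tuq, tinv = np.unique(t, return_inverse=True)
    n_nodes = len(ruq) + len(tuq)
    graph = coo_matrix(
        (np.ones(len(matches)), (rinv, tinv + len(ruq))), shape=(n_nodes, n_nodes))
    _, node_label = connected_components(graph, directed=False)
    edge_label = node_label[rinv]
    # relabel components consecutively in order of first appearance
    _, first = np.unique(edge_label, return_index=True)
    remap = {edge_label[i]: rank for rank, i in enumerate(np.sort(first))}
    matches["cluster_id"] = np.array([remap[c] for c in edge_label], dtype=int)
    ref_deg = np.bincount(rinv)[rinv]
    tgt_deg = np.bincount(tinv)[tinv]
    matches["is_unique"] = (ref_deg == 1) & (tgt_deg == 1)
    return matches
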