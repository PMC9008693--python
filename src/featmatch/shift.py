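"""Step 2a-2b — neighbor-consensus inter-dataset shift model and residuals.

The systematic inter-dataset shift in each dimension (RT drift, MZ
calibration offset, FI gain) is generally nonlinear in the reference value,
so it is estimated *locally*: the expected shift of a candidate match is the
median inter-dataset distance of its k nearest neighbor matches.  Only
matches that are unique after Step 1 serve as neighbors, which makes the
consensus robust to the conflicting edges inside multi-match clusters.

Two neighbor definitions are provided:

``cross``
    k neighbors ranked per dimension by the reference-value difference in
    that dimension alone (RT for the RT model, MZ for MZ, log10FI for FI).
    The result is a smoothed curve: matches at the same reference abscissa
    receive the same expected shift.
``circle``
    one shared neighbor set per match, ranked by Euclidean distance in the
    (RT_ref, MZ_ref) plane after scaling each axis to unit MAD.  Matches at
    the same RT but different MZ may then receive different shifts.

Residuals (observed distance − expected shift) are made unit-free by a
robust normalization: in each dimension the scale is F x MAD of the
residuals (F = 3 by default), so a normalized residual of magnitude 1 sits
exactly at the median ± F·MAD threshold.  MAD is the raw median absolute
deviation, without the Gaussian 1.4826 consistency factor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import FeatureSet

logger = logging.getLogger(__name__)

_DIST_COLS = {"rt": "rtdist", "mz": "mzdist", "fi": "log10fidist"}
_EXP_COLS = {"rt": "rt_expected", "mz": "mz_expected", "fi": "fi_expected"}
_RES_COLS = {"rt": "rt_residual", "mz": "mz_residual", "fi": "fi_residual"}
_NORM_COLS = {"rt": "rt_norm", "mz": "mz_norm", "fi": "fi_norm"}

_CHUNK = 512  # rows per block when forming neighbor-distance matrices


def mad(x: np.ndarray) -> float:
    """Raw median absolute deviation (no consistency factor)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def default_k(n_ref_features: int, fraction: float = 0.01, floor: int = 5) -> int:
    """Default neighbor count: ``ceil(fraction x reference set size)``, min ``floor``."""
    return max(floor, math.ceil(fraction * n_ref_features))


@dataclass
class ShiftModel:
    """Per-match expected inter-dataset shifts from neighbor consensus."""

    method: str
    k: int
    rt_expected: np.ndarray
    mz_expected: np.ndarray
    fi_expected: np.ndarray | None = None

    @property
    def dims(self) -> tuple[str, ...]:
        return ("rt", "mz", "fi") if self.fi_expected is not None else ("rt", "mz")

    def expected(self, dim: str) -> np.ndarray:
        return getattr(self, _EXP_COLS[dim])


def _knn_median(queries: np.ndarray, anchors: np.ndarray, values: np.ndarray,
                k: int) -> np.ndarray:
    """Median of ``values`` over the k nearest anchors per query (ties at
    rank k all included), with a scalar query distance |query − anchor|."""
    out = np.empty(len(queries))
    for s in range(0, len(queries), _CHUNK):
        q = queries[s:s + _CHUNK, None]
        d = np.abs(q - anchors[None, :])
        out[s:s + _CHUNK] = _masked_median_at_k(d, values, k)
    return out


def _masked_median_at_k(d: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    """Per row of distance matrix ``d``: median of ``values`` over the k
    smallest entries, including all ties at the k-th distance."""
    kth = np.partition(d, k - 1, axis=1)[:, k - 1]
    masked = np.where(d <= kth[:, None], values[None, :], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(masked, axis=1)


def fit_shift(
    matches: pd.DataFrame,
    ref: FeatureSet,
    method: str = "cross",
    k: int | None = None,
) -> ShiftModel:
    """Fit the expected inter-dataset shift for every candidate match (Step 2a).

    Neighbors are drawn from the Step-1 unique matches only.  ``k`` defaults
    to 1% of the reference set size (min 5) and is reduced with a warning if
    fewer eligible neighbors exist.  A unique match may be its own neighbor
    (the median makes self-inclusion innocuous).
    """
    if method not in ("cross", "circle"):
        raise ValueError(f"unknown neighbor method {method!r}")
    if len(matches) == 0:
        raise ValidationError("no candidate matches to model")
    eligible = matches["is_unique"].to_numpy()
    n_elig = int(eligible.sum())
    if n_elig == 0:
        raise ValidationError(
            "no unique matches available as shift-model neighbors; "
            "widen the thresholds")
    if k is None:
        k = default_k(len(ref))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_elig:
        logger.warning("k=%d exceeds the %d eligible neighbors; using k=%d",
                       k, n_elig, n_elig)
        k = n_elig

    ridx = matches["ref_index"].to_numpy()
    e_ridx = ridx[eligible]
    has_fi = ref.has_fi and matches["log10fidist"].notna().all()

    dvals = {d: matches[_DIST_COLS[d]].to_numpy()[eligible]
             for d in (("rt", "mz", "fi") if has_fi else ("rt", "mz"))}
    expected: dict[str, np.ndarray] = {}

    if method == "cross":
        absc = {"rt": ref.rt, "mz": ref.mz}
        if has_fi:
            absc["fi"] = ref.log10fi
        for d, a in absc.items():
            expected[d] = _knn_median(a[ridx], a[e_ridx], dvals[d], k)
    else:  # circle: one shared neighbor set in the scaled (RT_ref, MZ_ref) plane
        scales = {}
        for d, a in (("rt", ref.rt), ("mz", ref.mz)):
            s = mad(a[e_ridx])
            if s == 0:
                logger.warning("MAD of %s_ref over eligible neighbors is 0; "
                               "axis left unscaled", d)
                s = 1.0
            scales[d] = s
        q_rt, q_mz = ref.rt[ridx] / scales["rt"], ref.mz[ridx] / scales["mz"]
        a_rt, a_mz = ref.rt[e_ridx] / scales["rt"], ref.mz[e_ridx] / scales["mz"]
        for d in dvals:
            expected[d] = np.empty(len(matches))
        for s in range(0, len(matches), _CHUNK):
            d2 = ((q_rt[s:s + _CHUNK, None] - a_rt[None, :]) ** 2
                  + (q_mz[s:s + _CHUNK, None] - a_mz[None, :]) ** 2)
            for d, vals in dvals.items():
                expected[d][s:s + _CHUNK] = _masked_median_at_k(d2, vals, k)

    for d, e in expected.items():
        if not np.all(np.isfinite(e)):
            raise ValidationError(f"non-finite expected shift in dimension {d}")
    return ShiftModel(method=method, k=k,
                      rt_expected=expected["rt"], mz_expected=expected["mz"],
                      fi_expected=expected.get("fi"))


def compute_residuals(matches: pd.DataFrame, model: ShiftModel) -> pd.DataFrame:
    """Residual = observed inter-dataset distance − expected shift, per dimension."""
    if len(matches) != len(model.rt_expected):
        raise ValidationError("shift model does not cover all matches")
    matches = matches.copy()
    for d in model.dims:
        matches[_EXP_COLS[d]] = model.expected(d)
        matches[_RES_COLS[d]] = matches[_DIST_COLS[d]].to_numpy() - model.expected(d)
    return matches


def normalize_residuals(
    matches: pd.DataFrame,
    F: float = 3.0,
    centered: bool = True,
) -> pd.DataFrame:
    """Normalize residuals so magnitude 1 falls at the robust threshold (Step 2b).

    Default (centered) convention: ``(residual − median) / (F x MAD)``; the
    ``centered=False`` variant divides raw residuals by ``median + F x MAD``.
    Degenerate scales: if all residuals in a dimension are identical the
    normalized values are set to 0; if MAD is 0 but residuals differ (more
    than half sit exactly at the median) the mean absolute deviation about
    the median is used as the spread instead.  Both emit a warning.
    """
    if F <= 0:
        raise ValueError("F must be positive")
    if len(matches) < 2:
        raise ValidationError("need at least 2 matches to normalize residuals")
    matches = matches.copy()
    for d in ("rt", "mz", "fi"):
        col = _RES_COLS[d]
        if col not in matches.columns:
            continue
        x = matches[col].to_numpy(dtype=float)
        med = float(np.median(x))
        scale = mad(x)
        if scale == 0.0:
            if np.all(x == med):
                logger.warning("all %s residuals identical; normalized set to 0", d)
                matches[_NORM_COLS[d]] = 0.0
                matches.attrs[f"{d}_norm_threshold"] = med
                continue
            scale = float(np.mean(np.abs(x - med)))
            logger.warning("MAD of %s residuals is 0 with unequal residuals; "
                           "falling back to mean absolute deviation %.3g", d, scale)
        if centered:
            matches[_NORM_COLS[d]] = (x - med) / (F * scale)
        else:
            denom = med + F * scale
            if denom == 0:
                raise ValidationError(
                    f"uncentered normalization undefined: median + F*MAD = 0 in {d}")
            matches[_NORM_COLS[d]] = x / denom
        # residual value at which |normalized| = 1 (upper side)
        matches.attrs[f"{d}_norm_threshold"] = med + F * scale
    return matches
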