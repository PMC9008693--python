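"""Step 3 — optional poor-match detection by tightened robust thresholds.

A *poor match* is unique but sits far from the modeled inter-dataset shift —
typically an accidental pairing admitted by generous initial thresholds.
Because the shift trend is nonlinear while the Step-1 bands are linear, the
tightened limits are expressed on score/residual scale rather than as new
lines: a selected match is flagged when its penalization score (method
``"scores"``) or any per-dimension residual (method ``"residuals"``) exceeds
``median + F x MAD`` computed over the selected matches.  Flagging never
changes which matches were selected, only their status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .shift import mad

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PoorMatchConfig:
    method: str = "scores"
    F_tighten: float = 3.0

    def __post_init__(self):
        if self.method not in ("scores", "residuals"):
            raise ValidationError(f"unknown poor-match method {self.method!r}")
        if self.F_tighten <= 0:
            raise ValidationError("F_tighten must be positive")


def _exceeds(values: np.ndarray, F: float) -> np.ndarray:
    """True where a value exceeds median + F*MAD; with MAD = 0 the rule
    degenerates to 'strictly above the median'."""
    med = float(np.median(values))
    scale = mad(values)
    if scale == 0.0:
        return values > med
    return values > med + F * scale


def flag_poor_matches(
    matches: pd.DataFrame,
    config: PoorMatchConfig = PoorMatchConfig(),
) -> pd.DataFrame:
    """Flag selected matches far from the inter-dataset shift (Step 3).

    Requires cluster resolution to have run.  With fewer than 3 selected
    matches the robust statistics are meaningless and filtering is skipped
    with a warning.  Flagged matches get ``status = "poor"``; the survivors'
    count is the final U*.
    """
    if "status" not in matches.columns:
        raise ValidationError("run resolve_clusters before poor-match filtering")
    matches = matches.copy()
    sel = matches["status"].isin(("unique", "poor")).to_numpy()
    matches.loc[sel, "status"] = "unique"  # idempotent re-application
    if int(sel.sum()) < 3:
        logger.warning("fewer than 3 selected matches; poor-match filtering skipped")
        return matches

    if config.method == "scores":
        poor_sel = _exceeds(matches.loc[sel, "score"].to_numpy(), config.F_tighten)
    else:
        res_cols = [c for c in ("rt_residual", "mz_residual", "fi_residual")
                    if c in matches.columns]
        if not res_cols:
            raise ValidationError("residuals missing for poor-match method 'residuals'")
        poor_sel = np.zeros(int(sel.sum()), dtype=bool)
        for col in res_cols:
            x = matches.loc[sel, col].to_numpy()
            poor_sel |= _abs_dev_exceeds(x, config.F_tighten)

    idx = matches.index[sel][poor_sel]
    matches.loc[idx, "status"] = "poor"
    logger.info("poor-match filtering (%s, F=%g): flagged %d of %d selected",
                config.method, config.F_tighten, int(poor_sel.sum()), int(sel.sum()))
    return matches


def _abs_dev_exceeds(x: np.ndarray, F: float) -> np.ndarray:
    """|x − median(x)| > F*MAD(x) (strictly above 0 when MAD = 0)."""
    med = float(np.median(x))
    scale = mad(x)
    dev = np.abs(x - med)
    if scale == 0.0:
        return dev > 0
    return dev > F * scale
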