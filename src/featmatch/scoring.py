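"""Steps 2c-2e — penalization scores and recursive cluster resolution.

Each candidate match gets a single penalization score

    score = sqrt( W_RT * nRT^2 + W_MZ * nMZ^2 + W_FI * nFI^2 )

where ``n*`` are the normalized residuals and ``W`` nonnegative per-dimension
weights (default [1, 1, 1]; the worked real-data configuration [1, 1, 0.2]
down-weights FI, and W_FI = 0 removes it entirely).  Low score = close to the
modeled inter-dataset shift.

Multi-match clusters are resolved recursively: select the remaining edge with
the minimal score, discard every remaining edge sharing a feature with it,
repeat until the cluster is empty.  This is the published greedy-by-score
rule, deliberately not an optimal bipartite assignment.  Equal scores are
broken by smaller |normalized RT residual|, then |normalized MZ residual|,
then lexicographically smallest (ref_id, target_id), making the selection
independent of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

#: Worked configuration used for the paper-style real-data preset, where FI
#: should only influence the score when its difference is very large.
FI_DOWNWEIGHTED = (1.0, 1.0, 0.2)


@dataclass(frozen=True)
class WeightVector:
    """Per-dimension nonnegative residual weights (RT, MZ, FI)."""

    rt: float = 1.0
    mz: float = 1.0
    fi: float = 1.0

    def __post_init__(self):
        if min(self.rt, self.mz, self.fi) < 0:
            raise ConfigError("weights must be nonnegative")
        if max(self.rt, self.mz, self.fi) == 0:
            raise ConfigError("at least one weight must be strictly positive")


def penalization_scores(
    matches: pd.DataFrame,
    weights: WeightVector | tuple[float, float, float] = WeightVector(),
) -> pd.DataFrame:
    """Attach the penalization score (Step 2d) to every candidate match.

    Dimensions with weight 0 contribute nothing; a positive FI weight with no
    FI residuals available is forced to 0 with a warning.
    """
    if not isinstance(weights, WeightVector):
        weights = WeightVector(*weights)
    matches = matches.copy()
    w = {"rt": weights.rt, "mz": weights.mz, "fi": weights.fi}
    if w["fi"] > 0 and "fi_norm" not in matches.columns:
        logger.warning("FI residuals unavailable; forcing W_FI = 0")
        w["fi"] = 0.0
        if w["rt"] == 0 and w["mz"] == 0:
            raise ConfigError("no usable dimension left with positive weight")
    total = np.zeros(len(matches))
    for d, wd in w.items():
        if wd > 0:
            col = f"{d}_norm"
            if col not in matches.columns:
                raise ValidationError(f"normalized residuals missing for {d}")
            total += wd * matches[col].to_numpy() ** 2
    matches["score"] = np.sqrt(total)
    return matches


def _tie_key(row: pd.Series) -> tuple:
    return (row["score"],
            abs(row.get("rt_norm", 0.0)),
            abs(row.get("mz_norm", 0.0)),
            str(row["ref_id"]), str(row["target_id"]))


def resolve_clusters(matches: pd.DataFrame) -> pd.DataFrame:
    """Resolve every multi-match cluster into unique matches (Step 2e).

    Adds ``selected`` (bool) and ``status`` ("unique" or
    "discarded_in_cluster").  Step-1 unique matches pass through selected;
    within each multi-edge cluster the greedy minimum-score recursion runs to
    exhaustion.  The selected edges globally form a matching: no feature
    appears in more than one selected edge.
    """
    if "score" not in matches.columns:
        raise ValidationError("scores missing; run penalization_scores first")
    matches = matches.copy()
    n = len(matches)
    selected = np.zeros(n, dtype=bool)
    selected[matches["is_unique"].to_numpy()] = True

    multi = matches.loc[~matches["is_unique"]]
    for _, cluster in multi.groupby("cluster_id", sort=False):
        order = sorted(cluster.index, key=lambda i: _tie_key(matches.loc[i]))
        taken_ref: set = set()
        taken_tgt: set = set()
        for i in order:
            r, t = matches.at[i, "ref_index"], matches.at[i, "target_index"]
            if r in taken_ref or t in taken_tgt:
                continue
            selected[matches.index.get_loc(i)] = True
            taken_ref.add(r)
            taken_tgt.add(t)

    matches["selected"] = selected
    matches["status"] = np.where(selected, "unique", "discarded_in_cluster")
    logger.info("cluster resolution: %d unique matches (%d discarded in clusters)",
                int(selected.sum()), int((~selected).sum()))
    return matches
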