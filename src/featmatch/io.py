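"""Feature-table I/O and the core :class:`FeatureSet` container.

A *feature* is a detected LC-MS peak summarized across all samples of one
dataset by its median retention time (RT, minutes), mass-to-charge ratio
(MZ, Daltons) and feature intensity (FI, raw units; stored also as
``log10fi``).  Two such sets — *reference* and *target* — are the inputs to
the matching workflow; all distances and plots are expressed relative to the
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

#: Final per-match labels written by :func:`write_matches`.
MATCH_STATUSES = ("unique", "discarded_in_cluster", "poor", "outside_thresholds")

#: Columns of the matched-pairs output table, in order.
MATCH_COLUMNS = (
    "ref_feature_id",
    "target_feature_id",
    "rtdist",
    "mzdist",
    "log10fidist",
    "penalization_score",
    "status",
)


@dataclass
class FeatureSet:
    """One dataset's features with RT / MZ / log10FI and optional metadata.

    Parameters
    ----------
    feature_id
        Unique string label per feature.
    rt
        Median retention time in minutes, strictly positive.
    mz
        Median mass-to-charge ratio in Daltons, strictly positive.
    fi
        Median raw feature intensity, strictly positive, or ``None`` when the
        dataset carries no usable intensity (FI-dependent steps then require
        ``fi_enabled=False`` / weight 0).
    npeaks
        Optional per-feature count of samples in which the peak was detected
        (a quality proxy emitted by peak pickers such as XCMS).
    annotation
        Optional metabolite annotation per feature; empty string = unannotated.
    sample_intensities
        Optional samples x features intensity matrix (raw scale), columns
        aligned to ``feature_id`` order.
    """

    feature_id: np.ndarray
    rt: np.ndarray
    mz: np.ndarray
    fi: np.ndarray | None = None
    npeaks: np.ndarray | None = None
    annotation: np.ndarray | None = None
    sample_intensities: pd.DataFrame | None = None
    log10fi: np.ndarray = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.feature_id = np.asarray(self.feature_id, dtype=object)
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        n = len(self.feature_id)
        if len(self.rt) != n or len(self.mz) != n:
            raise ValidationError("feature_id, rt and mz must have equal length")
        ids, counts = np.unique(self.feature_id, return_counts=True)
        if (counts > 1).any():
            dupes = ids[counts > 1].tolist()
            raise ValidationError(f"duplicate feature_id values: {dupes}")
        for name in ("rt", "mz"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v) & (v > 0)):
                raise ValidationError(f"{name} must be strictly positive and finite")
        if self.fi is not None:
            self.fi = np.asarray(self.fi, dtype=float)
            if len(self.fi) != n:
                raise ValidationError("fi length mismatch")
            if not np.all(np.isfinite(self.fi) & (self.fi > 0)):
                raise ValidationError("fi must be strictly positive and finite")
            self.log10fi = np.log10(self.fi)
        else:
            self.log10fi = None
        if self.npeaks is not None:
            self.npeaks = np.asarray(self.npeaks, dtype=int)
            if len(self.npeaks) != n:
                raise ValidationError("npeaks length mismatch")
            if (self.npeaks < 0).any():
                raise ValidationError("npeaks must be nonnegative")
        if self.annotation is not None:
            self.annotation = np.asarray(
                ["" if a is None or (isinstance(a, float) and np.isnan(a)) else str(a)
                 for a in self.annotation], dtype=object)
            if len(self.annotation) != n:
                raise ValidationError("annotation length mismatch")
        if self.sample_intensities is not None:
            if self.sample_intensities.shape[1] != n:
                raise ValidationError(
                    "sample_intensities column count "
                    f"({self.sample_intensities.shape[1]}) != feature count ({n})")
            self.sample_intensities = self.sample_intensities.copy()
            self.sample_intensities.columns = pd.Index(self.feature_id)

    def __len__(self) -> int:
        return len(self.feature_id)

    @property
    def has_fi(self) -> bool:
        return self.fi is not None

    def to_dataframe(self) -> pd.DataFrame:
        """Flat per-feature table (without the sample matrix)."""
        df = pd.DataFrame({"feature_id": self.feature_id, "rt": self.rt, "mz": self.mz})
        if self.fi is not None:
            df["fi"] = self.fi
        if self.npeaks is not None:
            df["npeaks"] = self.npeaks
        if self.annotation is not None:
            df["annotation"] = self.annotation
        return df


DEFAULT_COLUMN_MAP = {"feature_id": "feature_id", "rt": "rt", "mz": "mz", "fi": "fi"}


def _infer_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_featureset(
    path: str,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
    sample_intensities: str | None = None,
) -> FeatureSet:
    """Read a delimited feature table into a validated :class:`FeatureSet`.

    ``column_map`` maps canonical field names (``feature_id``, ``rt``, ``mz``,
    ``fi``, optionally ``npeaks`` and ``annotation``) to the file's column
    names.  Omitting ``fi`` from the map loads a set without intensities.
    Rows whose rt/mz/fi are missing or nonpositive are dropped with a logged
    count.  ``sample_intensities`` optionally names a second delimited file
    (samples x features, header row = feature ids).
    """
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    table = pd.read_csv(path, sep=sep)
    if column_map is None:
        cmap = {k: v for k, v in DEFAULT_COLUMN_MAP.items()
                if v in table.columns or k in ("feature_id", "rt", "mz")}
        for optional in ("npeaks", "annotation"):
            if optional in table.columns:
                cmap[optional] = optional
    else:
        cmap = dict(column_map)
    for field_name in ("feature_id", "rt", "mz"):
        if field_name not in cmap:
            raise ConfigError(f"column_map must map '{field_name}'")
    for field_name, col in cmap.items():
        if col not in table.columns:
            raise ConfigError(f"column '{col}' (mapped from '{field_name}') "
                              f"not found in {path}")
    numeric = ["rt", "mz"] + (["fi"] if "fi" in cmap else [])
    vals = {f: pd.to_numeric(table[cmap[f]], errors="coerce") for f in numeric}
    ok = np.ones(len(table), dtype=bool)
    for f in numeric:
        ok &= np.isfinite(vals[f].to_numpy()) & (vals[f].to_numpy() > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: rejected %d rows with missing/nonpositive rt, mz or fi",
                       path, n_bad)
    table = table.loc[ok]

    matrix = None
    if sample_intensities is not None:
        msep = _infer_delimiter(sample_intensities)
        matrix = pd.read_csv(sample_intensities, sep=msep, index_col=0)
        matrix = matrix[[str(i) for i in table[cmap["feature_id"]]]]

    return FeatureSet(
        feature_id=table[cmap["feature_id"]].astype(str).to_numpy(dtype=object),
        rt=table[cmap["rt"]].to_numpy(dtype=float),
        mz=table[cmap["mz"]].to_numpy(dtype=float),
        fi=table[cmap["fi"]].to_numpy(dtype=float) if "fi" in cmap else None,
        npeaks=table[cmap["npeaks"]].to_numpy() if "npeaks" in cmap else None,
        annotation=table[cmap["annotation"]].to_numpy() if "annotation" in cmap else None,
        sample_intensities=matrix,
    )


def write_featureset(fs: FeatureSet, path: str, delimiter: str = ",") -> None:
    """Write a feature set back to a delimited table (without the matrix)."""
    fs.to_dataframe().to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def matches_to_output(matches: pd.DataFrame) -> pd.DataFrame:
    """Project an internal match table onto the public matched-pairs schema."""
    out = pd.DataFrame({
        "ref_feature_id": matches["ref_id"],
        "target_feature_id": matches["target_id"],
        "rtdist": matches["rtdist"],
        "mzdist": matches["mzdist"],
        "log10fidist": matches.get("log10fidist", np.nan),
        "penalization_score": matches.get("score", np.nan),
        "status": matches.get("status", "unique"),
    })
    return out.reset_index(drop=True)


def write_matches(result: pd.DataFrame, path: str, delimiter: str = ",") -> None:
    """Write a matched-pairs table (public schema) as delimited text.

    Columns not in the public schema are dropped; an empty result yields a
    header-only file.  Values round-trip through :func:`read_matches` to at
    least 12 significant digits.
    """
    cols = [c for c in MATCH_COLUMNS if c in result.columns]
    if set(("ref_feature_id", "target_feature_id")) - set(result.columns):
        result = matches_to_output(result)
        cols = list(MATCH_COLUMNS)
    bad = set(result["status"].unique()) - set(MATCH_STATUSES) if len(result) else set()
    if bad:
        raise ValidationError(f"unknown match status values: {sorted(bad)}")
    result[cols].to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def read_matches(path: str, delimiter: str | None = None) -> pd.DataFrame:
    """Read back a matched-pairs table written by :func:`write_matches`."""
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    return pd.read_csv(sep=sep, filepath_or_buffer=path,
                       dtype={"ref_feature_id": str, "target_feature_id": str})
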