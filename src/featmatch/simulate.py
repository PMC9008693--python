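"""Synthetic paired-dataset generator with known ground truth.

Emulates the design of a simulation study for benchmarking feature
correspondence: a reference set of LC-MS-like features (RT uniform over the
gradient, MZ log-uniform over the instrument range, log10FI normal), a
target set containing a known subset of those features after a smooth
nonlinear RT shift, a systematic ppm MZ shift, a global log10FI offset and
per-feature random noise, plus dataset-specific decoy features drawn
independently so chance matches can occur.  Optional extras generate the
inputs of the validation strategies: sample-by-feature intensity matrices
with correlated adduct/isotopologue blocks, per-sample covariates with
per-feature effects, npeaks counts and shared annotations.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import FeatureSet

__all__ = ["SimulationParams", "GroundTruth", "SimulatedPair",
           "generate_pair", "score_against_truth"]


def sigmoid_plus_linear(amplitude: float, center: float, width: float,
                        slope: float) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth monotone-in-trend RT shift family: a logistic step of the given
    amplitude (minutes) around ``center`` plus a linear drift ``slope x RT``."""
    def fn(rt: np.ndarray) -> np.ndarray:
        return amplitude / (1.0 + np.exp(-(rt - center) / width)) + slope * rt
    return fn


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the paired-dataset simulator (defaults = the benchmark design).

    Sizes default to the benchmark's 4755 features per set with 2717 planted
    correspondences.  Noise defaults (RT 0.01 min, MZ 2 ppm, log10FI 0.05)
    are a low-noise regime; the RT shift is a 0.3 min sigmoid over a ~10 min
    gradient plus a mild linear drift, MZ is shifted systematically by 5 ppm
    and log10FI by 0.1.
    """

    n_ref: int = 4755
    n_shared: int = 2717
    n_target_extra: int | None = None        # default: n_ref − n_shared
    rt_range: tuple[float, float] = (0.5, 11.5)
    mz_range: tuple[float, float] = (70.0, 1000.0)
    log10fi_mean: float = 5.0
    log10fi_sd: float = 0.8
    # systematic shifts
    rt_shift_amplitude: float = 0.3
    rt_shift_center: float | None = None     # default: gradient midpoint
    rt_shift_width: float | None = None      # default: gradient span / 8
    rt_shift_slope: float = 0.01
    rt_shift_fn: Callable[[np.ndarray], np.ndarray] | None = None
    mz_shift_ppm: float = 5.0
    mz_shift_da: float = 0.0
    fi_shift: float = 0.1
    # random per-feature noise
    rt_noise_sd: float = 0.01                # minutes
    mz_noise_ppm_sd: float = 2.0             # ppm of the feature's m/z
    fi_noise_sd: float = 0.05                # log10 units
    # optional extras for the validation strategies
    adduct_block_size: int = 0
    adduct_block_amp: float = 0.3            # latent-factor loading (log10 units)
    n_samples: int = 0
    sample_noise_sd: float = 0.1             # residual log10 sd in the matrices
    covariate_effect_fraction: float = 0.3
    covariate_slope_sd: float = 0.15         # per standardized covariate unit
    annotate_fraction: float = 0.0
    include_npeaks: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_shared > self.n_ref:
            raise ValidationError(
                f"n_shared ({self.n_shared}) cannot exceed n_ref ({self.n_ref})")
        if min(self.rt_noise_sd, self.mz_noise_ppm_sd, self.fi_noise_sd) < 0:
            raise ValidationError("noise standard deviations must be nonnegative")

    @property
    def n_extra(self) -> int:
        return (self.n_ref - self.n_shared if self.n_target_extra is None
                else self.n_target_extra)

    def rt_shift(self, rt: np.ndarray) -> np.ndarray:
        """The generating RT shift function (minutes, as a function of RT)."""
        if self.rt_shift_fn is not None:
            return np.asarray(self.rt_shift_fn(np.asarray(rt, dtype=float)))
        lo, hi = self.rt_range
        center = self.rt_shift_center if self.rt_shift_center is not None else (lo + hi) / 2
        width = self.rt_shift_width if self.rt_shift_width is not None else (hi - lo) / 8
        return sigmoid_plus_linear(self.rt_shift_amplitude, center, width,
                                   self.rt_shift_slope)(np.asarray(rt, dtype=float))

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """The simulator's answer key: one-to-one true pairs and realized shifts."""

    pairs: pd.DataFrame  # ref_id, target_id, rt_shift, mz_shift, fi_shift

    def __post_init__(self):
        if self.pairs["ref_id"].duplicated().any() or \
           self.pairs["target_id"].duplicated().any():
            raise ValidationError("ground-truth pairs must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["ref_id"], self.pairs["target_id"]))


@dataclass
class SimulatedPair:
    """Generator output; iterable as ``ref, target, truth`` for convenience."""

    ref: FeatureSet
    target: FeatureSet
    truth: GroundTruth
    ref_covariates: pd.DataFrame | None = None
    target_covariates: pd.DataFrame | None = None

    def __iter__(self) -> Iterator:
        return iter((self.ref, self.target, self.truth))


def _base_features(rng: np.random.Generator, n: int, p: SimulationParams):
    rt = rng.uniform(*p.rt_range, size=n)
    lo, hi = np.log(p.mz_range[0]), np.log(p.mz_range[1])
    mz = np.exp(rng.uniform(lo, hi, size=n))
    log10fi = rng.normal(p.log10fi_mean, p.log10fi_sd, size=n)
    return rt, mz, log10fi


def _apply_block_rt(rng, rt: np.ndarray, n_shared: int, block: int) -> np.ndarray:
    """Give members of each adduct block (consecutive shared features) nearly
    identical RTs so they co-elute within a sub-second window."""
    rt = rt.copy()
    for start in range(0, n_shared - block + 1, block):
        rt[start:start + block] = rt[start] + rng.uniform(0, 0.002, size=block)
    return rt


def _shift_to_target(rng, p: SimulationParams, rt, mz, log10fi,
                     block_ids: np.ndarray | None = None):
    """Apply the systematic inter-dataset shifts plus per-feature noise.

    Members of an adduct block share one RT noise draw: the features of one
    metabolite co-elute in *both* datasets, so their retention shifts
    together rather than independently.
    """
    if p.rt_noise_sd > 0:
        rt_noise = rng.normal(0, p.rt_noise_sd, size=len(rt))
        if block_ids is not None:
            for b in np.unique(block_ids[block_ids >= 0]):
                members = np.flatnonzero(block_ids == b)
                rt_noise[members] = rt_noise[members[0]]
        rt_t = rt + p.rt_shift(rt) + rt_noise
    else:
        rt_t = rt + p.rt_shift(rt)
    mz_sys = mz * (1.0 + p.mz_shift_ppm * 1e-6) + p.mz_shift_da
    mz_t = mz_sys + rng.normal(0, 1, size=len(mz)) * mz * p.mz_noise_ppm_sd * 1e-6 \
        if p.mz_noise_ppm_sd > 0 else mz_sys
    fi_t = log10fi + p.fi_shift + (rng.normal(0, p.fi_noise_sd, size=len(log10fi))
                                   if p.fi_noise_sd > 0 else 0.0)
    return rt_t, mz_t, fi_t


def _sample_matrix(rng, p: SimulationParams, log10fi, slopes: np.ndarray,
                   covs: pd.DataFrame, block_ids: np.ndarray) -> pd.DataFrame:
    n, nf = p.n_samples, len(log10fi)
    z = (covs - covs.mean()) / covs.std(ddof=0)  # standardized covariates
    x = np.tile(log10fi, (n, 1))
    x += z.to_numpy() @ slopes.T
    if p.adduct_block_size >= 2:
        for b in np.unique(block_ids):
            if b < 0:
                continue
            u = rng.normal(0, 1, size=n)
            x[:, block_ids == b] += p.adduct_block_amp * u[:, None]
    x += rng.normal(0, p.sample_noise_sd, size=(n, nf))
    return pd.DataFrame(10.0 ** x)


def _covariates(rng, n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.normal(55.0, 10.0, size=n),
        "bmi": rng.normal(27.0, 4.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    })


def generate_pair(params: SimulationParams) -> SimulatedPair:
    """Generate a (reference, target, ground truth) triple from the design.

    The first ``n_shared`` reference features reappear in the target after
    the systematic shifts and noise; ``n_target_extra`` decoys are drawn
    independently (in the target's coordinate frame).  With ``n_samples > 0``
    sample-by-feature intensity matrices and per-sample covariates are also
    produced; shared features keep the same covariate effects in both
    datasets, decoys get their own.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    rt_r, mz_r, fi_r = _base_features(rng, p.n_ref, p)
    shared_blocks = None
    if p.adduct_block_size >= 2:
        rt_r = _apply_block_rt(rng, rt_r, p.n_shared, p.adduct_block_size)
        shared_blocks = np.full(p.n_shared, -1)
        nb = p.n_shared // p.adduct_block_size
        for b in range(nb):
            shared_blocks[b * p.adduct_block_size:(b + 1) * p.adduct_block_size] = b

    sh = slice(0, p.n_shared)
    rt_t_sh, mz_t_sh, fi_t_sh = _shift_to_target(rng, p, rt_r[sh], mz_r[sh],
                                                 fi_r[sh], block_ids=shared_blocks)

    rt_x, mz_x, fi_x = _base_features(rng, p.n_extra, p)
    rt_t_x, mz_t_x, fi_t_x = _shift_to_target(rng, p, rt_x, mz_x, fi_x)

    ref_ids = np.array([f"R{i + 1:05d}" for i in range(p.n_ref)], dtype=object)
    tgt_ids = np.array([f"T{i + 1:05d}" for i in range(p.n_shared + p.n_extra)],
                       dtype=object)
    rt_t = np.concatenate([rt_t_sh, rt_t_x])
    mz_t = np.concatenate([mz_t_sh, mz_t_x])
    fi_t = np.concatenate([fi_t_sh, fi_t_x])

    truth = GroundTruth(pairs=pd.DataFrame({
        "ref_id": ref_ids[sh],
        "target_id": tgt_ids[:p.n_shared],
        "rt_shift": rt_t_sh - rt_r[sh],
        "mz_shift": mz_t_sh - mz_r[sh],
        "fi_shift": fi_t_sh - fi_r[sh],
    }))

    annotation_r = annotation_t = None
    if p.annotate_fraction > 0:
        n_ann = int(round(p.annotate_fraction * p.n_shared))
        which = rng.choice(p.n_shared, size=n_ann, replace=False)
        annotation_r = np.full(p.n_ref, "", dtype=object)
        annotation_t = np.full(len(tgt_ids), "", dtype=object)
        for j, idx in enumerate(sorted(which)):
            annotation_r[idx] = annotation_t[idx] = f"met_{j + 1:04d}"

    npeaks_r = npeaks_t = None
    if p.include_npeaks:
        base = rng.integers(200, 2000, size=p.n_ref)
        npeaks_r = base
        npeaks_t = np.concatenate([
            np.clip(base[sh] + rng.integers(-100, 101, size=p.n_shared), 1, None),
            rng.integers(200, 2000, size=p.n_extra)])

    ref_cov = tgt_cov = None
    matrix_r = matrix_t = None
    if p.n_samples > 0:
        n_cov = 3
        block_ids_r = np.full(p.n_ref, -1)
        if shared_blocks is not None:
            block_ids_r[sh] = shared_blocks
        block_ids_t = np.concatenate([block_ids_r[sh], np.full(p.n_extra, -1)])

        slopes_r = np.zeros((p.n_ref, n_cov))
        active = rng.random(p.n_ref) < p.covariate_effect_fraction
        slopes_r[active] = rng.normal(0, p.covariate_slope_sd,
                                      size=(int(active.sum()), n_cov))
        slopes_x = np.zeros((p.n_extra, n_cov))
        active_x = rng.random(p.n_extra) < p.covariate_effect_fraction
        slopes_x[active_x] = rng.normal(0, p.covariate_slope_sd,
                                        size=(int(active_x.sum()), n_cov))
        slopes_t = np.vstack([slopes_r[sh], slopes_x])  # shared biology

        ref_cov = _covariates(rng, p.n_samples)
        tgt_cov = _covariates(rng, p.n_samples)
        matrix_r = _sample_matrix(rng, p, fi_r, slopes_r, ref_cov, block_ids_r)
        matrix_t = _sample_matrix(rng, p, fi_t, slopes_t, tgt_cov, block_ids_t)

    ref = FeatureSet(feature_id=ref_ids, rt=rt_r, mz=mz_r, fi=10.0 ** fi_r,
                     npeaks=npeaks_r, annotation=annotation_r,
                     sample_intensities=matrix_r)
    target = FeatureSet(feature_id=tgt_ids, rt=rt_t, mz=mz_t, fi=10.0 ** fi_t,
                        npeaks=npeaks_t, annotation=annotation_t,
                        sample_intensities=matrix_t)
    return SimulatedPair(ref=ref, target=target, truth=truth,
                         ref_covariates=ref_cov, target_covariates=tgt_cov)


def score_against_truth(result, truth: GroundTruth) -> dict:
    """Recovery metrics of a matching result against the simulator's answer key.

    ``result`` is a :class:`featmatch.pipeline.MatchResult` or a match table
    with ``ref_id``/``target_id``/``status`` columns.  Reports recovery,
    false positives and precision both for the selected unique matches
    (before poor-match filtering) and for the final set after it.
    """
    matches = result.matches if hasattr(result, "matches") else result
    if len(matches) and len(truth):
        ids_in_play = set(matches["ref_id"]) | set(truth.pairs["ref_id"])
        if not (set(matches["ref_id"]) & set(truth.pairs["ref_id"])) and ids_in_play:
            raise ValidationError("result and ground truth share no feature ids")
    true_pairs = truth.pair_set
    sel = matches[matches["status"].isin(("unique", "poor"))] if len(matches) else matches
    fin = matches[matches["status"] == "unique"] if len(matches) else matches

    def _metrics(df) -> tuple[int, int]:
        pairs = set(zip(df["ref_id"], df["target_id"]))
        correct = len(pairs & true_pairs)
        return correct, len(pairs) - correct

    sel_correct, sel_fp = _metrics(sel)
    fin_correct, fin_fp = _metrics(fin)
    n_true = max(len(truth), 1)
    return {
        "n_true": len(truth),
        "selected": len(sel),
        "recovery": sel_correct / n_true,
        "false_positives": sel_fp,
        "precision": sel_correct / len(sel) if len(sel) else 0.0,
        "final": len(fin),
        "final_recovery": fin_correct / n_true,
        "final_false_positives": fin_fp,
        "final_precision": fin_correct / len(fin) if len(fin) else 0.0,
    }
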