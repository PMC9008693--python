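"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from featmatch import FeatureSet, ThresholdSpec, generate_pair, SimulationParams


def make_featureset(ids, rt, mz, fi=None, **kwargs) -> FeatureSet:
    return FeatureSet(feature_id=np.asarray(ids, dtype=object),
                      rt=np.asarray(rt, dtype=float),
                      mz=np.asarray(mz, dtype=float),
                      fi=None if fi is None else np.asarray(fi, dtype=float),
                      **kwargs)


def random_featureset(rng: np.random.Generator, n: int, prefix: str = "f",
                      with_fi: bool = True) -> FeatureSet:
    return make_featureset(
        [f"{prefix}{i:04d}" for i in range(n)],
        rt=rng.uniform(0.5, 11.5, n),
        mz=np.exp(rng.uniform(np.log(70), np.log(1000), n)),
        fi=10 ** rng.normal(5, 0.8, n) if with_fi else None,
    )


def make_match_df(edges, cluster_id=0, is_unique=False) -> pd.DataFrame:
    """Build a minimal scored match table from edge dicts with keys
    ref, target, score and optional rt_norm / mz_norm / residual columns."""
    ref_ids = {e["ref"]: i for i, e in enumerate(edges) if "ref_index" not in e}
    tgt_ids = {e["target"]: i for i, e in enumerate(edges) if "target_index" not in e}
    rows = []
    for e in edges:
        rows.append({
            "ref_index": e.get("ref_index", ref_ids.get(e["ref"], 0)),
            "target_index": e.get("target_index", tgt_ids.get(e["target"], 0)),
            "ref_id": e["ref"], "target_id": e["target"],
            "rtdist": e.get("rtdist", 0.0), "mzdist": e.get("mzdist", 0.0),
            "log10fidist": e.get("log10fidist", 0.0),
            "cluster_id": e.get("cluster_id", cluster_id),
            "is_unique": e.get("is_unique", is_unique),
            "score": e.get("score", 0.0),
            "rt_norm": e.get("rt_norm", 0.0), "mz_norm": e.get("mz_norm", 0.0),
        })
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A small realistic simulated pair used by several test modules."""
    return generate_pair(SimulationParams(n_ref=400, n_shared=250, seed=7))


@pytest.fixture(scope="session")
def default_thresholds() -> ThresholdSpec:
    return ThresholdSpec.symmetric(rt=0.5, mz=0.01, fi=1.0)
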