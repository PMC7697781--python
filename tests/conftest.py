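"""Shared fixtures: tiny hand-built tables and a fast synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from smbpls import BlockSimConfig, FeatureTable, MultiBlock, SimConfig


def make_table(
    intensities: np.ndarray,
    sample_ids: list[str],
    feature_ids: list[str],
    subjects: list[str] | None = None,
    labels: list[str] | None = None,
    time_points: list[str] | None = None,
    roles: list[str] | None = None,
    orders: list[int] | None = None,
    mz: list[float] | None = None,
    rt: list[float] | None = None,
    name: str = "block",
) -> FeatureTable:
    n = len(sample_ids)
    meta = pd.DataFrame(
        {
            "subject_id": subjects or [f"S{i}" for i in range(n)],
            "class_label": labels or ["A"] * n,
            "time_point": time_points or ["w1"] * n,
            "injection_order": orders or list(range(1, n + 1)),
            "role": roles or ["sample"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    var = pd.DataFrame(
        {
            "mz": mz if mz is not None else [np.nan] * len(feature_ids),
            "rt": rt if rt is not None else [np.nan] * len(feature_ids),
            "mode": "ESI+",
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return FeatureTable(
        intensities=pd.DataFrame(
            np.asarray(intensities, dtype=float), index=meta.index, columns=var.index
        ),
        sample_meta=meta,
        var_meta=var,
        name=name,
    )


def multiblock_from_arrays(
    arrays: list[np.ndarray],
    names: list[str] | None = None,
    subjects: list[str] | None = None,
    labels: list[str] | None = None,
) -> MultiBlock:
    """Wrap plain (already preprocessed) matrices in MultiBlock bookkeeping."""
    n = arrays[0].shape[0]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    names = names or [f"b{k}" for k in range(len(arrays))]
    tables = []
    for arr, name in zip(arrays, names):
        fids = [f"{name}_f{j}" for j in range(arr.shape[1])]
        t = make_table(
            np.zeros_like(np.asarray(arr, dtype=float)), sample_ids, fids,
            subjects=subjects, labels=labels, name=name,
        )
        t = FeatureTable(
            intensities=pd.DataFrame(np.asarray(arr, float), index=t.intensities.index, columns=fids),
            sample_meta=t.sample_meta, var_meta=t.var_meta, name=name,
            allow_negative=True,
        )
        tables.append(t)
    return MultiBlock(tables)


def small_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """A reduced study (6+6 subjects, 60-feature blocks) for fast tests."""
    block_kwargs = dict(
        n_features=60, n_diet_markers=8, n_time_markers=4,
        n_qc=5, n_blank_features=5, cluster_size=5,
        missing_sample_rate=0.05,
    )
    block_kwargs.update(overrides.pop("block_kwargs", {}))
    return SimConfig(
        n_subjects_per_diet=overrides.pop("n_subjects_per_diet", 6),
        blocks=(
            BlockSimConfig(name="plasma", **block_kwargs),
            BlockSimConfig(name="urine", **block_kwargs),
            BlockSimConfig(name="feces", **block_kwargs),
        ),
        seed=seed,
        **overrides,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20241112)
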