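"""Feature filtering, QC drift correction and the scaling chain.

The modeling chain applied to each block is: Pareto scaling (center each
feature and divide by the square root of its standard deviation, damping
the dominance of high-intensity features) followed by division of the
whole block by its Frobenius norm, which puts blocks of different units
and sizes on the same footing.  All scaling statistics can be frozen into
a :class:`ScalingState` estimated on training data and re-applied to new
samples, so cross-validation never leaks test information.

Upstream of scaling live the feature-table filters used for untargeted
LC-MS data: removal of features present in blank injections, an m/z upper
cutoff with retention-time truncation, and a QC-based signal-drift
normalization (per feature, a smooth trend over injection order is fitted
to the QC samples and divided out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import FeatureTable, MultiBlock, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ColumnScaling:
    """Frozen per-feature means/scale divisors for one block."""

    means: np.ndarray
    divisors: np.ndarray  # sqrt(sd); 1.0 where sd == 0 (center only)


@dataclass
class ScalingState:
    """Frozen statistics sufficient to transform new samples identically."""

    columns: list[ColumnScaling] = field(default_factory=list)
    frobenius_norms: list[float] = field(default_factory=list)
    steps: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# feature filters
# --------------------------------------------------------------------------

def blank_filter(table: FeatureTable, ratio_threshold: float = 1.0) -> FeatureTable:
    """Drop features at least as intense in blank injections as in samples.

    A feature is removed when mean(blank) >= ratio_threshold * mean(sample),
    missing intensities counting as zero in both means.  Requires at least
    one role=blank row; to run a pipeline without blanks, skip this filter
    explicitly rather than calling it.
    """
    if ratio_threshold <= 0:
        raise ValidationError("ratio_threshold must be > 0")
    roles = table.sample_meta["role"]
    blank_mask = (roles == "blank").to_numpy()
    sample_mask = (roles == "sample").to_numpy()
    if not blank_mask.any():
        raise ValidationError(
            "no blank rows present; skip the blank filter explicitly instead"
        )
    vals = np.nan_to_num(table.intensities.to_numpy(dtype=float), nan=0.0)
    blank_mean = vals[blank_mask].mean(axis=0)
    sample_mean = vals[sample_mask].mean(axis=0)
    with np.errstate(invalid="ignore"):
        remove = blank_mean >= ratio_threshold * sample_mean
    remove = np.nan_to_num(remove, nan=False).astype(bool)
    kept = [f for f, r in zip(table.feature_ids, remove) if not r]
    logger.info("blank_filter: removed %d of %d features", int(remove.sum()), table.n_features)
    return table.subset(feature_ids=kept)


def mz_rt_filter(
    table: FeatureTable,
    mz_max: float = 700.0,
    rt_window: tuple[float, float] | None = None,
) -> FeatureTable:
    """Drop features with m/z above ``mz_max`` or retention time outside
    ``rt_window``; features lacking mz/rt metadata pass unchanged.

    The boundary is inclusive: a feature at exactly ``mz_max`` is kept
    (only masses strictly higher are discarded).
    """
    if rt_window is not None and rt_window[0] > rt_window[1]:
        raise ValidationError(f"rt_window min > max: {rt_window}")
    mz = pd.to_numeric(table.var_meta.get("mz"), errors="coerce")
    rt = pd.to_numeric(table.var_meta.get("rt"), errors="coerce")
    drop = (mz > mz_max).fillna(False)
    if rt_window is not None:
        drop |= ((rt < rt_window[0]) | (rt > rt_window[1])).fillna(False)
    kept = [f for f, d in zip(table.feature_ids, drop) if not d]
    logger.info("mz_rt_filter: removed %d of %d features", int(drop.sum()), table.n_features)
    return table.subset(feature_ids=kept)


# --------------------------------------------------------------------------
# QC drift normalization
# --------------------------------------------------------------------------

def _fit_trend(
    qc_order: np.ndarray, qc_vals: np.ndarray, all_order: np.ndarray,
    smoother: str, span: float,
) -> np.ndarray:
    if smoother == "linear":
        coef = np.polyfit(qc_order, qc_vals, 1)
        return np.polyval(coef, all_order)
    if smoother == "loess":
        fitted = lowess(qc_vals, qc_order, frac=span, return_sorted=True)
        return np.interp(all_order, fitted[:, 0], fitted[:, 1])
    raise ValidationError(f"unknown smoother {smoother!r}")


def qc_drift_normalize(
    table: FeatureTable, smoother: str = "linear", span: float = 0.75
) -> FeatureTable:
    """Divide out the per-feature intensity trend fitted to QC injections.

    For each feature, the smoother is fitted to QC intensity versus
    injection order; every row's intensity is divided by the fitted trend
    at its own injection order and rescaled so the feature's QC median is
    preserved (units are unchanged).  Features with fewer than two usable
    QC values, or a fitted trend that is not strictly positive anywhere it
    is needed, pass through unchanged with a warning.
    """
    roles = table.sample_meta["role"]
    qc_mask = (roles == "QC").to_numpy()
    order = table.sample_meta["injection_order"].to_numpy(dtype=float)
    if qc_mask.sum() < 2 or len(np.unique(order[qc_mask])) < 2:
        raise ValidationError("need >= 2 QC rows with distinct injection_order")

    vals = table.intensities.to_numpy(dtype=float).copy()
    skipped = 0
    for j in range(vals.shape[1]):
        col = vals[:, j]
        qc_vals = col[qc_mask]
        usable = ~np.isnan(qc_vals)
        if usable.sum() < 2:
            skipped += 1
            continue
        trend = _fit_trend(order[qc_mask][usable], qc_vals[usable], order, smoother, span)
        needed = ~np.isnan(col)
        if np.any(trend[needed] <= 0):
            skipped += 1
            continue
        corrected = col / trend
        qc_median_raw = np.nanmedian(qc_vals)
        qc_median_new = np.nanmedian(corrected[qc_mask])
        if qc_median_new > 0:
            corrected *= qc_median_raw / qc_median_new
        vals[:, j] = corrected
    if skipped:
        logger.warning(
            "qc_drift_normalize: %d feature(s) passed through unchanged "
            "(too few QC values or non-positive trend)", skipped,
        )
    out = table.intensities.copy()
    out.iloc[:, :] = vals
    return FeatureTable(
        intensities=out,
        sample_meta=table.sample_meta.copy(),
        var_meta=table.var_meta.copy(),
        name=table.name,
    )


# --------------------------------------------------------------------------
# scaling chain
# --------------------------------------------------------------------------

def pareto_scale(
    matrix: np.ndarray, state: ColumnScaling | None = None
) -> tuple[np.ndarray, ColumnScaling]:
    """Center each column and divide by the square root of its sample SD.

    Zero-variance columns are centered only.  With a stored state, the
    frozen means/divisors are applied (test folds see no test statistics).
    """
    X = np.asarray(matrix, dtype=float)
    if state is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        divisors = np.where(sds > 0, np.sqrt(sds), 1.0)
        state = ColumnScaling(means=means, divisors=divisors)
    elif state.means.shape[0] != X.shape[1]:
        raise ValidationError(
            f"state has {state.means.shape[0]} features, matrix has {X.shape[1]}"
        )
    return (X - state.means) / state.divisors, state


def frobenius_normalize(
    blocks: MultiBlock, state: ScalingState | None = None
) -> tuple[MultiBlock, ScalingState]:
    """Divide each block by its Frobenius norm (recorded, or reused frozen)."""
    if state is not None and state.frobenius_norms:
        norms = list(state.frobenius_norms)
    else:
        norms = []
        for b in blocks.blocks:
            n = float(np.linalg.norm(b.intensities.to_numpy(dtype=float)))
            if n == 0:
                raise ValidationError(f"zero Frobenius norm in block {b.name!r}")
            norms.append(n)
        if state is None:
            state = ScalingState()
        state.frobenius_norms = norms
        state.steps.append("frobenius")
    out = blocks.map_blocks(lambda arr, i: arr / norms[i])
    out.block_norms = list(norms)
    return out, state


def preprocess_blocks(
    blocks: MultiBlock, state: ScalingState | None = None
) -> tuple[MultiBlock, ScalingState]:
    """Pareto-scale every block, then Frobenius-normalize the set.

    The one-call form of the modeling scaling chain; pass a frozen state
    to transform held-out samples with training statistics.
    """
    if state is None:
        state = ScalingState(steps=["pareto"])
        scaled = []
        for b in blocks.blocks:
            arr, col = pareto_scale(b.intensities.to_numpy(dtype=float))
            state.columns.append(col)
            scaled.append(arr)
    else:
        scaled = [
            pareto_scale(b.intensities.to_numpy(dtype=float), state.columns[i])[0]
            for i, b in enumerate(blocks.blocks)
        ]
    mb = blocks.map_blocks(lambda arr, i: scaled[i])
    mb, state = frobenius_normalize(mb, state)
    return mb, state


def log_transform(values: np.ndarray, offset_policy: str = "half-min") -> np.ndarray:
    """Natural log of non-negative values, column-wise.

    Zeros are replaced by half the smallest positive value in their column
    under the ``half-min`` policy; under ``error`` any zero raises.
    Negative values always raise.
    """
    X = np.asarray(values, dtype=float)
    if np.nanmin(X) < 0:
        raise ValidationError("log_transform: negative value")
    one_d = X.ndim == 1
    X = X.reshape(-1, 1).copy() if one_d else X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        zero = col == 0
        if zero.any():
            if offset_policy == "error":
                raise ValidationError(f"log_transform: zero in column {j} under 'error' policy")
            pos = col[col > 0]
            if pos.size == 0:
                raise ValidationError(f"log_transform: column {j} has no positive value")
            col[zero] = pos.min() / 2.0
    out = np.log(X)
    return out.ravel() if one_d else out
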