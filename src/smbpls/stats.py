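"""Biomarker selection, univariate confirmation and correlation loadings.

Features surviving the sparsity constraint — those with a nonzero row in
the regression-coefficient matrix — are the model's candidate biomarkers.
Each is confirmed univariately by one-way ANOVA on the log-transformed
intensities across the target groups (p <= 0.05 flagged significant).

Correlation loadings place every variable at its Pearson correlations
(r1, r2) with the first two latent-variable score vectors; the plot's
outer circle (radius 1) marks 100% of a variable's variance explained by
the two LVs, the inner circle (radius sqrt(0.5)) marks 50%.  For a
preselected variable set, pairwise correlations are computed after
projecting each variable onto the span of the first two scores (a rank-2
representation), with two-sided p-values from the exact t transform of r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MultiBlock, ValidationError
from .model import SMBPLSRModel
from .preprocess import log_transform

logger = logging.getLogger(__name__)


@dataclass
class CorrelationLoadings:
    """Per-variable (r1, r2) coordinates plus reference-circle geometry."""

    coords: pd.DataFrame          # columns r1, r2; NaN rows flagged constant
    inner_radius: float = np.sqrt(0.5)
    outer_radius: float = 1.0

    def circle(self, radius: float, n: int = 200) -> np.ndarray:
        ang = np.linspace(0.0, 2.0 * np.pi, n)
        return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def select_biomarkers(model: SMBPLSRModel, n_components: int | None = None) -> pd.DataFrame:
    """Features with any nonzero regression coefficient, by block.

    Returns a frame with columns block, feature_id, max_abs_coefficient and
    per-class coefficient direction, sorted by coefficient magnitude
    descending.  A dense model (all degrees of sparsity zero) triggers a
    warning — every feature is then "selected".
    """
    if all(g == 0 for g in model.sparsity_degrees):
        logger.warning("select_biomarkers: model is dense; all features returned")
    B = model.coefficients(n_components)
    nonzero = np.any(B != 0, axis=1)
    block_of = np.repeat(model.block_names, model.feature_counts)
    rows = []
    for j in np.nonzero(nonzero)[0]:
        rec = {
            "block": block_of[j],
            "feature_id": model.feature_ids[j],
            "max_abs_coefficient": float(np.max(np.abs(B[j]))),
        }
        for gi, cls in enumerate(model.class_labels):
            rec[f"direction_{cls}"] = float(np.sign(B[j, gi]))
        rows.append(rec)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(
            "max_abs_coefficient", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
    return out


def anova_log(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """One-way ANOVA F and p on natural-log-transformed values.

    Values must be non-negative; zeros are offset by the half-minimum rule
    before the log.  Degenerate input with zero variance everywhere and
    equal group means returns (0, 1) rather than raising.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValidationError("anova_log needs >= 2 groups")
    if any(np.sum(groups == g) < 2 for g in uniq):
        raise ValidationError("anova_log needs >= 2 observations per group")
    logged = log_transform(values)
    parts = [logged[groups == g] for g in uniq]
    if np.allclose(np.concatenate(parts).var(), 0.0):
        return 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = sps.f_oneway(*parts)
    if np.isnan(f):  # zero within-group variance with equal means
        return 0.0, 1.0
    return float(f), float(p)


def biomarker_report(
    model: SMBPLSRModel,
    blocks: MultiBlock,
    groups: Sequence[str],
    alpha: float = 0.05,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Selected biomarkers with per-feature ANOVA confirmation.

    ``blocks`` carry raw (pre-scaling, non-negative) intensities aligned to
    the model samples; ``groups`` is the classification target per sample.
    """
    sel = select_biomarkers(model, n_components)
    if sel.empty:
        return sel.assign(F=[], p=[], significant=[])
    by_block = {b.name: b for b in blocks.blocks}
    fs, ps = [], []
    for _, row in sel.iterrows():
        tbl = by_block[row["block"]]
        vals = tbl.intensities[row["feature_id"]].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        f, p = anova_log(vals[ok], np.asarray(list(groups))[ok])
        fs.append(f)
        ps.append(p)
    sel = sel.assign(F=fs, p=ps)
    sel["significant"] = sel["p"] <= alpha
    return sel


def correlation_loadings(
    model_or_scores: SMBPLSRModel | np.ndarray,
    variables: pd.DataFrame,
) -> CorrelationLoadings:
    """Pearson correlations of each variable with the first two score vectors.

    ``variables`` is a samples x variables frame aligned to the model's
    samples (preprocessed or raw — correlation is scale-invariant, but the
    same representation used in the model is the conventional choice).
    Constant variables get NaN coordinates and a log entry.
    """
    T = model_or_scores.T if isinstance(model_or_scores, SMBPLSRModel) else np.asarray(model_or_scores)
    if T.shape[1] < 2:
        raise ValidationError("correlation loadings need >= 2 components")
    t1, t2 = T[:, 0], T[:, 1]
    vals = variables.to_numpy(dtype=float)
    if vals.shape[0] != T.shape[0]:
        raise ValidationError("variables not aligned to model samples")
    coords = np.full((vals.shape[1], 2), np.nan)
    n_const = 0
    for j in range(vals.shape[1]):
        v = vals[:, j]
        if np.isclose(v.std(), 0.0):
            n_const += 1
            continue
        coords[j, 0] = np.corrcoef(v, t1)[0, 1]
        coords[j, 1] = np.corrcoef(v, t2)[0, 1]
    if n_const:
        logger.warning("correlation_loadings: %d constant variable(s) flagged missing", n_const)
    return CorrelationLoadings(
        coords=pd.DataFrame(coords, index=variables.columns, columns=["r1", "r2"])
    )


def preselect_by_loading_distance(
    loadings: CorrelationLoadings,
    anchor: tuple[float, float] | str,
    cutoff: float = 0.3,
) -> list[str]:
    """Variables within ``cutoff`` Euclidean distance of an anchor point.

    The anchor is the correlation-loading coordinate of a class dummy
    variable (pass its name if it is a column of the loadings, or explicit
    (r1, r2) coordinates): variables close to a class in the plot are the
    ones most associated with it.
    """
    if isinstance(anchor, str):
        if anchor not in loadings.coords.index:
            raise ValidationError(f"anchor variable {anchor!r} not in loadings")
        ax, ay = loadings.coords.loc[anchor, ["r1", "r2"]]
    else:
        ax, ay = anchor
    d = np.hypot(loadings.coords["r1"] - ax, loadings.coords["r2"] - ay)
    return list(loadings.coords.index[d <= cutoff])


def rank2_correlation_heatmap(
    variables: pd.DataFrame,
    scores: np.ndarray,
    df_policy: str = "n-2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations of variables after rank-2 score projection.

    Each (centered) variable is orthogonally projected onto the span of
    the first two score vectors; Pearson r is computed between projections
    and the two-sided p-value from t = r sqrt((df)/(1-r^2)).  ``df_policy``
    is ``"n-2"`` (default) or the conservative ``"n-3"``.  Pairs involving
    a projection of near-zero norm are NaN-flagged.
    """
    vals = variables.to_numpy(dtype=float)
    n = vals.shape[0]
    if n <= 3:
        raise ValidationError("need more than 3 samples")
    if vals.shape[1] < 2:
        raise ValidationError("need >= 2 variables")
    S = np.asarray(scores)[:, :2]
    # orthonormal basis of the score plane
    Qb, _ = np.linalg.qr(S - S.mean(axis=0))
    centered = vals - vals.mean(axis=0)
    proj = Qb @ (Qb.T @ centered)
    norms = np.linalg.norm(proj, axis=0)
    tiny = norms < 1e-12 * max(1.0, float(np.abs(centered).max()))
    if tiny.any():
        logger.warning("rank2_correlation_heatmap: %d zero-norm projection(s)", int(tiny.sum()))
    m = vals.shape[1]
    R = np.eye(m)
    Pv = np.zeros((m, m))
    dof = n - 2 if df_policy == "n-2" else n - 3
    for i in range(m):
        for j in range(i + 1, m):
            if tiny[i] or tiny[j]:
                R[i, j] = R[j, i] = np.nan
                Pv[i, j] = Pv[j, i] = np.nan
                continue
            r = float(proj[:, i] @ proj[:, j] / (norms[i] * norms[j]))
            r = float(np.clip(r, -1.0, 1.0))
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt(dof / (1.0 - r * r))
                p = float(2.0 * sps.t.sf(abs(t), dof))
            R[i, j] = R[j, i] = r
            Pv[i, j] = Pv[j, i] = p
    cols = variables.columns
    return (
        pd.DataFrame(R, index=cols, columns=cols),
        pd.DataFrame(Pv, index=cols, columns=cols),
    )
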