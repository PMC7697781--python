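"""Leave-one-subject-out cross-validation and model-size selection.

Repeated-measures designs (each animal sampled at several time points)
demand grouped cross-validation: all samples of one subject form one test
fold ("leave-one-pig-out"), otherwise the model is scored on samples
correlated with its training data.  Within every fold the full scaling
chain is re-estimated on the training subjects only and applied frozen to
the held-out subject, so no preprocessing statistic leaks.

Two tuning parameters are optimized on the CV error: the degree of
sparsity of each component (greedy forward search over a grid, earlier
components held fixed) and the number of latent variables A_Opt (the
smallest A whose misclassification rate is not significantly above the
minimum; "significantly" is operationalized as the one-standard-error
rule on fold-wise error rates, with McNemar's test available as an
alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MultiBlock, ValidationError
from .model import IndicatorMatrix, encode_classes, fit_smbplsr
from .preprocess import preprocess_blocks

logger = logging.getLogger(__name__)

DEFAULT_SPARSITY_GRID = (0.0, 0.5, 0.8, 0.9, 0.95, 0.99)


@dataclass
class CVResult:
    """Everything the cross-validation loop measured.

    ``mcr_surface`` has shape (A_max, len(grid)): pooled misclassification
    rate of the a-component model for each candidate degree of sparsity of
    component a (earlier components at their chosen values).  ``mcr_per_a``
    and ``fold_mcr_per_a`` follow the chosen sparsity path.
    """

    fold_subjects: list[str]
    predictions: list[str] | np.ndarray
    true_values: list[str] | np.ndarray
    grid: list[float]
    mcr_surface: np.ndarray
    g_path: list[float]
    mcr_per_a: np.ndarray
    fold_mcr_per_a: np.ndarray          # (A_max, n_folds)
    a_opt: int
    confusion: Optional[pd.DataFrame]
    sr_cv: float
    mcr: float
    sensitivities: Optional[dict[str, float]]
    rmse: Optional[float] = None
    rmse_per_a: Optional[np.ndarray] = None
    mode: str = "classification"


def logo_splits(sample_meta: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train, test) index pair per unique subject, in sorted order.

    All of a subject's samples (every time point) form the test fold.
    """
    if "subject_id" not in sample_meta.columns:
        raise ValidationError("sample_meta lacks subject_id")
    subjects = sample_meta["subject_id"].to_numpy()
    unique = sorted(set(subjects))
    if len(unique) < 2:
        raise ValidationError("leave-one-subject-out needs >= 2 subjects")
    idx = np.arange(len(subjects))
    return [(idx[subjects != s], idx[subjects == s]) for s in unique]


def confusion_and_success_rate(
    true_labels: Sequence[str], predicted_labels: Sequence[str],
    class_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Pooled confusion matrix (true x predicted), SR and per-class sensitivity."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label vectors differ in length")
    classes = sorted(set(true_labels)) if class_labels is None else list(class_labels)
    outside = set(true_labels) | set(predicted_labels)
    if not outside <= set(classes):
        raise ValidationError(f"label(s) outside class set: {sorted(outside - set(classes))}")
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        mat.loc[t, p] += 1
    total = len(true_labels)
    sr = float(np.trace(mat.to_numpy())) / total
    sens = {}
    for c in classes:
        actual = int(mat.loc[c].sum())
        sens[c] = float(mat.loc[c, c]) / actual if actual else float("nan")
    return mat, sr, sens


def select_n_components(
    mcr_per_a: np.ndarray,
    fold_mcr_per_a: np.ndarray,
    rule: str = "one-se",
    predictions_per_a: Optional[Sequence[Sequence[str]]] = None,
    true_labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> int:
    """Smallest A not significantly worse than the error minimum.

    ``one-se``: A_Opt is the smallest A with MCR(A) <= min MCR + SE, where
    SE is the fold-wise standard deviation at the argmin over sqrt(n_folds).
    ``mcnemar``: the smallest A whose disagreement with the argmin model is
    not significant under McNemar's exact test (needs pooled predictions).
    """
    mcr_per_a = np.asarray(mcr_per_a, dtype=float)
    best = int(np.argmin(mcr_per_a))
    if rule == "one-se":
        folds = np.asarray(fold_mcr_per_a, dtype=float)[best]
        se = folds.std(ddof=1) / np.sqrt(folds.size) if folds.size > 1 else 0.0
        ok = np.nonzero(mcr_per_a <= mcr_per_a[best] + se)[0]
        return int(ok[0]) + 1
    if rule == "mcnemar":
        if predictions_per_a is None or true_labels is None:
            raise ValidationError("mcnemar rule needs pooled predictions")
        ref = np.asarray(predictions_per_a[best]) == np.asarray(true_labels)
        for a in range(best + 1):
            cand = np.asarray(predictions_per_a[a]) == np.asarray(true_labels)
            b = int(np.sum(ref & ~cand))
            c = int(np.sum(~ref & cand))
            n = b + c
            p = 1.0 if n == 0 else float(stats.binomtest(min(b, c), n, 0.5).pvalue)
            if p > alpha:
                return a + 1
        return best + 1
    raise ValidationError(f"unknown rule {rule!r}")


def _fold_predictions(
    blocks: MultiBlock,
    Y: IndicatorMatrix | np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    A: int,
    g_path: Sequence[float],
) -> np.ndarray:
    """Pooled out-of-fold continuous predictions for one (A, g-path)."""
    n = blocks.n_samples
    if isinstance(Y, IndicatorMatrix):
        Yvals = Y.values
        width = Yvals.shape[1]
    else:
        Yvals = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        width = Yvals.shape[1]
    pooled = np.full((n, width), np.nan)
    for train, test in folds:
        tr = _subset_multiblock(blocks, train)
        te = _subset_multiblock(blocks, test)
        tr_pre, state = preprocess_blocks(tr)
        if isinstance(Y, IndicatorMatrix):
            ytr = IndicatorMatrix(Yvals[train], Y.class_labels)
        else:
            ytr = Yvals[train]
        model = fit_smbplsr(tr_pre, ytr, A, g_path, scaling_state=state)
        yhat, _ = model.predict(te)
        pooled[test] = yhat
    return pooled


def _subset_multiblock(blocks: MultiBlock, rows: np.ndarray) -> MultiBlock:
    ids = [blocks.sample_ids[i] for i in rows]
    return MultiBlock(
        [b.subset(sample_ids=ids) for b in blocks.blocks],
        list(blocks.block_names),
    )


def _hard_labels(yhat: np.ndarray, classes: list[str]) -> list[str]:
    return [classes[j] for j in np.argmax(yhat, axis=1)]


def cross_validate(
    blocks: MultiBlock,
    targets: Sequence,
    grid: Sequence[float] = DEFAULT_SPARSITY_GRID,
    a_max: int = 2,
    mode: str = "classification",
    selection_rule: str = "one-se",
) -> CVResult:
    """Leave-one-subject-out CV with greedy sparsity and A_Opt selection.

    ``targets`` are class labels (classification) or numbers (regression);
    ``grid`` the candidate degrees of sparsity (sorted ascending so ties
    resolve to the smaller value); ``a_max`` the largest model size tried.
    Preprocessing (Pareto + Frobenius) happens inside each fold.
    """
    grid = sorted(float(v) for v in grid)
    if not grid:
        raise ValidationError("empty sparsity grid")
    if mode not in {"classification", "regression"}:
        raise ValidationError(f"unknown mode {mode!r}")
    meta = blocks.sample_meta
    folds = logo_splits(meta)
    fold_subjects = sorted(set(meta["subject_id"]))

    if mode == "classification":
        Y = encode_classes([str(t) for t in targets])
        true_arr = np.array([str(t) for t in targets])
        classes = Y.class_labels
        missing_train = [
            c for c in classes
            if any(len(set(true_arr[tr]) & {c}) == 0 for tr, _ in folds)
        ]
        if missing_train:
            logger.warning(
                "cross_validate: class(es) %s absent from some training fold",
                missing_train,
            )
    else:
        Y = np.asarray(targets, dtype=float)
        true_arr = Y

    n = blocks.n_samples
    surface = np.full((a_max, len(grid)), np.nan)
    fold_err = np.full((a_max, len(folds)), np.nan)
    err_per_a = np.full(a_max, np.nan)
    preds_per_a: list[np.ndarray] = []
    g_path: list[float] = []

    for a in range(1, a_max + 1):
        best_err, best_gi, best_pooled = np.inf, 0, None
        for gi, g in enumerate(grid):
            pooled = _fold_predictions(blocks, Y, folds, a, g_path + [g])
            if mode == "classification":
                labels = _hard_labels(pooled, classes)
                err = float(np.mean(np.array(labels) != true_arr))
            else:
                err = float(np.sqrt(np.mean((pooled.ravel() - true_arr) ** 2)))
            surface[a - 1, gi] = err
            if err < best_err - 1e-15:   # strict: ties keep the smaller g
                best_err, best_gi, best_pooled = err, gi, pooled
        g_path.append(grid[best_gi])
        err_per_a[a - 1] = best_err
        preds_per_a.append(best_pooled)
        for fi, (_, test) in enumerate(folds):
            if mode == "classification":
                lab = _hard_labels(best_pooled[test], classes)
                fold_err[a - 1, fi] = float(np.mean(np.array(lab) != true_arr[test]))
            else:
                fold_err[a - 1, fi] = float(
                    np.sqrt(np.mean((best_pooled[test].ravel() - true_arr[test]) ** 2))
                )

    if mode == "classification":
        label_preds = [_hard_labels(p, classes) for p in preds_per_a]
        a_opt = select_n_components(
            err_per_a, fold_err, rule=selection_rule,
            predictions_per_a=label_preds, true_labels=list(true_arr),
        )
        final_labels = label_preds[a_opt - 1]
        confusion, sr, sens = confusion_and_success_rate(
            list(true_arr), final_labels, classes
        )
        return CVResult(
            fold_subjects=fold_subjects, predictions=final_labels,
            true_values=list(true_arr), grid=list(grid), mcr_surface=surface,
            g_path=g_path, mcr_per_a=err_per_a, fold_mcr_per_a=fold_err,
            a_opt=a_opt, confusion=confusion, sr_cv=sr, mcr=1.0 - sr,
            sensitivities=sens, mode=mode,
        )

    a_opt = select_n_components(err_per_a, fold_err, rule="one-se")
    final = preds_per_a[a_opt - 1].ravel()
    rmse = float(np.sqrt(np.mean((final - true_arr) ** 2)))
    return CVResult(
        fold_subjects=fold_subjects, predictions=final, true_values=true_arr,
        grid=list(grid), mcr_surface=surface, g_path=g_path,
        mcr_per_a=err_per_a, fold_mcr_per_a=fold_err, a_opt=a_opt,
        confusion=None, sr_cv=float("nan"), mcr=float("nan"),
        sensitivities=None, rmse=rmse, rmse_per_a=err_per_a, mode=mode,
    )


def optimize_sparsity(
    blocks: MultiBlock,
    targets: Sequence,
    grid: Sequence[float],
    a_max: int,
    mode: str = "classification",
) -> tuple[list[float], np.ndarray]:
    """Greedy per-component sparsity path and the full CV-error surface."""
    res = cross_validate(blocks, targets, grid=grid, a_max=a_max, mode=mode)
    return res.g_path, res.mcr_surface
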