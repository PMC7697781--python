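"""Sparse multi-block PLS regression (sMBPLSR) and consensus PCA.

The engine fits NIPALS PLS2 on the horizontally concatenated,
block-normalized superblock.  Per latent variable the loading-weight
vector is soft-thresholded to a configurable degree of sparsity before
the scores are formed, which performs variable selection inside the model
fit.  Block bookkeeping is kept throughout: the sub-vector of the super
weight belonging to block b gives the block score ``t_b = X_b w_b`` and
the super weight ``omega_b = ||w_b||^2`` (the block's share of the squared
weight mass; the unit-norm constraint makes the shares sum to one, and
the super score is exactly the sum of the block scores).

Model equations per component a (X the deflated superblock, Y the
centered indicator matrix):

    w_a  = soft_threshold(X' u / ||X' u||, g_a)      sparse super weight
    t_a  = X w_a                                      super score
    q_a  = Y' t_a / (t_a' t_a)                        Y-loading
    u    = Y q_a / (q_a' q_a)                         iterate to convergence
    p_a  = X' t_a / (t_a' t_a)                        X-loading
    X   <- X - t_a p_a',   Y <- Y - t_a q_a'          deflation
    B    = W (P' W)^{-1} Q'                           coefficients

Consensus PCA on the same superblock provides the unsupervised overview
with the analogous block score / super weight decomposition.
"""

from __future__ import annotations

import io as _io
import json
import logging
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import MultiBlock, ValidationError
from .preprocess import ScalingState, preprocess_blocks

logger = logging.getLogger(__name__)

_CONV_TOL = 1e-10
_MAX_ITER = 500


@dataclass
class IndicatorMatrix:
    """0/1 class-membership matrix, one column per sorted class label."""

    values: np.ndarray
    class_labels: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValidationError("indicator matrix needs >= 2 classes")
        if not np.all(self.values.sum(axis=1) == 1):
            raise ValidationError("each indicator row must sum to 1")


def encode_classes(labels: Sequence[str]) -> IndicatorMatrix:
    """One-hot encode class labels; column order is sorted label order."""
    labels = [str(l) for l in labels]
    if any(l == "" for l in labels):
        raise ValidationError("empty class label present")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError(f"need >= 2 distinct classes, got {classes}")
    idx = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, idx[l]] = 1.0
    return IndicatorMatrix(values=Y, class_labels=classes)


def soft_threshold(w: np.ndarray, degree_of_sparsity: float) -> np.ndarray:
    """Shrink a weight vector toward sparsity and renormalize to unit length.

    With degree of sparsity g in [0, 1), k = max(1, round((1-g) p)) entries
    are retained: lambda is the (k+1)-th largest absolute entry (0 if
    k >= p) and every entry is shrunk by lambda toward zero.  Entries tied
    exactly at lambda are zeroed, so fewer than k may survive; if the tie
    wipes out everything, the first largest-magnitude entry (by index) is
    retained as a logged fallback.
    """
    w = np.asarray(w, dtype=float)
    if not 0.0 <= degree_of_sparsity < 1.0:
        raise ValidationError(f"degree of sparsity must be in [0, 1), got {degree_of_sparsity}")
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValidationError("soft_threshold: zero weight vector")
    p = w.size
    k = max(1, int(math.floor((1.0 - degree_of_sparsity) * p + 0.5)))
    a = np.abs(w)
    lam = 0.0 if k >= p else float(np.sort(a)[::-1][k])
    shrunk = np.sign(w) * np.maximum(a - lam, 0.0)
    if not shrunk.any():
        j = int(np.argmax(a))  # first index among the tied maxima
        logger.info("soft_threshold: tie collapsed all entries; retaining index %d", j)
        shrunk = np.zeros_like(w)
        shrunk[j] = w[j]
    nnz = int(np.count_nonzero(shrunk))
    if nnz < k:
        logger.debug("soft_threshold: ties at lambda left %d < k=%d entries", nnz, k)
    return shrunk / np.linalg.norm(shrunk)


@dataclass
class SMBPLSRModel:
    """Fitted sparse multi-block PLS model.

    Arrays follow the conventional PLS naming: ``W`` (p x A) sparse super
    weights, ``P`` X-loadings, ``Q`` Y-loadings, ``T`` (n x A) super
    scores, ``B`` (p x G) regression coefficients mapping preprocessed X
    to centered Y.  ``block_scores`` is a list (per block) of n x A
    arrays, ``super_weights`` is blocks x A with columns summing to one.
    """

    A: int
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    B: np.ndarray
    y_mean: np.ndarray
    class_labels: list[str]
    sparsity_degrees: list[float]
    block_names: list[str]
    feature_counts: list[int]
    block_scores: list[np.ndarray]
    super_weights: np.ndarray
    explained_x: np.ndarray
    explained_y: np.ndarray
    scaling_state: Optional[ScalingState] = None
    feature_ids: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------
    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficients using the first ``n_components`` LVs."""
        a = self.A if n_components is None else n_components
        if not 1 <= a <= self.A:
            raise ValidationError(f"n_components must be in [1, {self.A}]")
        W, P, Q = self.W[:, :a], self.P[:, :a], self.Q[:, :a]
        M = P.T @ W
        try:
            inv = np.linalg.inv(M)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("degenerate components: P'W singular") from exc
        return W @ inv @ Q.T

    def predict(
        self, new_blocks: MultiBlock, n_components: int | None = None,
        preprocessed: bool = False,
    ) -> tuple[np.ndarray, list[str]]:
        """Continuous responses and argmax class labels for new samples.

        Raw aligned blocks are transformed with the model's frozen
        scaling state unless ``preprocessed=True``.  Ties in the argmax go
        to the first class in column order (logged).
        """
        if not preprocessed:
            if self.scaling_state is None:
                raise ValidationError("model carries no scaling state")
            new_blocks, _ = preprocess_blocks(new_blocks, self.scaling_state)
        X = new_blocks.concatenated()
        if X.shape[1] != self.W.shape[0]:
            raise ValidationError(
                f"feature mismatch: model has {self.W.shape[0]}, input has {X.shape[1]}"
            )
        B = self.coefficients(n_components)
        yhat = X @ B + self.y_mean
        hard = np.argmax(yhat, axis=1)
        if yhat.shape[1] >= 2:
            srt = np.sort(yhat, axis=1)
            ties = np.isclose(srt[:, -1], srt[:, -2])
            if ties.any():
                logger.info("predict: %d tie(s) broken toward first class", int(ties.sum()))
        labels = [self.class_labels[j] for j in hard]
        return yhat, labels

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz-style zip archive (exact round-trip)."""
        path = Path(path)
        arrays = {
            "W": self.W, "P": self.P, "Q": self.Q, "T": self.T, "B": self.B,
            "y_mean": self.y_mean, "super_weights": self.super_weights,
            "explained_x": self.explained_x, "explained_y": self.explained_y,
        }
        for i, bs in enumerate(self.block_scores):
            arrays[f"block_scores_{i}"] = bs
        if self.scaling_state is not None:
            for i, c in enumerate(self.scaling_state.columns):
                arrays[f"scal_means_{i}"] = c.means
                arrays[f"scal_div_{i}"] = c.divisors
        meta = {
            "A": self.A,
            "class_labels": self.class_labels,
            "sparsity_degrees": self.sparsity_degrees,
            "block_names": self.block_names,
            "feature_counts": self.feature_counts,
            "feature_ids": self.feature_ids,
            "frobenius_norms": (
                self.scaling_state.frobenius_norms if self.scaling_state else None
            ),
            "scaling_steps": self.scaling_state.steps if self.scaling_state else None,
        }
        with zipfile.ZipFile(path, "w") as zf:
            for key, arr in arrays.items():
                buf = _io.BytesIO()
                np.save(buf, arr)
                zf.writestr(key + ".npy", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SMBPLSRModel":
        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = {
                n[:-4]: np.load(_io.BytesIO(zf.read(n)))
                for n in zf.namelist() if n.endswith(".npy")
            }
        state = None
        if meta["frobenius_norms"] is not None:
            from .preprocess import ColumnScaling
            cols = []
            i = 0
            while f"scal_means_{i}" in arrays:
                cols.append(ColumnScaling(arrays[f"scal_means_{i}"], arrays[f"scal_div_{i}"]))
                i += 1
            state = ScalingState(
                columns=cols,
                frobenius_norms=list(meta["frobenius_norms"]),
                steps=list(meta["scaling_steps"]),
            )
        n_blocks = len(meta["block_names"])
        return cls(
            A=meta["A"], W=arrays["W"], P=arrays["P"], Q=arrays["Q"],
            T=arrays["T"], B=arrays["B"], y_mean=arrays["y_mean"],
            class_labels=list(meta["class_labels"]),
            sparsity_degrees=list(meta["sparsity_degrees"]),
            block_names=list(meta["block_names"]),
            feature_counts=list(meta["feature_counts"]),
            block_scores=[arrays[f"block_scores_{i}"] for i in range(n_blocks)],
            super_weights=arrays["super_weights"],
            explained_x=arrays["explained_x"], explained_y=arrays["explained_y"],
            scaling_state=state,
            feature_ids=list(meta["feature_ids"]),
        )


def _block_slices(counts: Sequence[int]) -> list[slice]:
    edges = np.concatenate([[0], np.cumsum(counts)])
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def fit_smbplsr(
    blocks: MultiBlock,
    Y: IndicatorMatrix | np.ndarray,
    A: int,
    sparsity_degrees: Sequence[float] | float = 0.0,
    scaling_state: Optional[ScalingState] = None,
) -> SMBPLSRModel:
    """Fit the sparse multi-block PLS model on preprocessed blocks.

    ``blocks`` must already be Pareto-scaled and Frobenius-normalized (use
    :func:`smbpls.preprocess.preprocess_blocks`); pass the resulting state
    so the model can transform future samples identically.  Y is centered
    internally.  ``sparsity_degrees`` is one degree per component or a
    scalar applied to every component.
    """
    if A < 1:
        raise ValidationError("A must be >= 1")
    g = (
        [float(sparsity_degrees)] * A
        if np.isscalar(sparsity_degrees)
        else [float(v) for v in sparsity_degrees]
    )
    if len(g) != A:
        raise ValidationError(f"need {A} sparsity degrees, got {len(g)}")

    if isinstance(Y, IndicatorMatrix):
        Yraw = Y.values.astype(float)
        class_labels = Y.class_labels
    else:
        Yraw = np.atleast_2d(np.asarray(Y, dtype=float).T).T
        class_labels = [f"y{j}" for j in range(Yraw.shape[1])]

    X = blocks.concatenated()
    n, p = X.shape
    if Yraw.shape[0] != n:
        raise ValidationError("X and Y row counts differ")
    y_mean = Yraw.mean(axis=0)
    Yc = Yraw - y_mean
    if np.allclose(Yc, 0):
        raise ValidationError("degenerate Y: constant after centering")

    counts = blocks.feature_counts()
    slices = _block_slices(counts)
    ssx_total = float(np.sum(X ** 2))
    ssy_total = float(np.sum(Yc ** 2))

    Xd, Yd = X.copy(), Yc.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((Yc.shape[1], A))
    T = np.zeros((n, A))
    block_scores = [np.zeros((n, A)) for _ in counts]
    super_weights = np.zeros((len(counts), A))
    explained_x = np.zeros(A)
    explained_y = np.zeros(A)

    for a in range(A):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if np.allclose(u, 0):
            raise ValidationError(f"degenerate Y residual at component {a + 1}")
        t_old = None
        for it in range(_MAX_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValidationError(f"degenerate X residual at component {a + 1}")
            w /= nw
            w = soft_threshold(w, g[a])
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValidationError(f"zero score at component {a + 1}")
            q = Yd.T @ t / tt
            u = Yd @ q / float(q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= _CONV_TOL * np.linalg.norm(t):
                break
            t_old = t
        else:
            logger.warning(
                "fit_smbplsr: component %d did not converge in %d iterations; "
                "accepting last iterate", a + 1, _MAX_ITER,
            )
        p_load = Xd.T @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t
        for b, sl in enumerate(slices):
            block_scores[b][:, a] = Xd[:, sl] @ w[sl]
            super_weights[b, a] = float(w[sl] @ w[sl])
        explained_x[a] = 100.0 * tt * float(p_load @ p_load) / ssx_total
        explained_y[a] = 100.0 * tt * float(q @ q) / ssy_total
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q)

    M = P.T @ W
    if abs(np.linalg.det(M)) < 1e-300:
        raise ValidationError("degenerate components: P'W singular")
    B = W @ np.linalg.inv(M) @ Q.T

    return SMBPLSRModel(
        A=A, W=W, P=P, Q=Q, T=T, B=B, y_mean=y_mean,
        class_labels=class_labels, sparsity_degrees=g,
        block_names=list(blocks.block_names), feature_counts=counts,
        block_scores=block_scores, super_weights=super_weights,
        explained_x=explained_x, explained_y=explained_y,
        scaling_state=scaling_state,
        feature_ids=[f for b in blocks.blocks for f in b.feature_ids],
    )


@dataclass
class CPCAResult:
    """Consensus PCA of the concatenated superblock."""

    A: int
    T: np.ndarray                 # super scores (n x A), U * S
    P: np.ndarray                 # unit loadings (p x A)
    block_scores: list[np.ndarray]
    super_weights: np.ndarray     # blocks x A, columns sum to 1
    explained_x: np.ndarray       # % of total X variance per component


def cpca_fit(blocks: MultiBlock, A: int) -> CPCAResult:
    """Principal components of the superblock with block decomposition.

    Blocks must be centered and Frobenius-normalized.  The super weight of
    a block on a component is the squared mass of its slice of the unit
    loading vector; the block score is the block's slice of data projected
    on that slice.  If A exceeds the matrix rank the result is truncated
    with a warning.
    """
    X = blocks.concatenated()
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int(np.sum(S > tol))
    if A > rank:
        logger.warning("cpca_fit: A=%d exceeds rank %d; truncating", A, rank)
        A = rank
    if A < 1:
        raise ValidationError("cpca_fit: zero-rank input")
    T = U[:, :A] * S[:A]
    P = Vt[:A].T
    slices = _block_slices(blocks.feature_counts())
    block_scores = [X[:, sl] @ P[sl, :] for sl in slices]
    super_weights = np.array([[float(P[sl, a] @ P[sl, a]) for a in range(A)] for sl in slices])
    explained_x = 100.0 * S[:A] ** 2 / float(np.sum(X ** 2))
    return CPCAResult(
        A=A, T=T, P=P, block_scores=block_scores,
        super_weights=super_weights, explained_x=explained_x,
    )
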