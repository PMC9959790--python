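"""Chemometrics core: SD scaling, PCA, PLS-DA and contiguous-block CV.

PLS-DA is ordinary PLS1 regression of a 0/1 class vector on the scaled
concentration matrix, classified by thresholding the continuous prediction
(default threshold 0.4, ties called positive).  Latent variables are
extracted by the deterministic NIPALS sequence (first weight vector
proportional to X'y; no random initialisation), and model complexity is
selected as the first minimum of RMSECV under contiguous-block
cross-validation with seven blocks, following standard chemometrics practice
for ordered sample tables.

Conventions: PCA defaults to *uncentered* SD-scaled data (the variant whose
first component absorbs the common positive-concentration direction), PLS
defaults to centered X and y (autoscaling is applied upstream by the caller).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_array(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


@dataclass
class Scaler:
    """Column SD scaler (optionally mean-centering first)."""

    sd: np.ndarray
    mean: np.ndarray | None = None
    columns: list | None = None

    def transform(self, X):
        Xa, cols = _as_array(X)
        if Xa.shape[1] != self.sd.size:
            raise ValueError(
                f"variable mismatch: scaler has {self.sd.size} columns, data has {Xa.shape[1]}"
            )
        out = (Xa - self.mean) / self.sd if self.mean is not None else Xa / self.sd
        if cols is not None:
            return pd.DataFrame(out, index=X.index, columns=cols)
        return out


def scale_matrix(X, center: bool = False) -> tuple[np.ndarray | pd.DataFrame, Scaler]:
    """Divide each column by its sample SD (ddof=1), mean-centering first iff asked."""
    Xa, cols = _as_array(X)
    if Xa.shape[0] < 2:
        raise ValueError("need at least two samples to scale")
    sd = Xa.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [cols[i] if cols else int(i) for i in zero]
        raise ValueError(f"constant column(s), cannot SD-scale: {names}")
    mean = Xa.mean(axis=0) if center else None
    scaler = Scaler(sd=sd, mean=mean, columns=cols)
    return scaler.transform(X), scaler


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray          # variables x components (orthonormal columns)
    scores: np.ndarray            # samples x components
    explained_pct: np.ndarray     # % of the total sum of squares, per component
    center: bool
    mean: np.ndarray | None = None
    columns: list | None = None


def pca(Xs, n_pc: int, center: bool = False) -> PCAModel:
    """PCA of the (optionally centered) matrix by singular value decomposition.

    ``explained_pct[k] = 100 * sigma_k^2 / sum(sigma^2)`` with the total taken
    over the full decomposition of the same matrix.
    """
    Xa, cols = _as_array(Xs)
    n, p = Xa.shape
    if not 1 <= n_pc <= min(n, p):
        raise ValueError(f"n_pc must be in [1, {min(n, p)}], got {n_pc}")
    mean = Xa.mean(axis=0) if center else None
    Xc = Xa - mean if center else Xa
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S ** 2).sum())
    explained = 100.0 * S[:n_pc] ** 2 / total if total > 0 else np.zeros(n_pc)
    return PCAModel(
        loadings=Vt[:n_pc].T,
        scores=U[:, :n_pc] * S[:n_pc],
        explained_pct=explained,
        center=center,
        mean=mean,
        columns=cols,
    )


# ---------------------------------------------------------------------------
# PLS (NIPALS, single response)
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    n_lv: int
    weights: np.ndarray           # p x n_lv
    x_loadings: np.ndarray        # p x n_lv
    y_loadings: np.ndarray        # n_lv
    coef: np.ndarray              # p (regression vector at n_lv)
    x_mean: np.ndarray | None
    y_mean: float
    center: bool
    columns: list | None = None
    training_labels: np.ndarray | None = None


def _nipals(X: np.ndarray, y: np.ndarray, n_lv: int):
    """Sequential NIPALS latent variables of centered (X, y).

    Returns (W, P, Q, n_extracted); extraction stops early if the residual
    covariance vanishes (rank exhausted).
    """
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    Xr = X.copy()
    yr = y.astype(float).copy()
    eps = 1e-12 * max(1.0, np.abs(X).max()) * max(1.0, np.abs(y).max())
    k = 0
    for a in range(n_lv):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= eps:
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= eps ** 2:
            break
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t) / tt
        W[:, a], P[:, a], Q[a] = w, p_a, q_a
        Xr -= np.outer(t, p_a)
        yr -= q_a * t
        k += 1
    return W[:, :k], P[:, :k], Q[:k], k


def _coef_sequence(W: np.ndarray, P: np.ndarray, Q: np.ndarray, max_lv: int) -> list[np.ndarray]:
    """Regression vectors for 1..max_lv latent variables.

    Beyond the extracted rank the last vector is repeated (the fit cannot
    improve further).
    """
    p, k = W.shape
    coefs = []
    last = np.zeros(p)
    for a in range(1, max_lv + 1):
        if a <= k:
            Wk, Pk, Qk = W[:, :a], P[:, :a], Q[:a]
            last = Wk @ np.linalg.solve(Pk.T @ Wk, Qk)
        coefs.append(last)
    return coefs


def pls_fit(X, y, n_lv: int, center: bool = True) -> PLSModel:
    """Fit a PLS1 / PLS-DA model with ``n_lv`` latent variables."""
    Xa, cols = _as_array(X)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if ya.size != n:
        raise ValueError("X and y length mismatch")
    if np.unique(ya).size < 2:
        raise ValueError("y is single-valued (single-class): cannot fit PLS-DA")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    x_mean = Xa.mean(axis=0) if center else None
    y_mean = float(ya.mean()) if center else 0.0
    Xc = Xa - x_mean if center else Xa.copy()
    yc = ya - y_mean
    W, P, Q, k = _nipals(Xc, yc, n_lv)
    coef = _coef_sequence(W, P, Q, n_lv)[-1]
    return PLSModel(
        n_lv=n_lv, weights=W, x_loadings=P, y_loadings=Q, coef=coef,
        x_mean=x_mean, y_mean=y_mean, center=center, columns=cols,
        training_labels=np.asarray(y),
    )


def pls_predict(m: PLSModel, X_new) -> np.ndarray:
    """Continuous class estimates for new samples."""
    Xa, cols = _as_array(X_new)
    if Xa.shape[1] != m.coef.size:
        raise ValueError(
            f"variable mismatch: model has {m.coef.size} variables, data has {Xa.shape[1]}"
        )
    if cols is not None and m.columns is not None and cols != m.columns:
        raise ValueError("variable names do not match the training columns")
    Xc = Xa - m.x_mean if m.center else Xa
    return Xc @ m.coef + m.y_mean


# ---------------------------------------------------------------------------
# Contiguous-block cross-validation
# ---------------------------------------------------------------------------


def contiguous_blocks(n: int, n_blocks: int) -> list[np.ndarray]:
    """Split 0..n-1 in order into near-equal contiguous blocks, larger first."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_blocks > n:
        raise ValueError("more blocks than samples")
    base, extra = divmod(n, n_blocks)
    sizes = [base + 1] * extra + [base] * (n_blocks - extra)
    idx = np.arange(n)
    blocks, start = [], 0
    for s in sizes:
        blocks.append(idx[start : start + s])
        start += s
    return blocks


@dataclass
class CVResult:
    rmsecv: np.ndarray            # per LV count 1..max_lv
    rmsec: np.ndarray
    q2: np.ndarray
    r2: np.ndarray
    chosen_n_lv: int
    block_sizes: list[int]
    skipped_folds: list[int] = field(default_factory=list)
    cv_predictions: np.ndarray | None = None   # at chosen_n_lv; NaN for skipped folds


def cv_pls(X, y, n_blocks: int = 7, max_lv: int | None = None, center: bool = True) -> CVResult:
    """Contiguous-block cross-validation of PLS1 over 1..max_lv latent variables.

    RMSECV pools the held-out predictions of all usable folds; Q2 = 1 -
    PRESS/TSS with TSS about the overall mean of y; RMSEC and R2 come from the
    full-data fit.  The chosen complexity is the first minimum of RMSECV.
    """
    Xa, _ = _as_array(X)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    blocks = contiguous_blocks(n, n_blocks)
    min_train = n - max(len(b) for b in blocks)
    cap = min(p, min_train - 1)
    if max_lv is None:
        max_lv = cap
    if max_lv > cap:
        warnings.warn(f"max_lv={max_lv} too large for the smallest training fold; capped at {cap}")
        max_lv = cap
    if max_lv < 1:
        raise ValueError("no usable latent variables")

    preds = np.full((n, max_lv), np.nan)
    skipped = []
    for bi, block in enumerate(blocks):
        train = np.setdiff1d(np.arange(n), block, assume_unique=True)
        y_tr = ya[train]
        if np.unique(y_tr).size < 2:
            warnings.warn(f"fold {bi}: training data single-class; fold skipped")
            skipped.append(bi)
            continue
        X_tr = Xa[train]
        x_mean = X_tr.mean(axis=0) if center else np.zeros(p)
        y_mean = y_tr.mean() if center else 0.0
        W, P, Q, _ = _nipals(X_tr - x_mean, y_tr - y_mean, max_lv)
        Xc_te = Xa[block] - x_mean
        for a, coef in enumerate(_coef_sequence(W, P, Q, max_lv)):
            preds[block, a] = Xc_te @ coef + y_mean
    used = ~np.isnan(preds[:, 0])
    if not used.any():
        raise ValueError("all folds degenerate: cross-validation impossible")

    resid = preds[used] - ya[used, None]
    press = (resid ** 2).sum(axis=0)
    rmsecv = np.sqrt(press / used.sum())
    tss = float(((ya[used] - ya.mean()) ** 2).sum())
    q2 = 1.0 - press / tss

    # full-data fit
    x_mean = Xa.mean(axis=0) if center else np.zeros(p)
    y_mean = ya.mean() if center else 0.0
    W, P, Q, _ = _nipals(Xa - x_mean, ya - y_mean, max_lv)
    Xc = Xa - x_mean
    rss = np.array(
        [(((Xc @ coef + y_mean) - ya) ** 2).sum() for coef in _coef_sequence(W, P, Q, max_lv)]
    )
    rmsec = np.sqrt(rss / n)
    tss_full = float(((ya - ya.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss_full

    chosen = int(np.argmin(rmsecv)) + 1  # first minimum on ties
    return CVResult(
        rmsecv=rmsecv, rmsec=rmsec, q2=q2, r2=r2, chosen_n_lv=chosen,
        block_sizes=[len(b) for b in blocks], skipped_folds=skipped,
        cv_predictions=preds[:, chosen - 1],
    )


# ---------------------------------------------------------------------------
# Classification and ROC
# ---------------------------------------------------------------------------


def classify(y_hat, threshold: float = 0.4) -> np.ndarray:
    """Label positive iff the continuous estimate is >= threshold (tie -> positive)."""
    y_hat = np.asarray(y_hat, dtype=float)
    if not np.all(np.isfinite(y_hat)):
        raise ValueError("non-finite class estimates")
    return (y_hat >= threshold).astype(int)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    operating_threshold: float


def roc(y_true, y_hat, thresholds: np.ndarray | None = None) -> ROCCurve:
    """Sensitivity/specificity as a function of the positive-call threshold.

    The reported operating threshold maximises min(sensitivity, specificity)
    — the point where both are high and comparable.
    """
    y_true = np.asarray(y_true).astype(int)
    y_hat = np.asarray(y_hat, dtype=float)
    if np.unique(y_true).size < 2:
        raise ValueError("both classes must be present")
    if thresholds is None:
        lo, hi = y_hat.min(), y_hat.max()
        pad = 1e-6 * max(1.0, hi - lo)
        thresholds = np.linspace(lo - pad, hi + pad, 201)
    thresholds = np.asarray(thresholds, dtype=float)
    pos = y_true == 1
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        called = y_hat >= t
        sens[i] = (called & pos).sum() / pos.sum()
        spec[i] = (~called & ~pos).sum() / (~pos).sum()
    best = int(np.argmax(np.minimum(sens, spec)))
    return ROCCurve(thresholds, sens, spec, float(thresholds[best]))
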