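"""One-class SIMCA modeling with a leverage/residual acceptance boundary.

A SIMCA model is a PCA of the (class-locally autoscaled) members of the
target class.  Each sample is summarised by two statistics:

* leverage — the Hotelling T² distance inside the retained score space,
  ``T²_i = sum_k t_ik² / lambda_k`` with ``lambda_k`` the score variances;
* residual — the squared reconstruction error ``Q_i = ||x_i - t_i P'||²``
  orthogonal to the retained components.

A sample is accepted when both statistics fall below their critical values:
the T² limit from the F-distribution for a new observation on
``(n_pc, n - n_pc)`` degrees of freedom, and the Q limit from the
Jackson–Mudholkar approximation built on the discarded eigenvalues.  So that
the rectangular region has overall confidence ~ 1 - alpha, each statistic is
limited at the Šidák-split level ``1 - sqrt(1 - alpha)`` by default
(``split_alpha=False`` applies alpha to each limit separately).  A combined
normalised-distance boundary ``sqrt((Q/Q_crit)² + (T²/T²_crit)²) <= 1`` is
available via ``boundary="combined"``.

Model complexity is chosen by contiguous-block cross-validated PRESS
(minimum, smallest count on ties); when an out-of-class set is supplied the
alternative criterion maximising the geometric mean of CV sensitivity and
specificity is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chemometrics import Scaler, _as_array, contiguous_blocks, scale_matrix


@dataclass
class SIMCAModel:
    class_label: str
    scaler: Scaler
    loadings: np.ndarray           # p x n_pc, orthonormal columns
    eigenvalues: np.ndarray        # retained score variances (length n_pc)
    discarded_eigenvalues: np.ndarray
    n_train: int
    n_pc: int
    alpha: float
    t2_crit: float
    q_crit: float
    boundary: str = "rectangular"
    split_alpha: bool = True


def _t2_limit(n: int, n_pc: int, alpha: float) -> float:
    """Hotelling T² limit for a new observation."""
    f = stats.f.ppf(1.0 - alpha, n_pc, n - n_pc)
    return n_pc * (n - 1) * (n + 1) / (n * (n - n_pc)) * f


def _q_limit(discarded: np.ndarray, alpha: float) -> float:
    """Jackson–Mudholkar critical value for the Q residual."""
    lam = np.asarray(discarded, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 0.0
    t1, t2, t3 = lam.sum(), (lam ** 2).sum(), (lam ** 3).sum()
    h0 = 1.0 - 2.0 * t1 * t3 / (3.0 * t2 ** 2)
    z = stats.norm.ppf(1.0 - alpha)
    if h0 <= 0:
        # fall back to the Box g*chi2 approximation when h0 degenerates
        g, dof = t2 / t1, t1 ** 2 / t2
        return float(g * stats.chi2.ppf(1.0 - alpha, dof))
    inner = z * np.sqrt(2.0 * t2 * h0 ** 2) / t1 + 1.0 + t2 * h0 * (h0 - 1.0) / t1 ** 2
    return float(t1 * inner ** (1.0 / h0))


def simca_fit(
    X_class,
    n_pc: int,
    alpha: float = 0.05,
    class_label: str = "positive",
    boundary: str = "rectangular",
    split_alpha: bool = True,
) -> SIMCAModel:
    """Fit a one-class SIMCA model on class members only."""
    Xa, _ = _as_array(X_class)
    n, p = Xa.shape
    if n < n_pc + 2:
        raise ValueError(f"need at least n_pc + 2 = {n_pc + 2} class members, got {n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if boundary not in ("rectangular", "combined"):
        raise ValueError("boundary must be 'rectangular' or 'combined'")
    Xs, scaler = scale_matrix(X_class, center=True)
    Xs_a, _ = _as_array(Xs)
    _, S, Vt = np.linalg.svd(Xs_a, full_matrices=False)
    lam = S ** 2 / (n - 1)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if n_pc > rank:
        raise ValueError(f"n_pc={n_pc} exceeds the data rank {rank}")
    a_each = 1.0 - np.sqrt(1.0 - alpha) if split_alpha else alpha
    return SIMCAModel(
        class_label=class_label,
        scaler=scaler,
        loadings=Vt[:n_pc].T,
        eigenvalues=lam[:n_pc],
        discarded_eigenvalues=lam[n_pc:],
        n_train=n,
        n_pc=n_pc,
        alpha=alpha,
        t2_crit=_t2_limit(n, n_pc, a_each),
        q_crit=_q_limit(lam[n_pc:], a_each),
        boundary=boundary,
        split_alpha=split_alpha,
    )


def simca_score(m: SIMCAModel, X_new):
    """Per-sample (leverage, residual, accepted) for new data.

    Returns a dict of arrays: ``leverage`` (Hotelling T²), ``residual`` (Q)
    and the boolean ``accepted`` mask under the model's boundary.
    """
    Xa, _ = _as_array(X_new)
    if Xa.shape[1] != m.loadings.shape[0]:
        raise ValueError(
            f"variable mismatch: model has {m.loadings.shape[0]} variables, "
            f"data has {Xa.shape[1]}"
        )
    Xs = m.scaler.transform(Xa)
    T = Xs @ m.loadings
    t2 = ((T ** 2) / m.eigenvalues).sum(axis=1)
    resid = Xs - T @ m.loadings.T
    q = (resid ** 2).sum(axis=1)
    tol = 1e-10 * max(1.0, float(m.eigenvalues[0]))
    if m.boundary == "combined":
        qc = max(m.q_crit, tol)
        d = np.sqrt((q / qc) ** 2 + (t2 / m.t2_crit) ** 2)
        accepted = d <= 1.0
    else:
        accepted = (t2 <= m.t2_crit) & (q <= m.q_crit + tol)
    return {"leverage": t2, "residual": q, "accepted": accepted}


def simca_variable_leverage(m: SIMCAModel) -> np.ndarray:
    """Per-variable leverage: row sums of squared retained loadings.

    Values lie in [0, 1] and sum to n_pc (orthonormal loadings)."""
    return (m.loadings ** 2).sum(axis=1)


@dataclass
class SIMCACVResult:
    press: np.ndarray              # per component count 1..max_pc
    recommended_n_pc: int          # argmin PRESS (smallest on ties)
    gmean: np.ndarray | None = None
    gmean_n_pc: int | None = None


def _elementwise_press(Xs_te: np.ndarray, P: np.ndarray) -> float:
    """Held-out PRESS by leave-one-variable-out imputation.

    For each held-out sample and each variable j, x_j is predicted from the
    remaining variables through the k-component loadings fit without the
    sample.  Unlike naive re-projection (which is monotone non-increasing in
    k), this estimate degrades once noise components are added, so PRESS
    attains a genuine minimum at the supported dimensionality.
    """
    p, k = P.shape
    total = 0.0
    for j in range(p):
        Pj = np.delete(P, j, axis=0)            # (p-1) x k
        xj = Xs_te[:, j]
        Xo = np.delete(Xs_te, j, axis=1)        # m x (p-1)
        scores, *_ = np.linalg.lstsq(Pj, Xo.T, rcond=None)
        xj_hat = P[j] @ scores
        total += float(((xj - xj_hat) ** 2).sum())
    return total


def simca_cv_press(
    X_class,
    max_pc: int,
    n_blocks: int = 7,
    X_out=None,
    alpha: float = 0.05,
) -> SIMCACVResult:
    """Contiguous-block CV of the class model: PRESS per component count.

    PRESS_k sums, over held-out class members, the squared reconstruction
    error using k components fit without them (element-wise leave-one-
    variable-out imputation, so PRESS has a genuine minimum).  With an
    out-of-class set the geometric mean of CV sensitivity and specificity per
    k is also reported.
    """
    Xa, _ = _as_array(X_class)
    n, p = Xa.shape
    blocks = contiguous_blocks(n, n_blocks)
    min_train = n - max(len(b) for b in blocks)
    cap = min(p, min_train - 1)
    if max_pc > cap:
        warnings.warn(f"max_pc={max_pc} too large for the smallest fold; truncated to {cap}")
        max_pc = cap
    if max_pc < 1:
        raise ValueError("no usable components")
    Xout_a = _as_array(X_out)[0] if X_out is not None else None

    press = np.zeros(max_pc)
    acc_in = np.zeros(max_pc)
    rej_out = np.zeros(max_pc)
    n_out_evals = 0
    for block in blocks:
        train = np.setdiff1d(np.arange(n), block, assume_unique=True)
        Xs_tr, scaler = scale_matrix(Xa[train], center=True)
        _, S, Vt = np.linalg.svd(Xs_tr, full_matrices=False)
        lam = S ** 2 / (len(train) - 1)
        Xs_te = scaler.transform(Xa[block])
        Xs_out = scaler.transform(Xout_a) if Xout_a is not None else None
        a_each = 1.0 - np.sqrt(1.0 - alpha)
        for k in range(1, max_pc + 1):
            P = Vt[:k].T
            press[k - 1] += _elementwise_press(np.asarray(Xs_te), P)
            if Xs_out is not None:
                t2c = _t2_limit(len(train), k, a_each)
                qc = _q_limit(lam[k:], a_each)
                tol = 1e-10 * max(1.0, float(lam[0]))

                def _accept(Z):
                    T = Z @ P
                    t2 = ((T ** 2) / lam[:k]).sum(axis=1)
                    q = ((Z - T @ P.T) ** 2).sum(axis=1)
                    return (t2 <= t2c) & (q <= qc + tol)

                acc_in[k - 1] += _accept(Xs_te).mean()
                rej_out[k - 1] += 1.0 - _accept(Xs_out).mean()
        n_out_evals += 1
    recommended = int(np.argmin(press)) + 1
    gmean = gmean_n_pc = None
    if Xout_a is not None:
        sens = acc_in / n_out_evals
        spec = rej_out / n_out_evals
        gmean = np.sqrt(sens * spec)
        gmean_n_pc = int(np.argmax(gmean)) + 1
    return SIMCACVResult(press=press, recommended_n_pc=recommended,
                         gmean=gmean, gmean_n_pc=gmean_n_pc)
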