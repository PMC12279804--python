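"""Batched soft-margin linear SVM solver.

Time-resolved decoding needs tens of thousands of tiny SVM fits per subject
(one per class x timepoint x fold x iteration), each on a handful of
trial-averaged exemplars in channel space.  All problems in a batch share
their sample count and label pattern, so they are solved simultaneously with
vectorised array operations.

The objective is the standard L2-regularised squared-hinge ("L2-loss") SVM

    min_w  0.5 ||w||^2 + C sum_i max(0, 1 - y_i w.x_i)^2

with the bias handled as an augmented constant feature scaled by
``intercept_scaling`` — i.e. exactly the objective scikit-learn's
``LinearSVC(loss="squared_hinge", C=C, intercept_scaling=s)`` minimises.
The scaling matters: ERP feature vectors sit far from the origin (trial
averages of like-signed voltages), so a unit-scaled augmented bias would be
heavily penalised and the fit would collapse to a degenerate small-norm
solution; a large scale (default 100) makes the bias effectively free, as in
the libsvm-style solvers common in ERP decoding toolboxes.  The dual is a
strictly convex non-negative quadratic program in only n (= sample count)
variables,

    min_a  0.5 a' (Q + I/(2C)) a - 1'a   s.t.  a >= 0,
    Q_ij = y_i y_j x_i.x_j,

which an active-set method (Lawson-Hanson) solves *exactly* in a few batched
n x n linear solves.  First-order solvers (liblinear's coordinate descent
included) converge impractically slowly on these problems: trial-averaged
ERP exemplars have large norms and tiny class separations, so the dual is
badly conditioned, while the active-set solve is unaffected.  Agreement with
a fully converged ``LinearSVC`` is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_linear_svm_batch", "decision_values"]


def _solve_masked(M: np.ndarray, rhs_mask: np.ndarray) -> np.ndarray:
    """Solve M_PP x_P = 1 for each problem, where P is a boolean column mask;
    entries outside P are fixed at 0 (their rows/cols replaced by identity)."""
    B, n, _ = M.shape
    pair = rhs_mask[:, :, None] & rhs_mask[:, None, :]
    Mp = np.where(pair, M, 0.0)
    idx = np.arange(n)
    diag = Mp[:, idx, idx]
    Mp[:, idx, idx] = np.where(rhs_mask, diag, 1.0)
    rhs = rhs_mask.astype(float)[:, :, None]
    return np.linalg.solve(Mp, rhs)[:, :, 0]


def fit_linear_svm_batch(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-9,
    fit_intercept: bool = True,
    intercept_scaling: float = 100.0,
) -> np.ndarray:
    """Fit one linear SVM per batch entry, exactly, via the dual active set.

    Parameters
    ----------
    X
        ``(B, n, d)`` feature array: B independent problems, n samples each.
    y
        ``(n,)`` labels in {+1, -1}, shared by all problems in the batch.
    C
        Soft-margin cost.
    tol
        KKT tolerance on the dual gradient (the duals start at gradient -1,
        so this is effectively relative).
    fit_intercept
        Append a constant feature of value ``intercept_scaling`` (the
        returned weight vector then has ``d + 1`` entries, the last being
        the bias already multiplied back to data units).
    intercept_scaling
        Scale of the augmented bias feature; large values leave the bias
        essentially unpenalised (see module docstring).

    Returns
    -------
    ``(B, d[+1])`` primal weight vectors ``w`` (+ bias as last entry).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    y = np.asarray(y, dtype=float)
    B, n, d = X.shape
    if y.shape != (n,):
        raise ValueError("y must have one label per sample")
    if not np.all(np.abs(y) == 1):
        raise ValueError("labels must be +1/-1")
    if fit_intercept:
        X = np.concatenate(
            [X, np.full((B, n, 1), float(intercept_scaling))], axis=2
        )

    Xy = X * y[None, :, None]
    M = np.einsum("bid,bjd->bij", Xy, Xy)
    idx = np.arange(n)
    M[:, idx, idx] += 1.0 / (2.0 * C)

    alpha = np.zeros((B, n))
    passive = np.zeros((B, n), dtype=bool)
    rows = np.arange(B)
    # Outer loop: admit the worst KKT violator per problem, then restore
    # feasibility of the passive set.  Finite termination is guaranteed for
    # strictly convex objectives; the cap is a safety net.
    for _ in range(4 * n + 16):
        grad = np.einsum("bij,bj->bi", M, alpha) - 1.0
        viol = np.where(~passive & (alpha == 0.0), grad, np.inf)
        worst = viol.min(axis=1)
        unfinished = worst < -tol
        if not unfinished.any():
            break
        enter = viol.argmin(axis=1)
        passive[rows[unfinished], enter[unfinished]] = True
        # Inner loop: equality solve on the passive set; if any passive
        # variable would go non-positive, step to the first boundary and
        # drop that variable, then re-solve.
        for _ in range(n + 1):
            trial = _solve_masked(M, passive)
            bad = passive & (trial <= 0.0)
            if not bad.any():
                alpha = np.where(passive, trial, 0.0)
                break
            need_fix = bad.any(axis=1)
            denom = alpha - trial
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(bad, alpha / denom, np.inf)
            step = np.clip(ratio.min(axis=1), 0.0, 1.0)
            blocker = ratio.argmin(axis=1)
            move = need_fix
            alpha = np.where(
                move[:, None], alpha + step[:, None] * (trial - alpha), alpha
            )
            alpha[rows[move], blocker[move]] = 0.0
            passive[rows[move], blocker[move]] = False
            # problems that were already fine adopt their solution unchanged
            ok = ~need_fix
            alpha = np.where(ok[:, None] & passive, trial, alpha)
            alpha = np.where(ok[:, None] & ~passive, 0.0, alpha)

    w = np.einsum("bn,bnd->bd", alpha, Xy)
    if fit_intercept:
        w[:, -1] *= float(intercept_scaling)  # bias in data units
    return w


def decision_values(w: np.ndarray, X: np.ndarray, fit_intercept: bool = True) -> np.ndarray:
    """Evaluate ``w . x (+ b)`` for batched weights ``(B, d[+1])`` and test
    features ``(B, m, d)``; returns ``(B, m)``."""
    if fit_intercept:
        return np.einsum("bmd,bd->bm", X, w[:, :-1]) + w[:, -1][:, None]
    return np.einsum("bmd,bd->bm", X, w)
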