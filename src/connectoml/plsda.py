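"""Partial least squares discriminant analysis (PLS-DA) with VIP scoring.

Independent verification arm for the SVM feature selection: a two-component
PLS-DA is fit on the consensus edges, each edge gets a variable-importance-
in-projection (VIP) score

    VIP_j = sqrt( p * sum_a[ SSY_a * (w_aj / ||w_a||)^2 ] / sum_a SSY_a )

with p predictors and SSY_a = b_a^2 * t_a' t_a the Y-sum-of-squares explained
by component a, so that sum_j VIP_j^2 = p exactly; edges at or above the 0.8
importance threshold are flagged. The fit is classical NIPALS on
column-standardised X with class membership coded ±1 and centred; class
predictions go by the sign of the predicted (centred) response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .rng import derive_int_seed

__all__ = ["PLSDAResult", "fit_plsda", "vip_scores", "plsda_cv_performance"]

VIP_THRESHOLD = 0.8


@dataclass
class PLSDAResult:
    """A fitted PLS-DA model (NIPALS, standardised X, ±1-coded y)."""

    n_components: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A), unit columns
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    ssy: np.ndarray  # (A,) explained Y sum of squares per component
    coef: np.ndarray  # (p,) regression vector on the standardised scale
    n_iter: np.ndarray  # NIPALS iterations per component
    converged: bool

    def decision_values(self, X) -> np.ndarray:
        """Predicted centred response for new rows (class = sign)."""
        z = (np.asarray(X, float) - self.x_mean) / self.x_sd
        return z @ self.coef

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_values(X) >= 0, 1, 0)


def _code_y(y) -> tuple[np.ndarray, float]:
    y = np.asarray(y, int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    coded = np.where(y == 1, 1.0, -1.0)
    mean = float(coded.mean())
    return coded - mean, mean


def fit_plsda(
    X, y, n_components: int = 2, tol: float = 1e-10, max_iter: int = 500
) -> PLSDAResult:
    """NIPALS PLS-DA on standardised X and ±1-centred y.

    With a single response column each component's weight direction has the
    closed form w ∝ X'y, so NIPALS converges in one pass; the iteration loop
    is kept for the general shape of the algorithm and non-convergence is
    flagged with the iteration count rather than raised.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components={n_components} invalid for X {X.shape}")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    E = (X - x_mean) / x_sd
    f, y_mean = _code_y(y)
    A = n_components
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    b = np.zeros(A)
    iters = np.zeros(A, dtype=int)
    converged = True
    for a in range(A):
        u = f.copy()
        t_old = None
        for it in range(1, max_iter + 1):
            w = E.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("degenerate component: X'y vanished (no covariance left)")
            w /= norm
            t = E @ w
            q = float(f @ t / (t @ t))
            u = f * q  # single-column Y: u stays proportional to f
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            converged = False
        iters[a] = it
        p_a = E.T @ t / (t @ t)
        b_a = float(f @ t / (t @ t))
        E = E - np.outer(t, p_a)
        f = f - b_a * t
        W[:, a], T[:, a], P[:, a], b[a] = w, t, p_a, b_a
    ssy = b**2 * np.einsum("na,na->a", T, T)
    # regression vector: B = W (P'W)^{-1} b
    coef = W @ np.linalg.solve(P.T @ W, b)
    return PLSDAResult(
        n_components=A,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        weights=W,
        scores=T,
        loadings=P,
        y_loadings=b,
        ssy=ssy,
        coef=coef,
        n_iter=iters,
        converged=converged,
    )


def vip_scores(model: PLSDAResult) -> np.ndarray:
    """Cumulative VIP over the model's components (sum VIP^2 = p exactly)."""
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = model.weights.shape[0]
    wnorm2 = (model.weights / np.linalg.norm(model.weights, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ model.ssy) / total)


def plsda_cv_performance(
    X, y, n_components: int = 2, k_folds: int = 10, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Stratified k-fold CV accuracy of the PLS-DA classifier.

    Standardisation happens inside each fold from fold-training statistics;
    folds mirror the SVM arm's stratified machinery. Returns (mean accuracy,
    per-fold accuracies).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    skf = StratifiedKFold(
        n_splits=k_folds, shuffle=True, random_state=derive_int_seed(seed, "plsda_cv")
    )
    accs = []
    for tr, te in skf.split(X, y):
        a = min(n_components, min(len(tr) - 1, X.shape[1]))
        model = fit_plsda(X[tr], y[tr], n_components=a)
        accs.append(float((model.predict(X[te]) == y[te]).mean()))
    accs = np.array(accs)
    return float(accs.mean()), accs
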