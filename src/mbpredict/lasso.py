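"""L1-penalized multinomial logistic regression with a λ path and CV selection.

The model links class probabilities to the predictor vector x_i through
the soft-max

    P(y_i = k | x_i) = exp(β_kᵀ x_i) / Σ_l exp(β_lᵀ x_i),

and the fit minimizes the penalized negative log-likelihood

    l(β) = −Σ_i log P(y_i | x_i, β) + λ Σ_k ||β_k||_1,

with the intercept excluded from the penalty.  The parameterization is
symmetric (one coefficient vector per class); the L1 penalty resolves
the soft-max shift ambiguity.

The solver is monotone FISTA (accelerated proximal gradient with a
function-value restart) combined with an active-set strategy: each λ is
solved on the working set of currently-active or KKT-violating columns
and the Karush–Kuhn–Tucker conditions are then verified on the full
set.  The λ grid is geometric from the data-driven λ_max (smallest λ
that zeroes every penalized coefficient) down to ratio·λ_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .metrics import argmax_predict, error_rate


def softmax_proba(logits: np.ndarray) -> np.ndarray:
    """Row-wise soft-max with log-sum-exp stabilization."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Class probabilities for coefficient set ``coef`` (K × p)."""
    return softmax_proba(X @ coef.T)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (np.asarray(y)[:, None] == classes[None, :]).astype(float)


def _nll(coef: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    logits = X @ coef.T
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    return float(np.sum(lse - (z * Y).sum(axis=1)))

def _nll_grad(coef: np.ndarray, X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    logits = X @ coef.T
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    denom = e.sum(axis=1, keepdims=True)
    P = e / denom
    nll = float(np.sum(np.log(denom[:, 0]) - (z * Y).sum(axis=1)))
    grad = (P - Y).T @ X  # K × p
    return nll, grad


def objective(coef: np.ndarray, X: np.ndarray, Y: np.ndarray, lam: float, penalized: np.ndarray) -> float:
    """Penalized negative log-likelihood l_LASSO(β)."""
    return _nll(coef, X, Y) + lam * np.abs(coef[:, penalized]).sum()


def _lipschitz(X: np.ndarray) -> float:
    """Upper bound on the gradient Lipschitz constant: ½ σ_max(X)²."""
    v = np.ones(X.shape[1]) / np.sqrt(X.shape[1])
    nrm = 1.0
    for _ in range(20):
        w = X @ v
        v = X.T @ w
        nrm = np.linalg.norm(v)
        if nrm == 0:
            return 1.0
        v /= nrm
    # small safety margin: the power iteration approaches σ_max² from below
    return 0.5 * 1.05 * nrm


def _soft_threshold(B: np.ndarray, t: float, penalized: np.ndarray) -> np.ndarray:
    out = B.copy()
    out[:, penalized] = np.sign(B[:, penalized]) * np.maximum(np.abs(B[:, penalized]) - t, 0.0)
    return out


def _fista(
    B0: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    penalized: np.ndarray,
    L: float,
    tol: float,
    max_iter: int,
    debug: bool = False,
) -> tuple[np.ndarray, bool]:
    """Accelerated proximal gradient; returns (coefficients, converged).

    The fast path uses the gradient-based adaptive restart (restart the
    momentum whenever the update turns against the last step), checking
    the objective only periodically; ``debug`` switches to the strictly
    monotone variant that evaluates and asserts the objective every
    iteration.
    """
    B = B0.copy()
    V = B.copy()
    t_mom = 1.0
    step = 1.0 / L
    f_prev = objective(B, X, Y, lam, penalized)
    converged = False
    check_every = 1 if debug else 8
    for it in range(max_iter):
        _, g = _nll_grad(V, X, Y)
        B_new = _soft_threshold(V - step * g, lam * step, penalized)
        if debug:
            f_new = objective(B_new, X, Y, lam, penalized)
            if f_new > f_prev:  # momentum overshoot: restart monotonically
                _, g = _nll_grad(B, X, Y)
                B_new = _soft_threshold(B - step * g, lam * step, penalized)
                f_new = objective(B_new, X, Y, lam, penalized)
                t_mom = 1.0
            assert f_new <= f_prev + 1e-9, "objective increased"
        elif np.vdot(V - B_new, B_new - B) > 0:  # adaptive restart
            t_mom = 1.0
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
        V = B_new + ((t_mom - 1) / t_new) * (B_new - B)
        B, t_mom = B_new, t_new
        if (it + 1) % check_every == 0:
            f_new = objective(B, X, Y, lam, penalized)
            if f_prev - f_new <= tol * check_every * (abs(f_prev) + 1.0) and f_new <= f_prev + 1e-9:
                converged = True
                break
            f_prev = f_new
    return B, converged


def kkt_violations(
    coef: np.ndarray, X: np.ndarray, Y: np.ndarray, lam: float, penalized: np.ndarray, tol: float
) -> np.ndarray:
    """Column indices whose zero coefficients violate |gradient| <= λ + tol."""
    _, g = _nll_grad(coef, X, Y)
    zero = coef == 0
    viol = (np.abs(g) > lam + tol) & zero
    viol[:, ~penalized] = False
    return np.flatnonzero(viol.any(axis=0))


def fit_lasso_mlr(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalized: np.ndarray | None = None,
    classes: np.ndarray | None = None,
    coef_init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    kkt_tol: float = 1e-4,
    debug: bool = False,
) -> tuple[np.ndarray, bool]:
    """Minimize the L1-penalized multinomial log-likelihood at one λ.

    Returns (K × p coefficient matrix, converged flag).  ``penalized``
    marks the columns the L1 penalty applies to (default: all but the
    first, which is taken to be the intercept).
    """
    if lam < 0 or not np.isfinite(lam):
        raise ValueError("lambda must be finite and >= 0")
    if classes is None:
        classes = np.unique(y)
    Y = _one_hot(y, classes)
    n, p = X.shape
    K = classes.size
    if penalized is None:
        penalized = np.ones(p, dtype=bool)
        penalized[0] = False
    B = np.zeros((K, p)) if coef_init is None else coef_init.copy()
    # active-set outer loop: solve on the working set, then verify KKT globally
    work = np.flatnonzero((B != 0).any(axis=0) | ~penalized)
    converged = True
    for _ in range(20):
        if work.size:
            Lw = _lipschitz(X[:, work])
            Bw, conv = _fista(B[:, work], X[:, work], Y, lam, penalized[work], Lw, tol, max_iter, debug)
            B[:, work] = Bw
            converged = conv
        viol = kkt_violations(B, X, Y, lam, penalized, kkt_tol)
        new = np.setdiff1d(viol, work)
        if new.size == 0:
            break
        work = np.union1d(work, new)
    else:
        converged = False
    if not np.isfinite(objective(B, X, Y, lam, penalized)):
        raise FloatingPointError("non-finite LASSO objective")
    return B, converged


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 200, ratio: float = 1e-4,
                penalized: np.ndarray | None = None, classes: np.ndarray | None = None) -> np.ndarray:
    """Geometric λ grid from λ_max down to ratio·λ_max.

    λ_max is the smallest λ at which all penalized coefficients are 0:
    the largest |gradient| of the unpenalized log-likelihood over
    penalized coordinates, evaluated at the intercept-only (null) fit.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if classes is None:
        classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("response has fewer than 2 classes")
    Y = _one_hot(y, classes)
    n, p = X.shape
    if penalized is None:
        penalized = np.ones(p, dtype=bool)
        penalized[0] = False
    freq = Y.mean(axis=0)
    # null model: p_ik = f_k for all i (intercept-only optimum)
    G = (freq[None, :] - Y).T @ X
    lam_max = float(np.abs(G[:, penalized]).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


@dataclass
class LassoPath:
    lambdas: np.ndarray
    coef_sets: list[np.ndarray]
    classes: np.ndarray
    converged: np.ndarray
    cv_error: np.ndarray | None = None
    selected_lambda: float | None = None

    @property
    def selected_index(self) -> int | None:
        if self.selected_lambda is None:
            return None
        return int(np.argmin(np.abs(self.lambdas - self.selected_lambda)))


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    penalized: np.ndarray | None = None,
    classes: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    dev_ratio_stop: float = 0.999,
) -> LassoPath:
    """Fit the whole λ path with warm starts (λ descending).

    Like the reference penalized-path implementations, the path stops
    early once the fitted deviance saturates (the training data are
    essentially interpolated); the remaining, smaller λ values inherit
    the last computed coefficient set.
    """
    if classes is None:
        classes = np.unique(y)
    Y = _one_hot(y, classes)
    freq = Y.mean(axis=0)
    nll_null = float(-np.sum(Y * np.log(np.clip(freq, 1e-12, None))[None, :]))
    order = np.argsort(-np.asarray(lambdas, dtype=float))
    coefs: list[np.ndarray | None] = [None] * len(lambdas)
    conv = np.zeros(len(lambdas), dtype=bool)
    B = None
    last = None
    for rank, i in enumerate(order):
        if last is not None:
            coefs[i] = last
            conv[i] = True
            continue
        B, c = fit_lasso_mlr(
            X, y, float(lambdas[i]), penalized=penalized, classes=classes,
            coef_init=B, tol=tol, max_iter=max_iter,
        )
        coefs[i] = B.copy()
        conv[i] = c
        if nll_null > 0 and 1.0 - _nll(B, X, Y) / nll_null > dev_ratio_stop:
            last = B.copy()
    return LassoPath(np.asarray(lambdas, dtype=float), coefs, classes, conv)


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels 0..k-1, stratified by class."""
    y = np.asarray(y)
    folds = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    scheme: str = "kfold",
    k: int = 10,
    seed: int = 0,
    penalized: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 2000,
    dev_ratio_stop: float = 0.995,
) -> tuple[float, np.ndarray]:
    """Select λ by cross-validated error rate.

    ``scheme`` is "kfold" (stratified, ``k`` folds) or "loocv".  Ties in
    minimum CV error are broken toward the largest λ (sparser model).
    Fold fits use a slightly looser tolerance and deviance stop than the
    final fit: held-out error rates are insensitive at that resolution.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    if scheme == "loocv":
        folds = np.arange(n)
        k = n
    elif scheme == "kfold":
        if k > n:
            raise ValueError("k exceeds the number of samples")
        for attempt in range(10):
            folds = stratified_folds(y, k, rng)
            ok = all(np.unique(y[folds != f]).size == classes.size for f in range(k))
            if ok:
                break
        else:
            raise RuntimeError("could not build folds containing every class")
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    lambdas = np.asarray(lambdas, dtype=float)
    errors = np.zeros((k, lambdas.size))
    counts = np.zeros(k)
    for f in range(k):
        tr = folds != f
        va = ~tr
        maj = classes[np.argmax([(y[tr] == c).sum() for c in classes])]
        maj_col = int(np.flatnonzero(classes == maj)[0])
        path = fit_lasso_path(X[tr], y[tr], lambdas, penalized=penalized, classes=classes,
                              tol=tol, max_iter=max_iter, dev_ratio_stop=dev_ratio_stop)
        for i, B in enumerate(path.coef_sets):
            proba = predict_proba(B, X[va])
            yhat = argmax_predict(proba, classes, majority_first=maj_col)
            errors[f, i] = np.sum(yhat != y[va])
        counts[f] = va.sum()
    cv_er = errors.sum(axis=0) / counts.sum()
    best = cv_er.min()
    # ties -> largest lambda; grid is descending so take the first index
    sel = int(np.flatnonzero(cv_er <= best + 1e-12)[0])
    return float(lambdas[sel]), cv_er


def fit_mlr_ridge(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    classes: np.ndarray | None = None,
    penalized: np.ndarray | None = None,
) -> np.ndarray:
    """Unpenalized multinomial logistic fit with a tiny ridge guard.

    Used for the GLM stage of screening+GLM and for the oracle
    benchmark; the fixed small ridge (default 1e-6) on non-intercept
    coefficients keeps the fit finite under perfect separation.
    """
    if classes is None:
        classes = np.unique(y)
    Y = _one_hot(y, classes)
    n, p = X.shape
    K = classes.size
    if penalized is None:
        penalized = np.ones(p, dtype=bool)
        penalized[0] = False
    mask = np.broadcast_to(penalized, (K, p))

    def fun(flat):
        B = flat.reshape(K, p)
        nll, g = _nll_grad(B, X, Y)
        nll += 0.5 * ridge * np.sum((B * mask) ** 2)
        g = g + ridge * B * mask
        return nll, g.ravel()

    res = minimize(fun, np.zeros(K * p), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
    return res.x.reshape(K, p)
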