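"""Per-OTU count GLMMs, likelihood-ratio screening, and q-values.

Each OTU's counts are modelled conditional on fixed factors and (as a
random intercept) a grouping factor, with the log of total reads as an
offset:

    log μ_i = log T_i + X_i β + W_i b,   b_g ~ N(0, σ²_b).

Three model families are supported:

* ``nb`` — negative binomial with inverse dispersion θ;
* ``zinb`` — zero-inflated NB: a point mass at zero with probability
  φ_i (logit-linked, intercept-only under H0) mixed with an NB;
* ``tpnb`` — a two-part scheme dispatched on the observed zero
  proportion (ZP): plain NB when ZP ≤ 10%, a hurdle model (logistic
  presence + zero-truncated NB for positives) when 10% < ZP ≤ 80%,
  logistic regression alone when 80% < ZP < 90%, and the OTU is
  dropped (p := 1) when ZP ≥ 90%.

Screening tests H0 (phenotype absent) against H1 (phenotype added to
the mean model, and to the zero/presence components where they exist)
with a likelihood-ratio test; p-values are converted to q-values
(Benjamini–Hochberg step-up by default) and OTUs are selected by
thresholding q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from . import _glmm_kernels as K
from .io_filters import OTUTable, SampleCovariates
from .transforms import dummy_code

REGIME_NB = "nb"
REGIME_HURDLE = "hurdle"
REGIME_LOGISTIC = "logistic"
REGIME_DROPPED = "dropped"

_FAMILY_CODES = {
    "nb": K.NB,
    "truncated_nb": K.TRUNC_NB,
    "bernoulli": K.BERNOULLI,
    "zinb": K.ZINB,
}

_THETA_MIN = 1e-3


def nb_logpmf(z, mu, theta):
    """Log-pmf of the negative binomial with mean μ and inverse dispersion θ.

    Computed through log-gamma, stable for large counts and θ; as
    θ → ∞ it converges to the Poisson log-pmf.
    """
    z = np.asarray(z, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return (
        gammaln(z + theta)
        - gammaln(theta)
        - gammaln(z + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + z * (np.log(mu) - np.log(theta + mu))
    )


@dataclass
class GlmmFit:
    """A fitted count-model component."""

    family: str
    beta: np.ndarray
    gamma: np.ndarray | None
    theta: float | None
    sigma2_b: float
    b_modes: np.ndarray | None
    loglik: float
    converged: bool
    n_params: int


def _group_layout(groups: np.ndarray | None):
    """Sort order and contiguous group offsets for the kernel."""
    if groups is None:
        return None, np.zeros(1, dtype=np.int64)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    sorted_g = groups[order]
    change = np.flatnonzero(np.concatenate([[True], sorted_g[1:] != sorted_g[:-1]]))
    group_start = np.concatenate([change, [groups.size]]).astype(np.int64)
    return order, group_start


def fit_count_glmm(
    z: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    groups: np.ndarray | None,
    family: str,
    zero_design: np.ndarray | None = None,
    start: np.ndarray | None = None,
    maxiter: int = 200,
) -> GlmmFit:
    """Maximize the (Laplace-approximate) marginal likelihood of one component.

    ``family`` ∈ {nb, truncated_nb, bernoulli, zinb}.  ``X`` is the
    fixed-effect design (with intercept); ``zero_design`` the design of
    the ZINB zero component.  With ``groups`` given, a random intercept
    per group is integrated out by Laplace approximation; without, the
    fit is an exact GLM.  Non-convergence never raises: the flag is
    carried on the result.
    """
    fam = _FAMILY_CODES[family]
    z = np.asarray(z, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    offset = np.asarray(offset, dtype=np.float64)
    use_random = groups is not None and np.unique(np.asarray(groups)).size > 1
    order, group_start = _group_layout(groups if use_random else None)
    if order is not None:
        z_s, X_s, off_s = z[order], X[order], offset[order]
        Z0_s = zero_design[order] if zero_design is not None else None
    else:
        z_s, X_s, off_s = z, X, offset
        Z0_s = zero_design
    p = X.shape[1]
    q = zero_design.shape[1] if (family == "zinb" and zero_design is not None) else 0
    has_theta = family in ("nb", "truncated_nb", "zinb")

    n_par = p + q + int(has_theta) + int(use_random)

    if start is None:
        beta0 = np.zeros(p)
        if family == "bernoulli":
            pbar = min(max(z_s.mean(), 1e-3), 1 - 1e-3)
            beta0[0] = np.log(pbar / (1 - pbar))
        else:
            beta0[0] = np.log((z_s.sum() + 0.5) / np.exp(off_s).sum())
        x0 = [beta0]
        if q:
            g0 = np.zeros(q)
            zp = np.clip((z_s == 0).mean(), 0.02, 0.9)
            g0[0] = np.log(zp / (1 - zp))
            x0.append(g0)
        if has_theta:
            x0.append([0.0])  # log theta = 0 -> theta 1
        if use_random:
            x0.append([np.log(0.3)])
        x0 = np.concatenate(x0)
    else:
        x0 = np.asarray(start, dtype=float)

    bounds = [(-30, 30)] * p + [(-30, 30)] * q
    if has_theta:
        bounds.append((np.log(_THETA_MIN), 14.0))
    if use_random:
        bounds.append((-15.0, 8.0))

    Z0_mat = np.ascontiguousarray(Z0_s, dtype=np.float64) if q else np.zeros((z_s.size, 0))
    X_mat = np.ascontiguousarray(X_s)
    b_cache = np.zeros(max(len(group_start) - 1, 1))

    def unpack(x):
        beta = x[:p]
        gamma = x[p : p + q] if q else None
        i = p + q
        theta = float(np.exp(x[i])) if has_theta else 1.0
        if has_theta:
            i += 1
        sigma2 = float(np.exp(x[i])) if use_random else 0.0
        return beta, gamma, theta, sigma2

    def nll(x):
        beta, gamma, theta, sigma2 = unpack(x)
        gam = gamma if q else np.zeros(0)
        val, grad = K.nll_and_grad(fam, z_s, X_mat, off_s, Z0_mat, beta, gam, theta,
                                   sigma2, group_start, use_random, has_theta, b_cache)
        if not np.isfinite(val):
            return 1e12, np.zeros_like(x)
        return val, grad

    res = minimize(nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 3e-6})
    beta, gamma, theta, sigma2 = unpack(res.x)
    loglik = -float(res.fun)
    converged = bool(res.success) and np.isfinite(loglik)

    b_modes = None
    if use_random:
        eta = off_s + X_s @ beta
        gz = Z0_mat @ gamma if q else np.zeros_like(z_s)
        b_modes = K.conditional_modes(fam, z_s, eta, gz, theta, sigma2, group_start)
        # sigma2 at the lower boundary: compare with the pure fixed-effect fit
        if np.log(sigma2) < -13.0:
            glm = fit_count_glmm(z, X, offset, None, family, zero_design=zero_design, maxiter=maxiter)
            if glm.loglik >= loglik:
                return GlmmFit(family, glm.beta, glm.gamma, glm.theta, 0.0, np.zeros(len(group_start) - 1),
                               glm.loglik, glm.converged, n_par)
    return GlmmFit(family, beta, gamma, theta if has_theta else None, sigma2, b_modes,
                   loglik, converged, n_par)


def fit_hurdle(
    z: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    groups: np.ndarray | None,
    start_presence: np.ndarray | None = None,
    start_positive: np.ndarray | None = None,
) -> tuple[GlmmFit, GlmmFit, float, bool]:
    """NB hurdle: logistic presence fit + zero-truncated NB fit on positives.

    Returns (presence fit, positive-part fit, total loglik, converged).
    """
    z = np.asarray(z, dtype=float)
    pres = (z > 0).astype(float)
    fit_p = fit_count_glmm(pres, X, np.zeros_like(z), groups, "bernoulli", start=start_presence)
    pos = z > 0
    groups_pos = np.asarray(groups)[pos] if groups is not None else None
    fit_c = fit_count_glmm(z[pos], X[pos], np.asarray(offset)[pos], groups_pos,
                           "truncated_nb", start=start_positive)
    total = fit_p.loglik + fit_c.loglik
    return fit_p, fit_c, total, fit_p.converged and fit_c.converged


def tpnb_dispatch(zero_proportion: float) -> str:
    """Map an OTU's zero proportion to the two-part NB fitting regime."""
    zp = float(zero_proportion)
    if not (0.0 <= zp <= 1.0):
        raise ValueError("zero proportion must lie in [0, 1]")
    if zp <= 0.10:
        return REGIME_NB
    if zp <= 0.80:
        return REGIME_HURDLE
    if zp < 0.90:
        return REGIME_LOGISTIC
    return REGIME_DROPPED


def lrt(loglik0: float, loglik1: float, df: int, both_converged: bool = True) -> tuple[float, float]:
    """Likelihood-ratio test: T_n = 2(logL1 − logL0) against chi-square(df).

    Negative statistics (numerical artifacts of the approximate
    marginal likelihood) are clipped to 0.  Non-convergence of either
    fit yields the conservative p = 1.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    t = max(2.0 * (loglik1 - loglik0), 0.0)
    if not both_converged or not np.isfinite(t):
        return t, 1.0
    return t, float(chi2.sf(t, df))


@dataclass
class ScreeningResult:
    """Per-OTU screening records, in the input OTU order."""

    taxon_ids: tuple[str, ...]
    statistic: np.ndarray
    df: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray = field(default=None)
    regime: list[str] = field(default_factory=list)
    converged: np.ndarray = field(default=None)

    def to_frame(self, q_cutoff: float = 0.05):
        import pandas as pd

        return pd.DataFrame(
            {
                "taxon_id": list(self.taxon_ids),
                "regime": self.regime,
                "statistic": self.statistic,
                "df": self.df,
                "p_value": self.p_value,
                "q_value": self.q_value,
                "selected": self.q_value <= q_cutoff,
            }
        )


def _phenotype_dummies(y: np.ndarray) -> np.ndarray:
    mat, _ = dummy_code(np.asarray(y))
    return mat


def screen_all(
    table: OTUTable,
    covs: SampleCovariates,
    model: str = "tpnb",
    include_random: bool = True,
    q_method: str = "bh",
    sample_mask: np.ndarray | None = None,
) -> ScreeningResult:
    """Likelihood-ratio screen of every OTU for a phenotype effect.

    H0 conditions each OTU's counts on the fixed factors (and the
    random intercept when ``include_random``); H1 adds the phenotype.
    Degrees of freedom: K−1 where the phenotype enters one component
    (NB; the pure-logistic regime of TPNB), 2(K−1) where it enters two
    (ZINB mean+zero; hurdle presence+positive).  Dropped (ZP ≥ 90%) and
    non-converged OTUs get p = 1.
    """
    if model not in ("nb", "zinb", "tpnb"):
        raise ValueError(f"unknown screening model {model!r}")
    if sample_mask is not None:
        idx = np.flatnonzero(sample_mask)
        table = table.take_samples(idx)
        covs = covs.take(idx)
    y = covs.phenotype
    Klev = np.unique(np.asarray(y)).size
    if Klev < 2:
        raise ValueError("phenotype must have at least 2 levels")
    ydum = _phenotype_dummies(y)
    n = table.n_samples

    # fixed-effect designs
    cols = [np.ones((n, 1))]
    for name, v in covs.fixed.items():
        v = np.asarray(v)
        if np.issubdtype(v.dtype, np.number):
            vv = v.astype(float)
            sd = vv.std()
            cols.append(((vv - vv.mean()) / (sd if sd > 0 else 1.0)).reshape(-1, 1))
        else:
            mat, _ = dummy_code(v)
            cols.append(mat)
    X0 = np.hstack(cols)
    X1 = np.hstack([X0, ydum])

    groups = None
    if include_random and covs.random:
        first = next(iter(covs.random))
        groups = np.asarray(covs.random[first])

    offset = np.log(table.totals.astype(float))
    m = table.n_taxa
    stat = np.zeros(m)
    dfs = np.zeros(m, dtype=int)
    pvals = np.ones(m)
    regimes: list[str] = []
    conv = np.zeros(m, dtype=bool)

    for j in range(m):
        z = table.counts[:, j].astype(float)
        zp = float((z == 0).mean())
        if model == "tpnb":
            regime = tpnb_dispatch(zp)
        else:
            regime = REGIME_DROPPED if zp >= 0.90 else model
        regimes.append(regime)
        if regime == REGIME_DROPPED:
            pvals[j] = 1.0
            continue
        try:
            if regime == REGIME_NB or regime == "nb":
                f0 = fit_count_glmm(z, X0, offset, groups, "nb")
                s1 = _warm_start(f0, extra=ydum.shape[1])
                f1 = fit_count_glmm(z, X1, offset, groups, "nb", start=s1)
                df = Klev - 1
                t, p = lrt(f0.loglik, f1.loglik, df, f0.converged and f1.converged)
                ok = f0.converged and f1.converged
            elif regime == "zinb":
                z0_0 = np.ones((n, 1))
                z0_1 = np.hstack([np.ones((n, 1)), ydum])
                f0 = fit_count_glmm(z, X0, offset, groups, "zinb", zero_design=z0_0)
                s1 = _warm_start_zinb(f0, extra_mean=ydum.shape[1], extra_zero=ydum.shape[1])
                f1 = fit_count_glmm(z, X1, offset, groups, "zinb", zero_design=z0_1, start=s1)
                df = 2 * (Klev - 1)
                t, p = lrt(f0.loglik, f1.loglik, df, f0.converged and f1.converged)
                ok = f0.converged and f1.converged
            elif regime == REGIME_HURDLE:
                h0p, h0c, ll0, ok0 = fit_hurdle(z, X0, offset, groups)
                _, _, ll1, ok1 = fit_hurdle(
                    z, X1, offset, groups,
                    start_presence=_warm_start(h0p, extra=ydum.shape[1]),
                    start_positive=_warm_start(h0c, extra=ydum.shape[1]),
                )
                df = 2 * (Klev - 1)
                t, p = lrt(ll0, ll1, df, ok0 and ok1)
                ok = ok0 and ok1
            else:  # logistic regime
                pres = (z > 0).astype(float)
                f0 = fit_count_glmm(pres, X0, np.zeros(n), groups, "bernoulli")
                s1 = _warm_start(f0, extra=ydum.shape[1])
                f1 = fit_count_glmm(pres, X1, np.zeros(n), groups, "bernoulli", start=s1)
                df = Klev - 1
                t, p = lrt(f0.loglik, f1.loglik, df, f0.converged and f1.converged)
                ok = f0.converged and f1.converged
        except Exception:
            t, p, df, ok = 0.0, 1.0, Klev - 1, False
        stat[j] = t
        dfs[j] = df
        pvals[j] = p
        conv[j] = ok

    qvals = compute_qvalues(pvals, method=q_method)
    return ScreeningResult(table.taxon_ids, stat, dfs, pvals, qvals, regimes, conv)


def _warm_start_zinb(fit: GlmmFit, extra_mean: int, extra_zero: int) -> np.ndarray:
    """H1 ZINB start: zeros appended to both the mean and zero components."""
    parts = [fit.beta, np.zeros(extra_mean), fit.gamma, np.zeros(extra_zero),
             [np.log(max(fit.theta, _THETA_MIN))]]
    if fit.b_modes is not None:
        parts.append([np.log(max(fit.sigma2_b, 1e-6))])
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _warm_start(fit: GlmmFit, extra: int) -> np.ndarray:
    """H1 starting point from an H0 fit: append zeros for the new coefficients."""
    parts = [fit.beta, np.zeros(extra)]
    if fit.gamma is not None:
        parts.append(fit.gamma)
    if fit.theta is not None:
        parts.append([np.log(max(fit.theta, _THETA_MIN))])
    if fit.b_modes is not None:
        parts.append([np.log(max(fit.sigma2_b, 1e-6))])
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def compute_qvalues(pvalues: np.ndarray, method: str = "bh", zeta: float = 0.5) -> np.ndarray:
    """q-values by the step-up rule q(p_[j]) = min_{t ≥ p_[j]} m π̂0 t / #{p ≤ t}.

    ``bh`` fixes π̂0 = 1 (classic Benjamini–Hochberg); ``storey``
    estimates π̂0(ζ) = #{p ≥ ζ}/(m(1−ζ)).  Output is in input order and
    monotone in the p-value ranks.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = min(1.0, np.sum(p >= zeta) / (m * (1.0 - zeta)))
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = m * pi0 * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_otus(screening: ScreeningResult, q_cutoff: float = 0.05) -> np.ndarray:
    """Indices of OTUs with q ≤ cutoff, in original order."""
    if not (0 < q_cutoff < 1):
        raise ValueError("q_cutoff must be in (0, 1)")
    return np.flatnonzero(screening.q_value <= q_cutoff)
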