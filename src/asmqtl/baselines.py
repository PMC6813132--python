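"""Comparison methods: per-site beta-binomial regression (``bb``) and a
linear mixed model on M-values (``lmm``).

Both consume the same per-individual counts as the mixed-model
estimators and emit the same ``ModelFit`` schema, so results are
drop-in comparable.  The LMM works on normalized data
M = log2((y + c) / (r - y + c)) and fits M = mu + x*beta + g + eps with
g ~ MVN(0, sigma_g^2 K) by REML, profiling out the scale so only the
variance ratio is optimized (one kinship eigendecomposition is shared
across sites).  The beta-binomial fits, per site, a maximum-likelihood
regression with mean logistic(mu + x*beta) and an intra-class
over-dispersion parameter on (0, 1).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit
from scipy.stats import betabinom, chi2

from .core import KinshipMatrix, PairCounts
from .inference import ModelFit, VarianceComponents, na_fit

BB = "bb"
LMM = "lmm"


def m_values(y: np.ndarray, r: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """M = log2((y + offset) / (r - y + offset)); finite whenever r > 0."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("individuals with r == 0 must be excluded upstream")
    return np.log2((y + offset) / (r - y + offset))


class KinshipEigen:
    """Cached eigendecomposition of a standardized kinship matrix, so
    per-site REML reduces to a one-dimensional profile optimization."""

    def __init__(self, K: KinshipMatrix):
        self.K = K
        w, U = np.linalg.eigh(K.values)
        self.w = np.clip(w, 0.0, None)
        self.U = U


def _lmm_profile_reml(lam: float, wt: np.ndarray, yr: np.ndarray,
                      Xr: np.ndarray):
    """Profile REML log-likelihood pieces at variance ratio lam =
    sigma_g^2 / sigma_eps^2, in the kinship eigenbasis."""
    v = lam * wt + 1.0          # scaled marginal variances
    Xv = Xr / v[:, None]
    XtVX = Xr.T @ Xv
    XtVy = Xv.T @ yr
    beta = np.linalg.solve(XtVX, XtVy)
    resid = yr - Xr @ beta
    n, p = Xr.shape
    rss = resid @ (resid / v)
    sigma2 = rss / (n - p)
    ll = -0.5 * (np.sum(np.log(v)) + np.linalg.slogdet(XtVX)[1]
                 + (n - p) * np.log(rss))
    return ll, beta, sigma2, XtVX


def fit_lmm_mvalues(M: np.ndarray, genotype: np.ndarray,
                    K: KinshipMatrix | KinshipEigen,
                    n_het: int = 0) -> ModelFit:
    """REML linear mixed model on M-values with a single kinship
    variance component; Wald chi-square(1) test on the genotype dosage
    effect.  Dosage is used on the 0..2 scale internally and the
    reported effect is rescaled to the per-allele scale (beta per
    alternate allele = dosage effect), matching the other estimators."""
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(K)
    M = np.asarray(M, dtype=float)
    x = np.asarray(genotype, dtype=float)
    n = len(M)
    if n < 10:
        return na_fit(LMM, n, n_het, "too_few_individuals")
    if np.ptp(x) == 0:
        return na_fit(LMM, n, n_het, "monomorphic")
    X = np.column_stack([np.ones(n), x / 2.0])   # per-allele coding
    yr = eig.U.T @ M
    Xr = eig.U.T @ X

    def neg_ll(log_lam):
        return -_lmm_profile_reml(np.exp(log_lam), eig.w, yr, Xr)[0]

    opt = minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(opt.x))
    ll, beta, sigma2, XtVX = _lmm_profile_reml(lam, eig.w, yr, Xr)
    covb = np.linalg.inv(XtVX) * sigma2
    se = float(np.sqrt(covb[1, 1]))
    if not np.isfinite(se) or se <= 0:
        return na_fit(LMM, n, n_het, "degenerate_se")
    wald = (beta[1] / se) ** 2
    vc = VarianceComponents(sigma_g2=lam * sigma2, sigma_u2=0.0,
                            sigma_e2=2.0 * sigma2)
    return ModelFit(method=LMM, mu_hat=float(beta[0]), beta_hat=float(beta[1]),
                    se_beta=se, wald_stat=float(wald),
                    p_value=float(chi2.sf(wald, 1)), vc=vc,
                    n_individuals=n, n_het=n_het, converged=bool(opt.success),
                    n_iter=int(opt.nfev))


def fit_lmm_pair(pc: PairCounts, K: KinshipMatrix | KinshipEigen,
                 offset: float = 0.5,
                 x_override: np.ndarray | None = None) -> ModelFit:
    pc = pc.drop_uninformative()
    n_het = int(np.sum(pc.genotype == 1))
    x = pc.genotype if x_override is None else np.asarray(x_override, float)
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(K)
    if pc.n != eig.K.n or list(eig.K.ids) != list(pc.individual_ids):
        eig = KinshipEigen(eig.K.subset(pc.individual_ids))
    return fit_lmm_mvalues(m_values(pc.y_total, pc.r_total, offset), x, eig,
                           n_het=n_het)


# ---------------------------------------------------------------------------
# beta-binomial regression
# ---------------------------------------------------------------------------

def _bb_nll(theta, x, y, r):
    mu, beta, s_logit = theta
    p = np.clip(expit(mu + x * beta), 1e-8, 1 - 1e-8)
    s = np.clip(expit(s_logit), 1e-8, 1 - 1e-8)
    k = (1 - s) / s
    return -np.sum(betabinom.logpmf(y, r, p * k, (1 - p) * k))


def _num_hessian(f, theta, h=1e-4):
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * h * h)
    return H


def fit_beta_binomial(y: np.ndarray, r: np.ndarray, genotype: np.ndarray,
                      n_het: int = 0) -> ModelFit:
    """Per-site beta-binomial ML: y_i ~ BetaBin(r_i) with mean
    logistic(mu + x_i beta) (x the per-allele dosage genotype/2) and
    intra-class over-dispersion s in (0,1); Wald test from the observed
    information.  When s collapses to the boundary the fit degrades to
    a plain binomial logistic regression and is flagged."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    x = np.asarray(genotype, dtype=float) / 2.0
    n = len(y)
    if n < 10:
        return na_fit(BB, n, n_het, "too_few_individuals")
    if np.ptp(x) == 0:
        return na_fit(BB, n, n_het, "monomorphic")
    from .inference import _glm_init
    coef0 = _glm_init(x, y, r)
    theta0 = np.array([coef0[0], coef0[1], np.log(0.05 / 0.95)])
    opt = minimize(_bb_nll, theta0, args=(x, y, r), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    theta = opt.x
    note = ""
    H = _num_hessian(lambda t: _bb_nll(t, x, y, r), theta)
    try:
        cov = np.linalg.inv(H)
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se = np.nan
    if not np.isfinite(se) or se <= 0:
        # boundary over-dispersion: fall back to binomial GLM information
        note = "boundary_overdispersion_glm_fallback"
        pi = np.clip(expit(theta[0] + x * theta[1]), 1e-8, 1 - 1e-8)
        w = r * pi * (1 - pi)
        X = np.column_stack([np.ones(n), x])
        cov = np.linalg.inv((X.T * w) @ X)
        se = float(np.sqrt(cov[1, 1]))
    wald = (theta[1] / se) ** 2
    s = float(expit(theta[2]))
    vc = VarianceComponents(sigma_g2=0.0, sigma_u2=0.0, sigma_e2=s)
    return ModelFit(method=BB, mu_hat=float(theta[0]),
                    beta_hat=float(theta[1]), se_beta=se,
                    wald_stat=float(wald), p_value=float(chi2.sf(wald, 1)),
                    vc=vc, n_individuals=n, n_het=n_het,
                    converged=bool(opt.success), n_iter=int(opt.nit),
                    note=note)


def fit_bb_pair(pc: PairCounts, x_override: np.ndarray | None = None) -> ModelFit:
    pc = pc.drop_uninformative()
    n_het = int(np.sum(pc.genotype == 1))
    x = pc.genotype if x_override is None else np.asarray(x_override, float)
    return fit_beta_binomial(pc.y_total, pc.r_total, x, n_het=n_het)
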