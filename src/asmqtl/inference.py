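"""Model fitting: PQL for the binomial mixed model, and the Wald test.

Three estimators share the same machinery and differ only in the design:

* ``joint``      — allele rows for phase-assignable heterozygotes plus
                   collapsed rows for homozygotes (ASM-assisted mapping);
* ``ind``        — collapsed rows for everyone (individual-level counts
                   only, heterozygote covariate 0.5);
* ``allele``     — allele rows of heterozygotes only (pure ASM analysis).

Fitting alternates a working linearization of the binomial likelihood
with average-information REML updates of the three variance components
(sigma_g^2, sigma_u^2, sigma_e^2) and a GLS update of the fixed effects
(mu, beta).  The per-allele genotype effect beta is tested with a Wald
chi-square on one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2

from .core import (DesignRow, KinshipMatrix, PairCounts, VarianceComponents,
                   collapse_homozygote_approx)

JOINT = "joint"
IND = "ind"
ALLELE = "allele"

MIN_HETS_ALLELE = 5           # allele-only analysis needs >= 5 heterozygotes
_VC_FLOOR = 1e-6
_PI_CLAMP = 1e-6


class InsufficientHetsError(ValueError):
    pass


class DegenerateFitError(RuntimeError):
    pass


@dataclass
class ModelFit:
    method: str
    mu_hat: float
    beta_hat: float
    se_beta: float
    wald_stat: float
    p_value: float
    vc: VarianceComponents
    n_individuals: int
    n_het: int
    converged: bool
    n_iter: int
    note: str = ""

    @property
    def h2_hat(self) -> float:
        return self.vc.h2


def na_fit(method: str, n: int, n_het: int, note: str) -> ModelFit:
    """Placeholder result for pairs that cannot be analysed (e.g. a
    monomorphic genotype); keeps batch runs going."""
    return ModelFit(method=method, mu_hat=np.nan, beta_hat=np.nan,
                    se_beta=np.nan, wald_stat=np.nan, p_value=np.nan,
                    vc=VarianceComponents(np.nan, np.nan, np.nan),
                    n_individuals=n, n_het=n_het, converged=False,
                    n_iter=0, note=note)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(pc: PairCounts, use_individual: bool = True,
                 use_allele: bool = True,
                 x_override: np.ndarray | None = None) -> list[DesignRow]:
    """Assemble observation rows for one SNP-CpG pair.

    ``x_override`` replaces the per-individual genotype dosage with a
    residualized (possibly non-integer) dosage; the within-heterozygote
    allele contrast of 1 is preserved by shifting both allele rows.
    Rows with zero total reads are dropped.
    """
    if not (use_individual or use_allele):
        raise ValueError("at least one of use_individual/use_allele")
    pc = pc.drop_uninformative()
    geno = pc.genotype if x_override is None else np.asarray(x_override, float)
    allele_ok = pc.has_allele_data()
    n_het = int(np.sum(pc.genotype == 1))
    if use_allele and not use_individual and int(allele_ok.sum()) < MIN_HETS_ALLELE:
        raise InsufficientHetsError(
            f"allele-only analysis needs >= {MIN_HETS_ALLELE} heterozygotes "
            f"with phase-assignable reads, got {int(allele_ok.sum())}")
    rows: list[DesignRow] = []
    for i in range(pc.n):
        het_with_alleles = bool(allele_ok[i])
        if use_allele and het_with_alleles:
            # allele-scale covariates: dose/2 -/+ 1/2 keeps the within-
            # individual contrast at exactly 1 after residualization
            x_ref = geno[i] / 2.0 - 0.5
            x_alt = geno[i] / 2.0 + 0.5
            for col, x in ((0, x_ref), (1, x_alt)):
                r = pc.r_allele[i, col]
                if r > 0:
                    rows.append(DesignRow(individual_index=i, x=float(x),
                                          y=float(pc.y_allele[i, col]),
                                          r=float(r), residual_scale=1.0,
                                          is_allele=True))
        elif use_individual:
            rows.append(collapse_homozygote_approx(
                i, geno[i], pc.y_total[i], pc.r_total[i],
                allow_het=True))
    return rows


# ---------------------------------------------------------------------------
# PQL fitting
# ---------------------------------------------------------------------------

def _glm_init(x, y, r, max_iter=25):
    """Binomial logistic IRLS for (mu, beta); cheap start values."""
    X = np.column_stack([np.ones_like(x), x])
    coef = np.zeros(2)
    ratio = np.clip((y + 0.5) / (r + 1.0), 0.01, 0.99)
    coef[0] = np.log(ratio.mean() / (1 - ratio.mean()))
    for _ in range(max_iter):
        eta = X @ coef
        pi = expit(eta)
        w = r * pi * (1 - pi) + 1e-10
        z = eta + (y - r * pi) / w
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - coef)) < 1e-8:
            coef = new
            break
        coef = new
    return coef


def fit_pql(rows: list[DesignRow], K: KinshipMatrix,
            tol: float = 1e-5, max_iter: int = 200,
            method: str = JOINT, n_het: int | None = None,
            fix_vc: tuple[float, float, float] | None = None) -> ModelFit:
    """Fit the binomial mixed model by penalized quasi-likelihood.

    Each outer iteration forms the working response
    z = eta + (y - r*pi) / (r*pi*(1-pi)) with weights w = r*pi*(1-pi),
    takes one average-information REML step for the variance components
    under V = sg2*Kd + su2*B + se2*D + W^-1 (Kd, B the kinship and
    same-individual matrices expanded to rows, D = diag(residual_scale)),
    and updates (mu, beta) by GLS.  Components are floored at 1e-6;
    non-convergence returns the last iterate flagged.
    """
    m = len(rows)
    x = np.array([rw.x for rw in rows])
    y = np.array([rw.y for rw in rows])
    r = np.array([rw.r for rw in rows])
    d = np.array([rw.residual_scale for rw in rows])
    idx = np.array([rw.individual_index for rw in rows])
    n_ind = len(np.unique(idx))
    if n_het is None:
        n_het = int(np.sum(np.bincount(idx, weights=np.array(
            [rw.is_allele for rw in rows], dtype=float)) > 0))
    if np.ptp(x) == 0 or m < 3:
        return na_fit(method, n_ind, n_het, "monomorphic_or_too_few_rows")

    Kd = K.values[np.ix_(idx, idx)]
    B = (idx[:, None] == idx[None, :]).astype(float)
    D = np.diag(d)
    X = np.column_stack([np.ones(m), x])
    parts = (Kd, B, D)

    coef = _glm_init(x, y, r)
    if fix_vc is not None:
        sig = np.maximum(np.asarray(fix_vc, dtype=float), _VC_FLOOR)
    else:
        sig = np.array([0.1, 0.1, 0.1])
    eta = X @ coef
    converged = False
    note = ""
    it = 0
    for it in range(1, max_iter + 1):
        pi = np.clip(expit(eta), _PI_CLAMP, 1 - _PI_CLAMP)
        w = r * pi * (1 - pi)
        w = np.maximum(w, 1e-8)
        z = eta + (y - r * pi) / w

        V = sig[0] * Kd + sig[1] * B + sig[2] * D + np.diag(1.0 / w)
        try:
            cf = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return na_fit(method, n_ind, n_het, "singular_V")
        Vi = cho_solve(cf, np.eye(m), check_finite=False)
        ViX = Vi @ X
        XtViX = X.T @ ViX
        try:
            XtViX_inv = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return na_fit(method, n_ind, n_het, "singular_working_system")
        new_coef = XtViX_inv @ (ViX.T @ z)
        P = Vi - ViX @ XtViX_inv @ ViX.T
        Pz = P @ z

        if fix_vc is None:
            # average-information REML step on (sg2, su2, se2)
            VkPz = [pk @ Pz for pk in parts]
            score = np.array([
                -0.5 * (np.sum(P * pk) - Pz @ vkpz)
                for pk, vkpz in zip(parts, VkPz)])
            AI = 0.5 * np.array([[vj @ P @ vk for vk in VkPz] for vj in VkPz])
            new_sig = _vc_step(sig, score, AI)
        else:
            new_sig = sig

        delta = max(np.max(np.abs(new_coef - coef)),
                    np.max(np.abs(new_sig - sig)))
        coef, sig = new_coef, new_sig
        # BLUP update of the linear predictor: with GLS fixed effects,
        # X*coef + R V^-1 (z - X*coef) simplifies to z - (Pz)/w
        eta = z - Pz / w
        if delta < tol:
            converged = True
            break
    if not converged:
        note = "max_iter_reached"

    se_beta = float(np.sqrt(max(XtViX_inv[1, 1], 0.0)))
    beta = float(coef[1])
    if se_beta <= 0 or not np.isfinite(se_beta):
        return na_fit(method, n_ind, n_het, "degenerate_se")
    wald = (beta / se_beta) ** 2
    p = float(chi2.sf(wald, df=1))
    vc = VarianceComponents(*[float(s) for s in sig])
    return ModelFit(method=method, mu_hat=float(coef[0]), beta_hat=beta,
                    se_beta=se_beta, wald_stat=float(wald), p_value=p,
                    vc=vc, n_individuals=n_ind, n_het=n_het,
                    converged=converged, n_iter=it, note=note)


def _vc_step(sig, score, AI, floor=_VC_FLOOR):
    """One damped AI-REML update with a gradient fallback."""
    try:
        step = np.linalg.solve(AI + 1e-8 * np.eye(3), score)
    except np.linalg.LinAlgError:
        step = score / max(np.trace(AI), 1.0)
    # step-halve until all components stay above a fraction of the floor
    for _ in range(30):
        cand = sig + step
        if np.all(cand > -floor):
            break
        step *= 0.5
    return np.maximum(sig + step, floor)


def wald_test(fit: ModelFit) -> float:
    """p = upper chi-square(1) tail of (beta/se)^2."""
    if not np.isfinite(fit.se_beta) or fit.se_beta <= 0:
        raise DegenerateFitError("standard error must be positive")
    return float(chi2.sf((fit.beta_hat / fit.se_beta) ** 2, df=1))


# ---------------------------------------------------------------------------
# one-stop per-pair fit
# ---------------------------------------------------------------------------

def fit_pair(pc: PairCounts, K: KinshipMatrix, method: str = JOINT,
             x_override: np.ndarray | None = None,
             tol: float = 1e-5, max_iter: int = 200) -> ModelFit:
    """Fit one SNP-CpG pair with the requested estimator."""
    use_ind = method in (JOINT, IND)
    use_all = method in (JOINT, ALLELE)
    if method == IND:
        use_all = False
    pc2 = pc.drop_uninformative()
    n_het = int(np.sum(pc2.genotype == 1))
    try:
        rows = build_design(pc2, use_individual=use_ind, use_allele=use_all,
                            x_override=x_override)
    except InsufficientHetsError as exc:
        return na_fit(method, pc2.n, n_het, str(exc))
    Ksub = K.subset(pc2.individual_ids) if K.n != pc2.n or \
        list(K.ids) != list(pc2.individual_ids) else K
    return fit_pql(rows, Ksub, tol=tol, max_iter=max_iter, method=method,
                   n_het=n_het)
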