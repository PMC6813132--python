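"""Synthetic bisulfite-sequencing study generator.

Emulates a population mQTL study: unrelated individuals genotyped at a
panel of SNPs (for the kinship matrix) plus one focal SNP per CpG site;
negative-binomial total read depths; a Beta(10,10) split of reads between
alleles; and allele-level methylated counts drawn from the logit-normal
binomial model with a polygenic effect (covariance proportional to K),
an individual-level environmental effect shared between alleles, and an
allele-level residual.  Heterozygotes keep their per-allele counts;
homozygotes are collapsed to individual-level totals.

Baseline generating conditions: n = 100, h2 = 0.3, pi0 = 0.5, MAF bin
centred on 0.3, rho = 0, TR = 20, phi = 3, sigma2 = 0.7, PVE = 0.1, with
10% of SNP-CpG pairs carrying a true genotype effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .core import KinshipMatrix, PairCounts, standardize_kinship

MAF_BINS = {
    0.1: (0.05, 0.15),
    0.3: (0.25, 0.35),
    0.5: (0.45, 0.50),
}


@dataclass
class SimConfig:
    """Knobs of the simulation study (all on the latent logit scale
    unless stated otherwise)."""

    n: int = 100                 # individuals
    h2: float = 0.3              # background heritability
    sigma2: float = 0.7          # total over-dispersion variance
    rho: float = 0.0             # shared-environment proportion
    maf: float = 0.3             # minor-allele-frequency bin centre
    tr: float = 20.0             # mean total reads per site
    phi: float = 3.0             # NB dispersion (var = TR + TR^2/phi)
    pi0: float = 0.5             # baseline methylation level
    pve: float = 0.1             # variance explained by the focal SNP
    n_sites: int = 10_000        # SNP-CpG pairs per study
    prop_true: float = 0.1       # fraction of pairs with beta != 0
    beta_shape_a: float = 10.0   # allele read-split Beta shapes
    beta_shape_b: float = 10.0
    n_snps_kinship: int = 1_000  # panel size behind the GRM
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must be in [0, 1)")
        if not (0 <= self.rho <= 1):
            raise ValueError("rho must be in [0, 1]")
        if not (0 <= self.pve < 1):
            raise ValueError("pve must be in [0, 1)")
        if self.pve + self.h2 >= 1:
            raise ValueError("need pve + h2 < 1")
        if self.tr <= 0 or self.phi <= 0:
            raise ValueError("TR and phi must be positive")
        if self.maf not in MAF_BINS:
            raise ValueError(f"maf bin centre must be one of {sorted(MAF_BINS)}")


@dataclass
class SimulatedSite:
    counts: PairCounts
    is_mqtl: bool
    beta_true: float
    latent: np.ndarray | None = None   # (n, 2) lambda_il, for diagnostics


def simulate_genotypes(n: int, p: int, maf_bin: float | None,
                       seed: int | np.random.Generator):
    """Genotype panel (n x p, dosages 0/1/2) and its standardized GRM.

    Each SNP's allele frequency is uniform in the requested MAF bin, or
    uniform on (0.05, 0.5) when ``maf_bin`` is None (kinship panel).
    The GRM is the usual centred/scaled dosage cross-product.
    """
    if p < 100:
        raise ValueError("need p >= 100 SNPs for a stable GRM")
    rng = np.random.default_rng(seed)
    if maf_bin is None:
        freqs = rng.uniform(0.05, 0.5, size=p)
    else:
        lo, hi = MAF_BINS[maf_bin]
        freqs = rng.uniform(lo, hi, size=p)
    G = rng.binomial(2, freqs, size=(n, p)).astype(float)
    W = (G - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))
    K = KinshipMatrix([f"ind{i}" for i in range(n)], W @ W.T / p)
    return G, standardize_kinship(K)


def simulate_focal_snp(n: int, maf_bin: float, rng: np.random.Generator):
    lo, hi = MAF_BINS[maf_bin]
    f = rng.uniform(lo, hi)
    return rng.binomial(2, f, size=n).astype(float)


def simulate_reads(cfg: SimConfig, n: int, rng: np.random.Generator):
    """Total reads ~ NB(mean TR, dispersion phi); allele split via
    q ~ Beta(a, b) and r1 ~ Bin(r, q)."""
    # NB with mean TR and var TR + TR^2/phi: gamma-Poisson mixture
    lam = rng.gamma(shape=cfg.phi, scale=cfg.tr / cfg.phi, size=n)
    r = rng.poisson(lam)
    q = rng.beta(cfg.beta_shape_a, cfg.beta_shape_b, size=n)
    r1 = rng.binomial(r, q)
    return r, r1, r - r1, q


def genetic_variance_coefficient(cfg: SimConfig) -> float:
    """Coefficient c with g ~ MVN(0, c*K):
    c = (1+rho) h2 sigma2 / (2 + (rho-1) h2)."""
    return (1 + cfg.rho) * cfg.h2 * cfg.sigma2 / (2 + (cfg.rho - 1) * cfg.h2)


def simulate_env_effects(cfg: SimConfig, n: int, rng: np.random.Generator,
                         pve: float | None = None) -> np.ndarray:
    """Per-individual (u + e1, u + e2) pairs, bivariate normal with
    variance (1-pve-h2)*sigma2 and correlation rho."""
    if pve is None:
        pve = cfg.pve
    if cfg.pve + cfg.h2 >= 1:
        raise ValueError("need pve + h2 < 1")
    v = (1 - pve - cfg.h2) * cfg.sigma2
    cov = v * np.array([[1.0, cfg.rho], [cfg.rho, 1.0]])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    return rng.standard_normal((n, 2)) @ L.T


def sigma_b_from_pve(cfg: SimConfig, x: np.ndarray) -> float:
    """Effect-size variance: sigma_b^2 = PVE*sigma2 / ((1-PVE)*V(x)),
    V(x) the sample variance of the genotype dosages."""
    vx = float(np.var(x, ddof=1))
    if vx <= 0:
        raise ValueError("monomorphic genotype vector")
    return cfg.pve * cfg.sigma2 / ((1 - cfg.pve) * vx)


def simulate_site(cfg: SimConfig, x: np.ndarray, K: KinshipMatrix,
                  is_mqtl: bool, rng: np.random.Generator,
                  chol_K: np.ndarray | None = None,
                  keep_latent: bool = False,
                  pair_id: str = "pair") -> SimulatedSite:
    """One SNP-CpG pair: latent logit(pi_il) = logit(pi0) + x_il*beta +
    g_i + u_i + e_il, then y_il ~ Bin(r_il, pi_il)."""
    n = len(x)
    c = genetic_variance_coefficient(cfg)
    if chol_K is None:
        chol_K = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
    g = np.sqrt(c) * (chol_K @ rng.standard_normal(n))
    env = simulate_env_effects(cfg, n, rng, pve=cfg.pve if is_mqtl else 0.0)
    if is_mqtl:
        beta = rng.normal(0.0, np.sqrt(sigma_b_from_pve(cfg, x)))
    else:
        beta = 0.0
    # allele genotypes: hets carry (0, 1); homozygotes (0,0) or (1,1)
    x_al = np.column_stack([(x == 2).astype(float), (x >= 1).astype(float)])
    lam = logit(cfg.pi0) + x_al * beta + g[:, None] + env
    pi = expit(lam)
    r, r1, r2, _ = simulate_reads(cfg, n, rng)
    y1 = rng.binomial(r1, pi[:, 0])
    y2 = rng.binomial(r2, pi[:, 1])
    het = x == 1
    y_allele = np.full((n, 2), np.nan)
    r_allele = np.full((n, 2), np.nan)
    y_allele[het, 0], y_allele[het, 1] = y1[het], y2[het]
    r_allele[het, 0], r_allele[het, 1] = r1[het], r2[het]
    pc = PairCounts(pair_id=pair_id, individual_ids=list(K.ids),
                    genotype=x, y_total=(y1 + y2).astype(float),
                    r_total=r.astype(float),
                    y_allele=y_allele, r_allele=r_allele)
    return SimulatedSite(counts=pc.drop_uninformative(), is_mqtl=is_mqtl,
                         beta_true=float(beta),
                         latent=lam if keep_latent else None)


def simulate_study(cfg: SimConfig, keep_latent: bool = False):
    """A full study: kinship from a fresh genotype panel, then
    ``n_sites`` SNP-CpG pairs with ``prop_true`` of them true mQTL.

    Returns (sites, K).  Reproducible for a fixed cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    _, K = simulate_genotypes(cfg.n, cfg.n_snps_kinship, None, rng)
    chol_K = np.linalg.cholesky(K.values + 1e-10 * np.eye(cfg.n))
    n_true = int(round(cfg.n_sites * cfg.prop_true))
    sites = []
    for s in range(cfg.n_sites):
        is_mqtl = s < n_true
        x = simulate_focal_snp(cfg.n, cfg.maf, rng)
        while np.ptp(x) == 0:      # resample monomorphic draws
            x = simulate_focal_snp(cfg.n, cfg.maf, rng)
        sites.append(simulate_site(cfg, x, K, is_mqtl, rng,
                                   chol_K=chol_K, keep_latent=keep_latent,
                                   pair_id=f"pair{s:05d}"))
    return sites, K


def empirical_h2_decomposition(cfg: SimConfig, n_sites: int = 2000,
                               seed: int | None = None) -> dict:
    """Monte-Carlo variance decomposition of the latent methylation level.

    Reports the share of across-individual latent variance attributable
    to the polygenic term versus the environmental terms under the
    generating model, to make the heritability bookkeeping measurable:
    the generating coefficient and the model's h2 definition use
    different environmental-variance conventions, so the realized
    decomposition need not equal the nominal h2 exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    c = genetic_variance_coefficient(cfg)
    var_g = []
    var_env = []
    for _ in range(n_sites):
        env = simulate_env_effects(cfg, cfg.n, rng, pve=0.0)
        g = np.sqrt(c) * rng.standard_normal(cfg.n)
        lam_bar = g + env.mean(axis=1)     # individual-level latent mean
        var_g.append(np.var(g, ddof=1))
        var_env.append(np.var(lam_bar - g, ddof=1))
    var_g, var_env = float(np.mean(var_g)), float(np.mean(var_env))
    sigma_u2 = cfg.rho * (1 - cfg.h2) * cfg.sigma2
    sigma_e2 = (1 - cfg.rho) * (1 - cfg.h2) * cfg.sigma2
    h2_model = c / (c + sigma_u2 + 0.5 * sigma_e2)
    return {
        "coefficient": c,
        "var_genetic": var_g,
        "var_env_individual": var_env,
        "h2_empirical": var_g / (var_g + var_env),
        "h2_model_formula": h2_model,
        "h2_nominal": cfg.h2,
    }
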