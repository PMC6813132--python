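"""Probabilistic core of the ASM-assisted mQTL model.

Methylation counts are modelled at the allele level: the methylated read
count of allele ``l`` in individual ``i`` is Binomial(r_il, pi_il) with

    logit(pi_il) = mu + x_il * beta + g_i + u_i + e_il

where ``x_il`` is the allele genotype (0 = reference, 1 = alternate),
``g`` is a polygenic effect with covariance sigma_g^2 * K (K the
standardized kinship matrix), ``u_i`` an individual-level environmental
effect shared by both alleles, and ``e_il`` an independent allele-level
residual.  Allele-level counts are observable only in heterozygotes; for
homozygotes the two alleles are collapsed into a single binomial
observation whose residual variance is halved (averaging two independent
allele residuals).  The background heritability of the latent methylation
level is

    h^2 = sigma_g^2 / (sigma_g^2 + sigma_u^2 + sigma_e^2 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import binom


class InvalidKinshipError(ValueError):
    """Kinship matrix is not square/symmetric or has non-positive trace."""


class DomainError(ValueError):
    """Count arguments outside their valid domain (e.g. y > r)."""


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------

@dataclass
class PairCounts:
    """Observed counts for one SNP-CpG pair.

    Per-individual totals (``y_total``, ``r_total``) are always present.
    Per-allele counts (``y_allele``, ``r_allele``, shape (n, 2), columns =
    reference / alternate allele) are present only for heterozygotes whose
    reads are phase-assignable; rows for other individuals are NaN/absent.
    """

    pair_id: str
    individual_ids: list
    genotype: np.ndarray          # 0/1/2 alt-allele dosage, NaN = missing
    y_total: np.ndarray
    r_total: np.ndarray
    y_allele: np.ndarray | None = None   # (n, 2) float, NaN where absent
    r_allele: np.ndarray | None = None
    snp_id: str | None = None
    cpg_id: str | None = None
    chrom: str | None = None
    pos_snp: int | None = None
    pos_cpg: int | None = None

    def __post_init__(self):
        self.genotype = np.asarray(self.genotype, dtype=float)
        self.y_total = np.asarray(self.y_total, dtype=float)
        self.r_total = np.asarray(self.r_total, dtype=float)
        if self.y_allele is not None:
            self.y_allele = np.asarray(self.y_allele, dtype=float)
            self.r_allele = np.asarray(self.r_allele, dtype=float)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def has_allele_data(self) -> np.ndarray:
        """Boolean mask of individuals with usable per-allele counts."""
        if self.r_allele is None:
            return np.zeros(self.n, dtype=bool)
        return np.isfinite(self.r_allele).all(axis=1) & (self.genotype == 1)

    def validate(self) -> None:
        if np.nanmin(self.y_total) < 0 or np.any(self.y_total > self.r_total):
            raise DomainError(f"{self.pair_id}: need 0 <= y <= r")
        mask = self.has_allele_data()
        if mask.any():
            ya = self.y_allele[mask]
            ra = self.r_allele[mask]
            if np.any(ya < 0) or np.any(ya > ra):
                raise DomainError(f"{self.pair_id}: allele counts out of range")
            if not np.allclose(ya.sum(axis=1), self.y_total[mask]):
                raise DomainError(f"{self.pair_id}: allele y do not sum to total")
            if not np.allclose(ra.sum(axis=1), self.r_total[mask]):
                raise DomainError(f"{self.pair_id}: allele r do not sum to total")

    def drop_uninformative(self) -> "PairCounts":
        """Remove individuals with zero total reads or missing genotype."""
        keep = (self.r_total > 0) & np.isfinite(self.genotype)
        if keep.all():
            return self
        return PairCounts(
            pair_id=self.pair_id,
            individual_ids=[v for v, k in zip(self.individual_ids, keep) if k],
            genotype=self.genotype[keep],
            y_total=self.y_total[keep],
            r_total=self.r_total[keep],
            y_allele=None if self.y_allele is None else self.y_allele[keep],
            r_allele=None if self.r_allele is None else self.r_allele[keep],
            snp_id=self.snp_id, cpg_id=self.cpg_id, chrom=self.chrom,
            pos_snp=self.pos_snp, pos_cpg=self.pos_cpg,
        )


@dataclass
class KinshipMatrix:
    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidKinshipError("kinship matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise InvalidKinshipError("id list does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-8):
            raise InvalidKinshipError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, ids) -> "KinshipMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[v] for v in ids])
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_u2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        denom = self.sigma_g2 + self.sigma_u2 + 0.5 * self.sigma_e2
        if denom <= 0:
            return 0.0
        return float(np.clip(self.sigma_g2 / denom, 0.0, 1.0))


@dataclass
class DesignRow:
    """One observation row: an allele of a heterozygote, or a collapsed
    homozygote (residual variance sigma_e^2 * residual_scale)."""

    individual_index: int
    x: float
    y: float
    r: float
    residual_scale: float = 1.0     # 1 for allele rows, 0.5 for collapsed
    is_allele: bool = False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def standardize_kinship(K: KinshipMatrix, psd_tol: float = -1e-8) -> KinshipMatrix:
    """Rescale K so that the mean of its diagonal equals one.

    Eigenvalues below ``psd_tol`` raise; those in [psd_tol, 0) are clipped
    to zero so the result is positive semi-definite.
    """
    v = np.array(K.values, dtype=float)
    tr = np.trace(v)
    if tr <= 0:
        raise InvalidKinshipError("kinship trace must be positive")
    v *= K.n / tr
    w = np.linalg.eigvalsh(v)
    if w[0] < psd_tol * max(1.0, abs(w[-1])):
        # repair by clipping negative eigenvalues at zero
        w, q = np.linalg.eigh(v)
        w = np.clip(w, 0.0, None)
        v = (q * w) @ q.T
        v = 0.5 * (v + v.T)
        tr = np.trace(v)
        v *= K.n / tr
    return KinshipMatrix(list(K.ids), v)


def linear_predictor(mu: float, beta: float, row: DesignRow,
                     g_i: float, u_i: float, e_row: float) -> float:
    """lambda = mu + x*beta + g_i + u_i + e_row; methylation prob = expit."""
    return mu + row.x * beta + g_i + u_i + e_row


def exact_homozygote_pmf(y: int, r: int, pi1: float, pi2: float) -> float:
    """Exact P(y | r, pi1, pi2) for a collapsed homozygote.

    The total count is the sum over the two (unobserved) alleles: the read
    split r1 ~ Bin(r, 0.5), then y1 ~ Bin(r1, pi1), y2 ~ Bin(r - r1, pi2).
    Evaluated by the full double sum; O(r^2), guarded at r <= 10,000.
    """
    if not (0 <= y <= r):
        raise DomainError("need 0 <= y <= r")
    if r > 10_000:
        raise DomainError("enumeration guard: r <= 10,000")
    return float(exact_homozygote_dist(int(r), pi1, pi2)[int(y)])


def exact_homozygote_dist(r: int, pi1: float, pi2: float) -> np.ndarray:
    """Full exact pmf over y = 0..r (vector of length r+1)."""
    split = binom.pmf(np.arange(r + 1), r, 0.5)
    out = np.zeros(r + 1)
    for r1 in range(r + 1):
        p1 = binom.pmf(np.arange(r1 + 1), r1, pi1)
        p2 = binom.pmf(np.arange(r - r1 + 1), r - r1, pi2)
        out += split[r1] * np.convolve(p1, p2)
    return out


def collapse_homozygote_approx(individual_index: int, genotype: float,
                               y: float, r: float,
                               allow_het: bool = False) -> DesignRow:
    """Represent a homozygote by one binomial row on the allele scale.

    The covariate is genotype/2 so beta keeps its per-allele meaning, and
    the residual variance is sigma_e^2 / 2: the collapsed latent residual
    is the average of two independent allele residuals.  Conditional on
    the two allele probabilities, Bin(r, (pi1+pi2)/2) matches the exact
    collapsed distribution in both mean and variance.

    Heterozygotes are rejected unless ``allow_het`` is set (used for
    heterozygotes whose reads cannot be assigned to alleles, which are
    analysed at the individual level with covariate 0.5).
    """
    if genotype == 1 and not allow_het:
        raise ValueError("collapse_homozygote_approx: heterozygous input")
    return DesignRow(individual_index=individual_index, x=genotype / 2.0,
                     y=y, r=r, residual_scale=0.5, is_allele=False)
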