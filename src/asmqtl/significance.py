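"""Permutation null construction, empirical FDR, and truth-based power.

Parametric p-values from the mixed-model Wald test are not perfectly
calibrated in small samples, so discoveries are declared against an
empirical null built by permuting genotype labels.  Two strategies are
provided: permuting allele/genotype labels across sampling units (each
heterozygote contributes its two alleles as separate units, each
homozygote one unit), and permuting the per-individual count pairs with
a fresh Bin(1/2) re-split of heterozygote alleles (better suited to
larger samples).  For simulations with known truth, power is computed at
a fixed realized false-discovery proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PairCounts
from .inference import DesignRow


@dataclass
class FdrTable:
    thresholds: np.ndarray       # sorted p-value cutoffs
    n_observed: np.ndarray       # observed #{p <= t}
    mean_n_permuted: np.ndarray  # average permuted #{p <= t}
    fdr_hat: np.ndarray          # monotone step-up estimate
    n_permutations: int

    def threshold_at(self, alpha: float) -> float:
        """Largest cutoff with estimated FDR <= alpha (-inf if none)."""
        ok = self.fdr_hat <= alpha
        return float(self.thresholds[ok][-1]) if ok.any() else -np.inf


# ---------------------------------------------------------------------------
# permutation strategies
# ---------------------------------------------------------------------------

def permute_design_labels(rows: list[DesignRow], B: int,
                          seed) -> list[list[DesignRow]]:
    """Permute genotype covariates across sampling units.

    Units are exactly the design rows: the two alleles of each phase-
    assignable heterozygote and each collapsed homozygote.  Counts (y, r)
    and the unit-to-individual assignment stay put; only the x labels
    move, so the multiset of labels is preserved.
    """
    if B < 1:
        raise ValueError("need B >= 1")
    rng = np.random.default_rng(seed)
    xs = np.array([rw.x for rw in rows])
    out = []
    for _ in range(B):
        perm = rng.permutation(len(rows))
        out.append([
            DesignRow(individual_index=rw.individual_index,
                      x=float(xs[j]), y=rw.y, r=rw.r,
                      residual_scale=rw.residual_scale,
                      is_allele=rw.is_allele)
            for rw, j in zip(rows, perm)])
    return out


def permute_labels(pc: PairCounts, B: int, seed,
                   use_individual: bool = True,
                   use_allele: bool = True) -> list[list[DesignRow]]:
    """Label permutation on a pair's design (see permute_design_labels)."""
    from .inference import build_design
    rows = build_design(pc, use_individual=use_individual,
                        use_allele=use_allele)
    return permute_design_labels(rows, B, seed)


def permute_counts_alt(pc: PairCounts, B: int, seed) -> list[PairCounts]:
    """Alternative strategy: permute (y_i, r_i) across individuals,
    keeping genotypes in place; heterozygote allele splits are redrawn
    with Bin(., 1/2) on methylated and unmethylated reads separately
    (so y and r totals are conserved).  Recommended for larger samples
    (roughly n > 150)."""
    if B < 1:
        raise ValueError("need B >= 1")
    rng = np.random.default_rng(seed)
    pc = pc.drop_uninformative()
    n = pc.n
    out = []
    for _ in range(B):
        perm = rng.permutation(n)
        y = pc.y_total[perm].astype(int)
        r = pc.r_total[perm].astype(int)
        het = pc.genotype == 1
        y_allele = np.full((n, 2), np.nan)
        r_allele = np.full((n, 2), np.nan)
        y1 = rng.binomial(y[het], 0.5)
        u1 = rng.binomial(r[het] - y[het], 0.5)
        y_allele[het, 0], y_allele[het, 1] = y1, y[het] - y1
        r_allele[het, 0] = y1 + u1
        r_allele[het, 1] = r[het] - y1 - u1
        out.append(PairCounts(
            pair_id=pc.pair_id, individual_ids=list(pc.individual_ids),
            genotype=pc.genotype.copy(), y_total=y.astype(float),
            r_total=r.astype(float), y_allele=y_allele, r_allele=r_allele,
            snp_id=pc.snp_id, cpg_id=pc.cpg_id))
    return out


# ---------------------------------------------------------------------------
# FDR estimation and power
# ---------------------------------------------------------------------------

def empirical_fdr(p_obs: np.ndarray, p_perm: np.ndarray) -> FdrTable:
    """Empirical FDR at each observed p-value threshold.

    fdr_hat(t) = (mean over permutations of #{p_perm <= t})
                 / max(1, #{p_obs <= t}),
    made monotone non-decreasing in t and capped at 1.  Permuted
    p-values are pooled across pairs (p_perm has shape (B, m)).
    """
    p_obs = np.asarray(p_obs, dtype=float)
    p_perm = np.atleast_2d(np.asarray(p_perm, dtype=float))
    keep = np.isfinite(p_obs)
    p_obs = p_obs[keep]
    B = p_perm.shape[0]
    flat = np.sort(p_perm[np.isfinite(p_perm)])
    thr = np.unique(p_obs)
    n_obs = np.searchsorted(np.sort(p_obs), thr, side="right")
    n_perm = np.searchsorted(flat, thr, side="right") / B
    fdr = n_perm / np.maximum(1, n_obs)
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]   # step-up monotone
    fdr = np.clip(fdr, 0.0, 1.0)
    return FdrTable(thresholds=thr, n_observed=n_obs,
                    mean_n_permuted=n_perm, fdr_hat=fdr, n_permutations=B)


def discoveries_at_fdr(table: FdrTable, p_obs: np.ndarray,
                       alpha: float) -> np.ndarray:
    """Boolean mask of pairs discovered at estimated FDR <= alpha."""
    t = table.threshold_at(alpha)
    return np.asarray(p_obs) <= t


def power_at_fdr(p: np.ndarray, truth: np.ndarray, alpha: float) -> float:
    """Power at a known-truth false-discovery proportion.

    Pairs are ranked by p-value; K is the largest rank whose realized
    FDP (#false in top K / K) is <= alpha, with ties entering together;
    power is the fraction of all true pairs in the top K.  Pairs with
    missing p are ranked last.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_true = int(truth.sum())
    if n_true == 0:
        raise ValueError("power undefined without true sites")
    p = np.where(np.isfinite(p), p, np.inf)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    false_cum = np.cumsum(~truth[order])
    true_cum = np.cumsum(truth[order])
    k = np.arange(1, len(p) + 1)
    fdp = false_cum / k
    # a rank is admissible only if the whole tie group is included
    last_of_tie = np.r_[sorted_p[1:] != sorted_p[:-1], True]
    ok = (fdp <= alpha) & last_of_tie & np.isfinite(sorted_p)
    if not ok.any():
        return 0.0
    K = k[ok][-1]
    return float(true_cum[K - 1] / n_true)
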