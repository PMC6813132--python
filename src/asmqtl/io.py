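"""File formats, covariate residualization, QC filters, CpG-context
annotation and enrichment statistics.

Pair counts travel as a long-format TSV with one row per
(pair, individual); kinship as a whitespace-delimited square matrix
(optionally headed by individual IDs); covariates as a TSV keyed by
individual ID.  CpG islands come in as BED (0-based half-open); pair
coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core import KinshipMatrix, PairCounts

log = logging.getLogger("asmqtl")

PAIRS_COLUMNS = ["pair_id", "snp_id", "cpg_id", "individual_id", "genotype",
                 "y_total", "r_total", "y_ref", "r_ref", "y_alt", "r_alt"]
OPTIONAL_COLUMNS = ["chrom", "pos_snp", "pos_cpg"]

RESULT_COLUMNS = ["pair_id", "method", "n", "n_het", "beta", "se",
                  "sigma_g2", "sigma_u2", "sigma_e2", "h2", "wald",
                  "pvalue", "converged", "note"]


# ---------------------------------------------------------------------------
# pair counts TSV
# ---------------------------------------------------------------------------

def read_pairs_tsv(path, max_reject_frac: float = 0.10) -> list[PairCounts]:
    """Read per-(SNP,CpG)-pair counts; invalid rows are rejected with a
    logged reason, and the whole file errors if >10% of rows fail."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "snp_id": str,
                                            "cpg_id": str,
                                            "individual_id": str})
    missing = [c for c in PAIRS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pairs file missing columns: {missing}")
    n_total = len(df)
    bad = pd.Series(False, index=df.index)

    geno = pd.to_numeric(df["genotype"], errors="coerce")
    ok_geno = geno.isin([0, 1, 2]) | geno.isna()
    _flag(bad, ~ok_geno, "unknown genotype code", df)
    num = {c: pd.to_numeric(df[c], errors="coerce")
           for c in ["y_total", "r_total", "y_ref", "r_ref", "y_alt", "r_alt"]}
    _flag(bad, (num["y_total"] < 0) | (num["y_total"] > num["r_total"]),
          "y_total outside [0, r_total]", df)
    has_allele = num["r_ref"].notna() & num["r_alt"].notna()
    _flag(bad, has_allele & (
        (num["y_ref"] + num["y_alt"] != num["y_total"])
        | (num["r_ref"] + num["r_alt"] != num["r_total"])),
        "allele counts do not sum to totals", df)
    _flag(bad, has_allele & (geno != 1), "allele counts on a homozygote", df)

    if n_total and bad.sum() / n_total > max_reject_frac:
        raise ValueError(
            f"{bad.sum()}/{n_total} rows rejected (> {max_reject_frac:.0%})")
    df = df[~bad]
    out = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        g = pd.to_numeric(grp["genotype"], errors="coerce").to_numpy(float)
        n = len(grp)
        y_allele = np.full((n, 2), np.nan)
        r_allele = np.full((n, 2), np.nan)
        for j, (cy, cr) in enumerate((("y_ref", "r_ref"), ("y_alt", "r_alt"))):
            y_allele[:, j] = pd.to_numeric(grp[cy], errors="coerce")
            r_allele[:, j] = pd.to_numeric(grp[cr], errors="coerce")
        pc = PairCounts(
            pair_id=str(pair_id),
            individual_ids=list(grp["individual_id"]),
            genotype=g,
            y_total=grp["y_total"].to_numpy(float),
            r_total=grp["r_total"].to_numpy(float),
            y_allele=y_allele, r_allele=r_allele,
            snp_id=str(grp["snp_id"].iloc[0]),
            cpg_id=str(grp["cpg_id"].iloc[0]),
            chrom=str(grp["chrom"].iloc[0]) if "chrom" in grp else None,
            pos_snp=int(grp["pos_snp"].iloc[0]) if "pos_snp" in grp else None,
            pos_cpg=int(grp["pos_cpg"].iloc[0]) if "pos_cpg" in grp else None,
        )
        pc.validate()
        out.append(pc)
    return out


def _flag(bad, mask, reason, df):
    mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
    new = mask & ~bad
    if new.any():
        for i in df.index[new][:5]:
            log.warning("row %s rejected: %s", i, reason)
        if new.sum() > 5:
            log.warning("... and %d more rows: %s", new.sum() - 5, reason)
    bad |= mask


def write_pairs_tsv(pairs: list[PairCounts], path) -> None:
    rows = []
    for pc in pairs:
        allele_ok = pc.has_allele_data()
        for i, ind in enumerate(pc.individual_ids):
            rec = {
                "pair_id": pc.pair_id, "snp_id": pc.snp_id or pc.pair_id,
                "cpg_id": pc.cpg_id or pc.pair_id, "individual_id": ind,
                "genotype": int(pc.genotype[i]),
                "y_total": int(pc.y_total[i]), "r_total": int(pc.r_total[i]),
            }
            if allele_ok[i]:
                rec.update(y_ref=int(pc.y_allele[i, 0]),
                           r_ref=int(pc.r_allele[i, 0]),
                           y_alt=int(pc.y_allele[i, 1]),
                           r_alt=int(pc.r_allele[i, 1]))
            else:
                rec.update(y_ref="NA", r_ref="NA", y_alt="NA", r_alt="NA")
            if pc.chrom is not None:
                rec.update(chrom=pc.chrom, pos_snp=pc.pos_snp,
                           pos_cpg=pc.pos_cpg)
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# kinship / covariates
# ---------------------------------------------------------------------------

def read_kinship(path, ids: list | None = None) -> KinshipMatrix:
    """Whitespace-delimited square matrix; first row may carry IDs.
    Without a header, IDs must be supplied (counts-file order)."""
    with open(path) as fh:
        first = fh.readline().split()
    has_header = any(not _is_number(tok) for tok in first)
    if has_header:
        vals = np.loadtxt(path, skiprows=1)
        return KinshipMatrix(first, np.atleast_2d(vals))
    vals = np.atleast_2d(np.loadtxt(path))
    if ids is None:
        ids = [f"ind{i}" for i in range(vals.shape[0])]
    return KinshipMatrix(list(ids), vals)


def write_kinship(K: KinshipMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(str(v) for v in K.ids) + "\n")
        np.savetxt(fh, K.values, fmt="%.10g")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_covariates(path) -> pd.DataFrame:
    """Covariate TSV: individual_id column + numeric columns; missing
    values are imputed by the column mean (flagged in the log)."""
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValueError("covariate file needs an individual_id column")
    df = df.set_index("individual_id")
    df = df.apply(pd.to_numeric, errors="coerce")
    for col in df.columns:
        if df[col].isna().any():
            log.warning("covariate %s: %d missing values imputed by mean",
                        col, int(df[col].isna().sum()))
            df[col] = df[col].fillna(df[col].mean())
    return df


def residualize_genotype(genotype: np.ndarray,
                         covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residual of the genotype dosage on [1, covariates].

    Allele-row covariates are then built as residual/2 -/+ 1/2, which
    keeps the within-heterozygote allele contrast at exactly 1.
    Collinear covariate columns are dropped with a warning.
    """
    x = np.asarray(genotype, dtype=float)
    C = covariates.to_numpy(float) if hasattr(covariates, "to_numpy") \
        else np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = len(x)
    if n <= C.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    Z = np.column_stack([np.ones(n), C])
    q, rmat = np.linalg.qr(Z)
    keep = np.abs(np.diag(rmat)) > 1e-10 * max(1.0, abs(rmat[0, 0]))
    if not keep.all():
        log.warning("dropping %d collinear covariate column(s)",
                    int((~keep).sum()))
        Z = Z[:, keep]
    coef, *_ = np.linalg.lstsq(Z, x, rcond=None)
    return x - Z @ coef


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass
class QcParams:
    min_individuals: int = 20
    extreme_low: float = 0.10
    extreme_high: float = 0.90
    extreme_frac: float = 0.90
    min_mean_depth: float = 5.0
    min_maf: float = 0.05
    max_allele_diff: float = 0.60


def qc_filter(pairs: list[PairCounts], params: QcParams | None = None):
    """Apply the five pair-level QC rules; returns (kept, report).

    Rules: (i) measured in >= min_individuals; (ii) not extreme
    (< 10% or > 90% methylation) in >= 90% of measured individuals;
    (iii) mean read depth >= 5; (iv) SNP MAF >= 0.05 among measured
    individuals; (v) mean reference/alternate allele methylation
    difference across heterozygotes <= 0.6 (mapping-bias guard).
    Order-independent: every rule is evaluated on the input pair.
    """
    params = params or QcParams()
    report = {k: 0 for k in ["n_input", "fail_min_individuals",
                             "fail_extreme_methylation", "fail_mean_depth",
                             "fail_maf", "fail_allele_difference", "n_kept"]}
    kept = []
    for pc0 in pairs:
        report["n_input"] += 1
        pc = pc0.drop_uninformative()
        bad = False
        if pc.n < params.min_individuals:
            report["fail_min_individuals"] += 1
            bad = True
        if pc.n:
            ratio = pc.y_total / pc.r_total
            extreme = (ratio < params.extreme_low) | (ratio > params.extreme_high)
            if extreme.mean() >= params.extreme_frac:
                report["fail_extreme_methylation"] += 1
                bad = True
            if pc.r_total.mean() < params.min_mean_depth:
                report["fail_mean_depth"] += 1
                bad = True
            f = pc.genotype.mean() / 2.0
            if min(f, 1 - f) < params.min_maf:
                report["fail_maf"] += 1
                bad = True
            mask = pc.has_allele_data() & (pc.r_allele > 0).all(axis=1) \
                if pc.r_allele is not None else np.zeros(pc.n, bool)
            if mask.any():
                diff = (pc.y_allele[mask, 0] / pc.r_allele[mask, 0]
                        - pc.y_allele[mask, 1] / pc.r_allele[mask, 1])
                if abs(float(np.mean(diff))) > params.max_allele_diff:
                    report["fail_allele_difference"] += 1
                    bad = True
        if not bad:
            kept.append(pc0)
    report["n_kept"] = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# CpG context annotation + enrichment
# ---------------------------------------------------------------------------

ISLAND, SHORE, SHELF, OPEN_SEA = "island", "shore", "shelf", "open_sea"


def read_islands_bed(path) -> dict[str, np.ndarray]:
    """CpG-island intervals per chromosome (BED: 0-based, half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return {c: g[["start", "end"]].to_numpy(int)
            for c, g in df.groupby("chrom")}


def annotate_cpg_context(chroms, positions,
                         islands: dict[str, np.ndarray]) -> np.ndarray:
    """Category per CpG by distance to the nearest island on the same
    chromosome: 0 -> island, (0, 2000] -> shore, (2000, 4000] -> shelf,
    else open sea.  Positions are 1-based; islands half-open 0-based."""
    out = np.empty(len(positions), dtype=object)
    for i, (chrom, pos) in enumerate(zip(chroms, positions)):
        iv = islands.get(chrom)
        if iv is None or len(iv) == 0:
            if chrom not in islands:
                log.warning("chromosome %s absent from island annotation; "
                            "classified open_sea", chrom)
            out[i] = OPEN_SEA
            continue
        p0 = int(pos) - 1          # 0-based coordinate of the CpG
        inside = (iv[:, 0] <= p0) & (p0 < iv[:, 1])
        if inside.any():
            out[i] = ISLAND
            continue
        dist = np.minimum(np.abs(iv[:, 0] - p0), np.abs(p0 - (iv[:, 1] - 1)))
        d = int(dist.min())
        out[i] = SHORE if d <= 2000 else SHELF if d <= 4000 else OPEN_SEA
    return out


def enrichment_test(is_mcpg: np.ndarray, context: np.ndarray,
                    category: str) -> dict:
    """Fisher exact test of mCpG membership vs a context category, with
    the log2 odds ratio and Woolf 95% CI (0.5 continuity correction when
    any cell is empty)."""
    is_mcpg = np.asarray(is_mcpg, dtype=bool)
    in_cat = np.asarray(context) == category
    if not in_cat.any():
        return {"category": category, "log2_or": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p_value": np.nan, "table": None}
    a = int(np.sum(is_mcpg & in_cat))
    b = int(np.sum(is_mcpg & ~in_cat))
    c = int(np.sum(~is_mcpg & in_cat))
    d = int(np.sum(~is_mcpg & ~in_cat))
    _, p = fisher_exact([[a, b], [c, d]])
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    or_hat = cells[0] * cells[3] / (cells[1] * cells[2])
    se_log = float(np.sqrt(np.sum(1.0 / cells)))
    lo, hi = np.log(or_hat) - 1.96 * se_log, np.log(or_hat) + 1.96 * se_log
    ln2 = np.log(2.0)
    return {"category": category, "log2_or": float(np.log(or_hat) / ln2),
            "ci_low": float(lo / ln2), "ci_high": float(hi / ln2),
            "p_value": float(p), "table": [[a, b], [c, d]]}


def disruption_rate(snp_pos, cpg_pos, is_mcpg) -> dict:
    """Fraction of pairs where the SNP sits on either base of the CpG
    dinucleotide (positions 1-based; CpG position = the C), among mCpG
    vs non-mCpG pairs, with a Fisher exact p."""
    snp_pos = np.asarray(snp_pos, dtype=int)
    cpg_pos = np.asarray(cpg_pos, dtype=int)
    is_mcpg = np.asarray(is_mcpg, dtype=bool)
    disrupted = (snp_pos == cpg_pos) | (snp_pos == cpg_pos + 1)
    a = int(np.sum(disrupted & is_mcpg))
    b = int(np.sum(~disrupted & is_mcpg))
    c = int(np.sum(disrupted & ~is_mcpg))
    d = int(np.sum(~disrupted & ~is_mcpg))
    _, p = fisher_exact([[a, b], [c, d]])
    return {
        "frac_disrupted_mcpg": a / max(1, a + b),
        "frac_disrupted_non_mcpg": c / max(1, c + d),
        "p_value": float(p),
        "n_disrupted": int(disrupted.sum()),
    }


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def fits_to_frame(pair_ids, fits) -> pd.DataFrame:
    rows = []
    for pid, f in zip(pair_ids, fits):
        rows.append({
            "pair_id": pid, "method": f.method, "n": f.n_individuals,
            "n_het": f.n_het, "beta": f.beta_hat, "se": f.se_beta,
            "sigma_g2": f.vc.sigma_g2, "sigma_u2": f.vc.sigma_u2,
            "sigma_e2": f.vc.sigma_e2,
            "h2": f.h2_hat if np.isfinite(f.beta_hat) else np.nan,
            "wald": f.wald_stat, "pvalue": f.p_value,
            "converged": bool(f.converged), "note": f.note or "",
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
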