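"""Convenience driver: simulate a study and fit one or more estimators.

Used by the power/type-I studies and the reproduction script; keeps the
simulation -> fit -> pooled p-value bookkeeping in one place.
"""

from __future__ import annotations

import numpy as np

from .baselines import BB, LMM, KinshipEigen, fit_bb_pair, fit_lmm_pair
from .inference import ALLELE, IND, JOINT, fit_pair
from .significance import power_at_fdr
from .simulate import SimConfig, simulate_study

ALL_METHODS = (JOINT, IND, ALLELE, BB, LMM)


def run_scenario(cfg: SimConfig, methods=(JOINT,)) -> dict:
    """Simulate one study under ``cfg`` and fit each estimator to every
    pair.  Returns {"truth": bool array, "pvalues": {method: array},
    "fits": {method: list of ModelFit}}."""
    sites, K = simulate_study(cfg)
    truth = np.array([s.is_mqtl for s in sites])
    eig = KinshipEigen(K) if LMM in methods else None
    out = {"truth": truth, "pvalues": {}, "fits": {}, "kinship": K,
           "sites": sites}
    for m in methods:
        if m == BB:
            fits = [fit_bb_pair(s.counts) for s in sites]
        elif m == LMM:
            fits = [fit_lmm_pair(s.counts, eig) for s in sites]
        else:
            fits = [fit_pair(s.counts, K, method=m) for s in sites]
        out["fits"][m] = fits
        out["pvalues"][m] = np.array([f.p_value for f in fits])
    return out


def scenario_power(result: dict, method: str, alpha: float) -> float:
    """Power (%) at known-truth false-discovery proportion alpha."""
    return 100.0 * power_at_fdr(result["pvalues"][method], result["truth"],
                                alpha)


def type_i_error(result: dict, method: str, level: float = 0.05) -> float:
    """Fraction of null pairs with p <= level."""
    p = result["pvalues"][method][~result["truth"]]
    p = p[np.isfinite(p)]
    return float(np.mean(p <= level))
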