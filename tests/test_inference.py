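import numpy as np
import pytest

from asmqtl.core import KinshipMatrix
from asmqtl.inference import (IND, JOINT, DegenerateFitError,
                              InsufficientHetsError, build_design, fit_pair,
                              fit_pql, na_fit, wald_test)
from asmqtl.simulate import SimConfig, simulate_site, simulate_study

from conftest import make_pair


def _het_pair(n_het, n_hom=0, seed=0):
    rng = np.random.default_rng(seed)
    n = n_het + n_hom
    geno = np.r_[np.ones(n_het), np.zeros(n_hom)]
    r = rng.integers(8, 25, size=n).astype(float)
    y = rng.binomial(r.astype(int), 0.5).astype(float)
    y_allele = np.full((n, 2), np.nan)
    r_allele = np.full((n, 2), np.nan)
    for i in range(n_het):
        r1 = rng.integers(2, int(r[i]) - 1)
        y1 = min(y[i], rng.integers(0, r1 + 1))
        y_allele[i] = [y1, y[i] - y1]
        r_allele[i] = [r1, r[i] - r1]
    return make_pair(geno, y, r, y_allele, r_allele)


class TestBuildDesign:
    def test_joint_counting_rule(self, toy_pair):
        rows = build_design(toy_pair)
        assert len(rows) == 4                     # 1 + 2 + 1
        allele_rows = [r for r in rows if r.is_allele]
        assert sorted(r.x for r in allele_rows) == [0.0, 1.0]
        hom_rows = [r for r in rows if not r.is_allele]
        assert sorted(r.x for r in hom_rows) == [0.0, 1.0]
        assert all(r.residual_scale == 0.5 for r in hom_rows)

    def test_individual_level_covariates(self, toy_pair):
        rows = build_design(toy_pair, use_allele=False)
        assert [r.x for r in rows] == [0.0, 0.5, 1.0]
        assert all(r.residual_scale == 0.5 for r in rows)

    def test_allele_only_requires_five_hets(self):
        with pytest.raises(InsufficientHetsError):
            build_design(_het_pair(4), use_individual=False)
        rows = build_design(_het_pair(5), use_individual=False)
        assert len(rows) == 10 and all(r.is_allele for r in rows)

    def test_het_without_phase_data_collapses(self, toy_pair):
        toy_pair.y_allele[:] = np.nan
        toy_pair.r_allele[:] = np.nan
        rows = build_design(toy_pair)
        assert len(rows) == 3
        assert [r.x for r in rows] == [0.0, 0.5, 1.0]

    def test_residualized_covariate_keeps_allele_contrast(self, toy_pair):
        rows = build_design(toy_pair, x_override=np.array([-0.3, 0.41, 1.7]))
        a = [r.x for r in rows if r.is_allele]
        assert a[1] - a[0] == pytest.approx(1.0)

    def test_zero_read_rows_dropped(self, toy_pair):
        toy_pair.r_total[0] = 0.0
        assert len(build_design(toy_pair)) == 3


def _simulated_fit_inputs(n=60, sigma_small=True, seed=2, beta=0.8):
    """Simulated pair with (nearly) no random effects, for GLM limits."""
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, 0.4, size=n).astype(float)
    r = rng.integers(10, 30, size=n).astype(float)
    from scipy.special import expit
    eta = -0.3 + beta * geno / 2.0
    y = rng.binomial(r.astype(int), expit(eta)).astype(float)
    pc = make_pair(geno, y, r)
    K = KinshipMatrix(pc.individual_ids, np.eye(n))
    return pc, K


class TestFitPql:
    def test_matches_glm_when_variance_components_vanish(self):
        import statsmodels.api as sm
        pc, K = _simulated_fit_inputs()
        rows = build_design(pc, use_allele=False)
        fit = fit_pql(rows, K, method=IND, fix_vc=(0.0, 0.0, 0.0))
        X = np.column_stack([np.ones(pc.n), pc.genotype / 2.0])
        glm = sm.GLM(np.column_stack([pc.y_total, pc.r_total - pc.y_total]),
                     X, family=sm.families.Binomial()).fit()
        assert fit.beta_hat == pytest.approx(glm.params[1], abs=1e-3)
        assert fit.p_value == pytest.approx(glm.pvalues[1], abs=1e-3)
        # and the freely-estimated fit stays close on binomial data
        free = fit_pair(pc, K, method=IND)
        assert free.beta_hat == pytest.approx(glm.params[1], abs=0.05)

    def test_monomorphic_returns_na(self):
        pc, K = _simulated_fit_inputs()
        pc.genotype[:] = 2.0
        fit = fit_pair(pc, K, method=IND)
        assert not fit.converged and np.isnan(fit.p_value)
        assert "monomorphic" in fit.note

    def test_joint_equals_individual_without_hets(self, identity_kinship):
        rng = np.random.default_rng(5)
        n = 40
        geno = rng.choice([0.0, 2.0], size=n)
        r = rng.integers(5, 30, size=n).astype(float)
        y = rng.binomial(r.astype(int), 0.4).astype(float)
        pc = make_pair(geno, y, r)
        K = identity_kinship(n)
        f1 = fit_pair(pc, K, method=JOINT)
        f2 = fit_pair(pc, K, method=IND)
        assert f1.beta_hat == pytest.approx(f2.beta_hat, abs=1e-8)
        assert f1.p_value == pytest.approx(f2.p_value, abs=1e-8)

    def test_invariance_to_row_order_and_relabeling(self):
        cfg = SimConfig(n=50, seed=9)
        rng = np.random.default_rng(9)
        from asmqtl.simulate import simulate_genotypes, simulate_focal_snp
        _, K = simulate_genotypes(50, 400, None, rng)
        x = simulate_focal_snp(50, 0.3, rng)
        site = simulate_site(cfg, x, K, True, rng)
        f0 = fit_pair(site.counts, K, method=JOINT)

        perm = rng.permutation(site.counts.n)
        pc = site.counts
        ids = [pc.individual_ids[i] for i in perm]
        pc2 = make_pair(pc.genotype[perm], pc.y_total[perm], pc.r_total[perm],
                        pc.y_allele[perm], pc.r_allele[perm], ids=ids)
        f1 = fit_pair(pc2, K, method=JOINT)
        assert f1.beta_hat == pytest.approx(f0.beta_hat, abs=1e-6)
        assert f1.p_value == pytest.approx(f0.p_value, abs=1e-6)

    def test_parameter_recovery_with_attenuation(self):
        """Across simulated mQTL, PQL estimates track the generating
        per-allele effects with the mild attenuation expected of
        working-model linearization (slope well below 1 would indicate
        a coding error; slope ~0.8-1.0 is the documented regime)."""
        cfg = SimConfig(n=150, pve=0.15, n_sites=60, prop_true=1.0, seed=31)
        sites, K = simulate_study(cfg)
        bt = np.array([s.beta_true for s in sites])
        bh = np.array([fit_pair(s.counts, K, method=JOINT).beta_hat
                       for s in sites])
        slope = np.polyfit(bt, bh, 1)[0]
        assert 0.7 < slope < 1.1
        assert np.corrcoef(bt, bh)[0, 1] > 0.9

    def test_null_wald_calibration_smoke(self):
        cfg = SimConfig(n=80, n_sites=150, prop_true=0.0, seed=12)
        sites, K = simulate_study(cfg)
        ps = np.array([fit_pair(s.counts, K, method=JOINT).p_value
                       for s in sites])
        assert 0.01 < np.mean(ps <= 0.05) < 0.13
        assert 0.35 < np.median(ps) < 0.65


class TestWaldTest:
    @pytest.mark.parametrize("stat,expected", [
        (0.0, 1.0), (3.841459, 0.05), (10.8276, 0.001)])
    def test_chi_square_quantiles(self, stat, expected):
        f = na_fit(JOINT, 10, 5, "")
        f.beta_hat, f.se_beta = np.sqrt(stat), 1.0
        assert wald_test(f) == pytest.approx(expected, rel=1e-3)

    def test_degenerate_se(self):
        f = na_fit(JOINT, 10, 5, "")
        f.beta_hat, f.se_beta = 1.0, 0.0
        with pytest.raises(DegenerateFitError):
            wald_test(f)
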