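"""NB GLM machinery: normalisation, dispersion, contrasts and their tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

import cistrans as ct
from cistrans import stats as st


def tmm_oracle(y, libs, ref):
    """Straightforward reimplementation of the TMM formula (30% M-trim,
    5% A-trim, inverse-variance weights), independent of the library code."""
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        keep = (y[:, j] > 0) & (y[:, ref] > 0)
        pj = y[keep, j] / libs[j]
        pr = y[keep, ref] / libs[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (libs[j] - y[keep, j]) / (libs[j] * y[keep, j]) + \
            (libs[ref] - y[keep, ref]) / (libs[ref] * y[keep, ref])
        sel = (M >= np.quantile(M, 0.3)) & (M <= np.quantile(M, 0.7)) & \
              (A >= np.quantile(A, 0.05)) & (A <= np.quantile(A, 0.95))
        factors[j] = 2 ** (np.sum(M[sel] / w[sel]) / np.sum(1 / w[sel]))
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        y = np.tile(np.arange(1, 51)[:, None], (1, 2)).astype(float)
        f = ct.tmm_norm_factors(y, np.array([1e4, 1e4]))
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, 500).astype(float) + 1
        y = np.column_stack([a, 2 * a])
        f = ct.tmm_norm_factors(y, np.array([a.sum(), 2 * a.sum()]))
        np.testing.assert_allclose(f, 1.0, atol=1e-9)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.negative_binomial(10, 0.05, size=(800, 4)).astype(float)
        libs = y.sum(axis=0)
        cpm = y / libs * 1e6
        uq = np.array([np.quantile(c[c > 0], 0.75) for c in cpm.T])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        ours = ct.tmm_norm_factors(y, libs)
        oracle = tmm_oracle(y, libs, ref)
        np.testing.assert_allclose(ours, oracle, rtol=1e-10)

    def test_all_zero_sample_rejected(self):
        y = np.column_stack([np.arange(10.0), np.zeros(10)])
        with pytest.raises(ValueError, match="all-zero"):
            ct.tmm_norm_factors(y, np.array([45.0, 1.0]))


class TestDispersion:
    gidx = np.repeat([0, 1], 10)
    offset = np.zeros(20)

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(150.0, size=(2000, 20)).astype(float)
        dm = ct.estimate_dispersion(y, self.gidx, self.offset, prior_df=0.0)
        assert np.median(dm.raw) < 0.01

    def test_monte_carlo_recovery_at_phi_0p4(self):
        rng = np.random.default_rng(4)
        phi, r = 0.4, 2.5
        y = rng.negative_binomial(r, r / (r + 200.0), size=(600, 20)).astype(float)
        dm = ct.estimate_dispersion(y, self.gidx, self.offset, prior_df=0.0)
        assert 0.3 <= np.median(dm.raw) <= 0.5

    def test_single_gene_grid_matches_optimiser(self):
        rng = np.random.default_rng(5)
        y = rng.negative_binomial(5, 5 / 205.0, size=(1, 20)).astype(float)
        fine = np.logspace(np.log10(0.05), np.log10(1.5), 400)
        dm = ct.estimate_dispersion(y, self.gidx, self.offset, grid=fine, prior_df=0.0)

        def neg_apl(log_phi):
            return -st._adjusted_profile_loglik(
                y, self.gidx, self.offset, np.array([np.exp(log_phi)]), 2)[0]

        res = optimize.minimize_scalar(neg_apl, bounds=(np.log(0.05), np.log(1.5)),
                                       method="bounded", options={"xatol": 1e-10})
        assert abs(dm.raw[0] - np.exp(res.x)) < 1e-4

    def test_shrunken_lies_between_raw_and_trend(self):
        rng = np.random.default_rng(6)
        r = 1 / 0.2
        y = rng.negative_binomial(r, r / (r + 100.0), size=(500, 20)).astype(float)
        dm = ct.estimate_dispersion(y, self.gidx, self.offset, prior_df=10.0)
        lo = np.minimum(dm.raw, dm.trend) - 1e-12
        hi = np.maximum(dm.raw, dm.trend) + 1e-12
        assert ((dm.dispersion >= lo) & (dm.dispersion <= hi)).all()

    def test_saturated_design_rejected(self):
        y = np.ones((5, 2))
        with pytest.raises(ValueError, match="saturated"):
            ct.estimate_dispersion(y, np.array([0, 1]), np.zeros(2))


class TestContrasts:
    def test_cis_effect_recovered_with_null_trans(self):
        # balanced +-2 cis effects (a one-signed genome-wide shift would be
        # indistinguishable from composition and absorbed by normalisation)
        sign = np.where(np.arange(200) % 2 == 0, 1.0, -1.0)
        truth = ct.make_truth(200, seed=30, base_log_expr=6.0, cis_lfc=2.0 * sign,
                              dispersion=0.05)
        design = ct.make_design("hemocyte", n_replicates=5, seed=31)
        est = ct.fit_contrasts(ct.simulate_counts(truth, design, seed=32),
                               normalize=False)
        ctrl = est[est.context == "control"]
        up = ctrl["lfc_cis"].to_numpy()[sign > 0]
        assert 1.8 <= np.median(up) <= 2.2
        assert -0.2 <= ctrl["lfc_trans"].median() <= 0.2

    def test_null_pvalues_are_uniform(self, null_estimates):
        for comp in ("parental", "cis", "trans"):
            p = null_estimates.loc[null_estimates.context == "control", f"p_{comp}"]
            assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_trans_identity_is_exact(self, recovery_run):
        _, est = recovery_run
        resid = est["lfc_trans"] - (est["lfc_parental"] - est["lfc_cis"])
        assert np.abs(resid.to_numpy()).max() == 0.0

    def test_response_context_is_difference_of_conditions(self, recovery_run):
        _, est = recovery_run
        wide = est.pivot(index="gene_id", columns="context", values="lfc_parental")
        np.testing.assert_allclose(
            wide["response"], wide["challenged"] - wide["control"], atol=1e-9)

    def test_depth_change_in_one_sample_leaves_estimates_unchanged(self):
        truth = ct.make_truth(300, seed=33, base_log_expr=6.0, dispersion=0.05)
        design = ct.make_design("hemocyte", n_replicates=3, seed=34)
        m = ct.simulate_counts(truth, design, seed=35)
        est1 = ct.fit_contrasts(m)
        scaled = m.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 4
        est2 = ct.fit_contrasts(ct.AlleleCountMatrix(scaled, m.meta))
        # TMM absorbs the pure depth change; estimates move only marginally
        diff = (est1["lfc_parental"] - est2["lfc_parental"]).abs()
        assert diff.median() < 0.05

    def test_missing_group_raises_design_error(self):
        truth = ct.make_truth(10, seed=0)
        design = ct.make_design("hemocyte", n_replicates=3, seed=0)
        m = ct.simulate_counts(truth, design, seed=1)
        no_hyb = m.subset_samples((m.meta.genotype != "hybrid").to_numpy())
        with pytest.raises(ValueError, match="missing groups"):
            ct.fit_contrasts(no_hyb)

    def test_zero_contrast_gives_boundary_pvalue(self):
        truth = ct.make_truth(20, seed=40, base_log_expr=7.0, dispersion=0.05)
        design = ct.make_design("hemocyte", n_replicates=4, seed=41)
        m = ct.simulate_counts(truth, design, seed=42)
        fit, _, key_of = st.prepare_fit(m)
        c = np.zeros(8)  # the trivial null contrast: estimate exactly 0
        lfc, F, p = st.ql_f_test(fit, c)
        assert (p >= 0.99).all() and np.allclose(lfc, 0.0)

    def test_f_test_agrees_with_likelihood_ratio_chi2_in_large_samples(self):
        truth = ct.make_truth(200, seed=43, base_log_expr=7.0, dispersion=0.05)
        design = ct.make_design("hemocyte", n_replicates=30, seed=44)
        m = ct.simulate_counts(truth, design, seed=45)
        fit, _, key_of = st.prepare_fit(m)
        c = np.zeros(8)
        c[key_of[("sim_parent", "total", "control")]] = 1.0
        c[key_of[("sec_parent", "total", "control")]] = -1.0
        _, F, p_f = st.ql_f_test(fit, c)
        df_total = fit.df_residual + fit.prior_df_ql
        delta = F * fit.s2_post
        p_chi = sps.chi2.sf(delta, 1)
        sel = (p_f > 1e-4) & (p_f < 0.9)
        rel = np.abs(p_f[sel] - p_chi[sel]) / p_chi[sel]
        assert np.median(rel) < 0.2


class TestBhFdr:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(ct.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(ct.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        q = ct.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p).all()


class TestDivergenceCorrelation:
    def _frame(self, parental, comp_vals, component):
        other = "trans" if component == "cis" else "cis"
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(parental))],
            "context": "control",
            "lfc_parental": parental,
            f"lfc_{component}": comp_vals,
            f"lfc_{other}": np.asarray(parental) - np.asarray(comp_vals),
        })

    def test_perfect_cis_correlation(self):
        p = np.linspace(-2, 2, 20)
        r, lo, hi = ct.divergence_correlation(self._frame(p, p, "cis"), "cis", "control")
        assert r == pytest.approx(1.0)

    def test_equal_variance_components_give_inverse_sqrt2(self):
        rng = np.random.default_rng(9)
        cis = rng.normal(0, 1, 20000)
        trans = rng.normal(0, 1, 20000)
        frame = self._frame(cis + trans, cis, "cis")
        r, lo, hi = ct.divergence_correlation(frame, "cis", "control")
        assert r == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ct.divergence_correlation(self._frame([1, 1, 1], [1, 1, 1], "cis"),
                                      "cis", "control")


class TestParentHybridContrasts:
    def test_additive_gene_sits_between_parents(self):
        # parental divergence 4 (log2), no dominance: hybrid total at midpoint
        truth = ct.make_truth(100, seed=50, base_log_expr=7.0, cis_lfc=2.0,
                              trans_lfc=2.0, dispersion=0.05)
        design = ct.make_design("hemocyte", n_replicates=5, seed=51)
        m = ct.simulate_counts(truth, design, seed=52)
        # every gene shares the shift, so compositional normalisation is off
        dom = ct.fit_parent_hybrid_contrasts(m, normalize=False)
        ctrl = dom[dom.context == "control"]
        # hybrid = (2^cis + 1)/2 * sec-parent level, parents at ratio 16
        assert ctrl["lfc_vs_sim"].median() == pytest.approx(np.log2(5 / 2) - 4, abs=0.3)
        assert ctrl["lfc_vs_sec"].median() == pytest.approx(np.log2(5 / 2), abs=0.3)
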