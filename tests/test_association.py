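"""Logistic fitting and the per-SNP marginal / 1-df / 2-df tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from hemegxe import (
    DegenerateDesignError,
    ModelSpec,
    SimulationConfig,
    bonferroni_threshold,
    center_exposure,
    dichotomize_exposure,
    fit_logistic,
    genome_scan,
    marginal_snp_test,
    simulate_cohort,
)
from hemegxe.association import test_interaction_1df as interaction_1df
from hemegxe.association import test_joint_2df as joint_2df
from hemegxe.simulate import CohortData, GenotypePanel


def _neg_ll(beta, y, X):
    eta = X @ beta
    return -(y @ eta - np.logaddexp(0.0, eta).sum())


def brute_force_mle(y, X):
    """Independent derivative-free maximizer of the same binomial likelihood."""
    res = optimize.minimize(
        _neg_ll,
        np.zeros(X.shape[1]),
        args=(y, X),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 200_000,
                 "maxfev": 200_000},
    )
    return res.x


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # exposed: 20 cases / 10 controls; unexposed: 30 cases / 40 controls
        y = np.r_[np.ones(20), np.zeros(10), np.ones(30), np.zeros(40)]
        x = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, np.column_stack([np.ones(100), x]), ["const", "x"])
        assert fit.converged
        assert fit.coef("x") == pytest.approx(math.log(80 / 30), abs=1e-8)

    def test_intercept_only_is_logit_of_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, np.ones((100, 1)), ["const"])
        assert fit.coef("const") == pytest.approx(math.log(30 / 70), abs=1e-8)

    def test_matches_derivative_free_oracle(self, rng):
        for _ in range(10):
            n = 200
            X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
            beta_true = rng.normal(0, 0.7, size=4)
            y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
            if not (0 < y.sum() < n):
                continue
            fit = fit_logistic(y, X)
            oracle = brute_force_mle(y, X)
            assert np.max(np.abs(fit.coefficients - oracle)) < 1e-6

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 4))])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ [0.3, 0.5, -0.4, 0.0, 0.8]))).astype(
            float
        )
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-7)
        assert np.allclose(
            np.sqrt(np.diag(fit.covariance)), ref.bse, rtol=1e-5
        )

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(DegenerateDesignError):
            fit_logistic(y, X)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_perfect_separation_detected(self):
        x = np.r_[np.linspace(-2, -0.1, 20), np.linspace(0.1, 2, 20)]
        y = (x > 0).astype(float)
        fit = fit_logistic(y, np.column_stack([np.ones(40), x]))
        assert not fit.converged
        assert fit.separated

    def test_wald_and_lrt_agree_on_large_sample(self, rng):
        n = 50_000
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.standard_normal(n)
        eta = -1.0 + 0.05 * g + 0.1 * e + 0.06 * g * e
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X3 = np.column_stack([np.ones(n), g, e, g * e])
        fit3 = fit_logistic(y, X3, ["const", "g", "e", "gxe"])
        fit2 = fit_logistic(y, X3[:, :3], ["const", "g", "e"])
        p_wald = fit3.wald_p("gxe")
        lr = 2 * (fit3.log_likelihood - fit2.log_likelihood)
        p_lrt = stats.chi2.sf(lr, 1)
        assert 0.8 < p_wald / p_lrt < 1.25


class TestExposureCoding:
    def test_centering_examples(self):
        assert np.allclose(center_exposure([1, 2, 3]), [-1, 0, 1])
        assert np.allclose(center_exposure(np.full(50, 1.36)), 0.0)

    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_centering_idempotent_and_mean_zero(self, values):
        once = center_exposure(values)
        assert abs(once.mean()) < 1e-9
        assert np.allclose(center_exposure(once), once, atol=1e-9)

    def test_dichotomize_at_control_median(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert dichotomize_exposure(v, np.ones(4, bool)).tolist() == [0, 0, 1, 1]
        assert dichotomize_exposure(np.full(5, 2.0), np.ones(5, bool)).sum() == 0
        # controls are the last three values only: their median is 2
        v = np.array([10.0, 1.0, 2.0, 3.0])
        mask = np.array([False, True, True, True])
        assert dichotomize_exposure(v, mask).tolist() == [1, 0, 0, 1]

    def test_dichotomize_without_controls_fails(self):
        with pytest.raises(ValueError, match="control"):
            dichotomize_exposure(np.arange(4.0), np.zeros(4, bool))

    def test_exposure_shift_moves_snp_main_effect_not_interaction(self, rng):
        """Adding a constant to the exposure is absorbed by the SNP main
        effect; the product-term estimate and its Wald p are algebraically
        invariant."""
        n = 400
        g = rng.binomial(2, 0.4, n).astype(float)
        e = rng.normal(1.3, 0.4, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.3 * g + 0.5 * g * e)))).astype(
            float
        )

        def fit_with(e_used):
            X = np.column_stack([np.ones(n), g, e_used, g * e_used])
            return fit_logistic(y, X, ["const", "snp", "heme", "snp_x_heme"])

        raw, shifted = fit_with(e), fit_with(e - e.mean())
        assert shifted.coef("snp_x_heme") == pytest.approx(
            raw.coef("snp_x_heme"), abs=1e-6
        )
        assert shifted.wald_p("snp_x_heme") == pytest.approx(
            raw.wald_p("snp_x_heme"), abs=1e-8
        )
        assert abs(shifted.coef("snp") - raw.coef("snp")) > 0.05


class TestPerSnpTests:
    def test_monomorphic_snp_flagged(self, null_cohort):
        cohort = null_cohort
        panel = cohort.panel
        mono = panel.genotypes.copy()
        mono[:, 0] = 0
        panel2 = GenotypePanel(
            snp_ids=panel.snp_ids, chromosome=panel.chromosome,
            position=panel.position, effect_allele=panel.effect_allele,
            other_allele=panel.other_allele, maf=panel.maf, genotypes=mono,
        )
        c2 = CohortData(
            cohort_label="m", status=cohort.status, exposure=cohort.exposure,
            bmi=cohort.bmi, age=cohort.age, eigenvectors=cohort.eigenvectors,
            panel=panel2,
        )
        r = interaction_1df(c2, panel.snp_ids[0])
        assert r.status == "monomorphic"
        assert math.isnan(r.p_1df)

    def test_duplicated_genotype_covariate_is_degenerate(self, null_cohort):
        c = null_cohort
        ev = np.column_stack(
            [c.panel.genotypes[:, 0].astype(float), c.eigenvectors]
        )
        c2 = CohortData(
            cohort_label="d", status=c.status, exposure=c.exposure, bmi=c.bmi,
            age=c.age, eigenvectors=ev, panel=c.panel,
        )
        with pytest.raises(DegenerateDesignError):
            marginal_snp_test(c2, c.panel.snp_ids[0])

    def test_joint_2df_in_unit_interval(self, effect_cohort):
        for sid in effect_cohort.panel.snp_ids:
            p = joint_2df(effect_cohort, sid)
            assert 0.0 <= p <= 1.0

    def test_marginal_effect_detected_by_2df_with_null_interaction(self):
        """A SNP with a strong marginal effect but no interaction lights up
        the joint test while the product-term test stays null-like."""
        cfg = SimulationConfig(
            n_cases=800, n_controls=1200, maf_range=(0.4, 0.4),
            or_snp=1.6, or_interaction=1.0, seed=17,
        )
        c = simulate_cohort(cfg)
        sid = c.panel.snp_ids[0]
        p2 = joint_2df(c, sid)
        r1 = interaction_1df(c, sid)
        assert p2 < 1e-3
        assert r1.p_1df > 0.05

    def test_interaction_recovered_with_wald_and_lrt(self, effect_cohort):
        sid = effect_cohort.panel.snp_ids[0]
        wald = interaction_1df(effect_cohort, sid, ModelSpec())
        lrt = interaction_1df(
            effect_cohort, sid, ModelSpec(interaction_test="lrt")
        )
        assert wald.p_1df < 0.05 and lrt.p_1df < 0.05
        assert wald.beta_interaction == pytest.approx(lrt.beta_interaction)


class TestGenomeScan:
    def test_one_row_per_snp_with_partitioned_status(self, null_cohort):
        table = genome_scan(null_cohort)
        assert len(table) == null_cohort.panel.n_snps
        assert set(table["STATUS"]) <= {
            "ok", "monomorphic", "separation", "non-convergence"
        }

    def test_scan_invariant_to_snp_input_order(self, null_cohort):
        c = null_cohort
        perm = np.random.default_rng(0).permutation(c.panel.n_snps)
        p = c.panel
        shuffled = GenotypePanel(
            snp_ids=[p.snp_ids[i] for i in perm],
            chromosome=p.chromosome[perm], position=p.position[perm],
            effect_allele=p.effect_allele[perm], other_allele=p.other_allele[perm],
            maf=p.maf[perm], genotypes=p.genotypes[:, perm],
        )
        c2 = CohortData(
            cohort_label=c.cohort_label, status=c.status, exposure=c.exposure,
            bmi=c.bmi, age=c.age, eigenvectors=c.eigenvectors, panel=shuffled,
        )
        t1, t2 = genome_scan(c), genome_scan(c2)
        assert t1.equals(t2)

    def test_rerun_is_deterministic(self, null_cohort):
        assert genome_scan(null_cohort).equals(genome_scan(null_cohort))


class TestBonferroni:
    def test_identity_at_single_test(self):
        assert bonferroni_threshold(0.04, 1) == 0.04

    def test_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)
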