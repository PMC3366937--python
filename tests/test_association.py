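"""Single-SNP association: trend test, allelic OR, MAF, dosage logistic."""

import numpy as np
import pytest

from hapghost import association as A
from hapghost.errors import (
    CollinearityError,
    ConvergenceError,
    DegeneratePredictorError,
    ValidationError,
)

from conftest import make_pheno

RS2856656 = A.GenotypeTable2x3((510, 38, 2), (487, 66, 2))
RS60206633 = A.GenotypeTable2x3((529, 30, 1), (527, 46, 2))


class TestTrendTest:
    def test_published_replication_tables(self):
        """Cochran-Armitage p-values match the replication-study printout."""
        assert A.trend_test(RS2856656).p == pytest.approx(0.008, abs=5e-4)
        assert A.trend_test(RS60206633).p == pytest.approx(0.062, abs=5e-4)

    def test_identical_rows_give_null(self):
        t = A.trend_test(A.GenotypeTable2x3((100, 40, 10), (100, 40, 10)))
        assert t.z == pytest.approx(0.0, abs=1e-12)
        assert t.p == pytest.approx(1.0)

    def test_equals_logistic_score_test(self):
        """The trend chi2 equals the score test of the genotype-scored
        logistic model (independent closed-form oracle)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            tab = A.GenotypeTable2x3(tuple(rng.integers(5, 200, 3)),
                                     tuple(rng.integers(5, 200, 3)))
            n = np.array(tab.control_counts, dtype=float) + np.array(tab.case_counts)
            r = np.array(tab.case_counts, dtype=float)
            s = np.array([0.0, 1.0, 2.0])
            N, R = n.sum(), r.sum()
            pbar = R / N
            # score statistic of logit P(case) = a + b*s under b = 0
            score = np.sum(s * (r - pbar * n))
            sbar = np.sum(n * s) / N
            info = pbar * (1 - pbar) * np.sum(n * (s - sbar) ** 2)
            chi2_score = score ** 2 / info
            assert A.trend_test(tab).chi2 == pytest.approx(chi2_score, rel=1e-6)


class TestAllelicOR:
    def test_published_or_and_woolf_ci(self):
        res = A.allelic_or(RS2856656)
        assert round(res.odds_ratio, 2) == 1.70
        assert round(res.ci_low, 2) == 1.15
        assert round(res.ci_high, 2) == 2.51

    def test_identical_rows_give_unit_or(self):
        res = A.allelic_or(A.GenotypeTable2x3((50, 30, 20), (50, 30, 20)))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_ci_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tab = A.GenotypeTable2x3(tuple(rng.integers(2, 300, 3)),
                                     tuple(rng.integers(2, 300, 3)))
            t = tab.allele_2x2().astype(float)
            res = A.allelic_or(tab)
            lo = np.log(t[1, 1] * t[0, 0] / (t[1, 0] * t[0, 1]))
            se = np.sqrt(1 / t[0, 0] + 1 / t[0, 1] + 1 / t[1, 0] + 1 / t[1, 1])
            assert res.ci_low == pytest.approx(np.exp(lo - 1.959963984540054 * se), abs=1e-10)
            assert res.ci_high == pytest.approx(np.exp(lo + 1.959963984540054 * se), abs=1e-10)

    def test_zero_cell_requires_continuity_flag(self):
        tab = A.GenotypeTable2x3((100, 0, 0), (90, 10, 0))
        with pytest.raises(ValidationError, match="continuity"):
            A.allelic_or(tab)
        res = A.allelic_or(tab, continuity=True)
        assert np.isfinite(res.odds_ratio)


class TestMaf:
    @pytest.mark.parametrize("counts,expected", [
        ((510, 38, 2), 0.038), ((487, 66, 2), 0.063),
        ((529, 30, 1), 0.029), ((527, 46, 2), 0.044),
        ((49, 91, 1), 0.33),
    ])
    def test_published_frequencies(self, counts, expected):
        assert A.maf(counts) == pytest.approx(expected, abs=5e-3)

    def test_fixed_for_counted_allele_folds_with_flag(self):
        f, flipped = A.fold_maf((0, 0, 10))
        assert f == 0.0 and flipped


class TestDoseLogistic:
    def _sim(self, rng, n=600, beta=0.7, p=0.3, with_cov=True):
        g = rng.binomial(2, p, n).astype(float)
        cov = rng.standard_normal((n, 2))
        eta = -0.5 + beta * g + (0.3 * cov[:, 0] if with_cov else 0)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        pheno = make_pheno(y, {"C1": cov[:, 0], "C2": cov[:, 1]} if with_cov else None)
        return g, pheno

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        g, pheno = self._sim(rng)
        res = A.dose_logistic(g, pheno, covariates=["C1", "C2"])
        X = sm.add_constant(np.column_stack([g, pheno.covariate_matrix(["C1", "C2"])]))
        fit = sm.Logit(pheno.status, X).fit(disp=0)
        assert res.log_or == pytest.approx(fit.params[1], abs=1e-6)
        assert res.se == pytest.approx(fit.bse[1], rel=1e-4)
        assert res.p_wald == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_hard_genotypes_equal_plain_logistic(self):
        """On 0/1/2 genotypes the dosage model is ordinary logistic
        regression on the genotype column (IRLS oracle written here)."""
        rng = np.random.default_rng(6)
        g, pheno = self._sim(rng, with_cov=False)
        res = A.dose_logistic(g, pheno)
        # independent small IRLS
        X = np.column_stack([np.ones_like(g), g])
        y = pheno.status.astype(float)
        beta = np.zeros(2)
        for _ in range(50):
            mu = 1 / (1 + np.exp(-X @ beta))
            W = mu * (1 - mu)
            beta = beta + np.linalg.solve(X.T @ (X * W[:, None]), X.T @ (y - mu))
        assert res.log_or == pytest.approx(beta[1], abs=1e-8)

    def test_antisymmetric_design_gives_zero_effect(self):
        """Cases' doses exactly mirror controls' doses -> beta = 0."""
        doses = np.array([0.0, 0.5, 1.0, 1.5, 2.0] * 2)
        status = np.array([1] * 5 + [0] * 5)
        res = A.dose_logistic(doses, make_pheno(status))
        assert res.log_or == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_effect_recovery_in_ghost_cohort(self, ghost_bundle):
        """At the true causal variant the fitted OR brackets the simulated 3.0."""
        res = A.dose_logistic(ghost_bundle.truth.causal_genotype.astype(float),
                              ghost_bundle.observed.phenotype,
                              covariates=["PC1", "PC2", "PC3", "PC4"])
        assert 2.0 < res.odds_ratio < 4.5

    def test_constant_dose_rejected(self):
        pheno = make_pheno([1, 0, 1, 0])
        with pytest.raises(DegeneratePredictorError):
            A.dose_logistic(np.ones(4), pheno)

    def test_separation_raises_with_trace(self):
        y = np.array([0] * 20 + [1] * 20)
        g = y.astype(float) * 2
        with pytest.raises(ConvergenceError) as exc:
            A.dose_logistic(g, make_pheno(y))
        assert len(exc.value.trace) > 1


class TestConditionalLogistic:
    def test_adjusting_on_self_is_collinear(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = rng.integers(0, 2, 200)
        with pytest.raises(CollinearityError):
            A.conditional_logistic(g, g, make_pheno(y))

    def test_block_signal_vanishes_under_truth_not_under_poor_dose(self, ghost_spec):
        """The distant-block association collapses when conditioning on the
        true causal genotype but persists under a poorly imputed dose."""
        from hapghost import synthetic_data as synth

        truth_null, crude_sig, dose_sig = 0, 0, 0
        reps = 12
        for seed in range(100, 100 + reps):
            b = synth.simulate_cohort(ghost_spec, 1000, 1000, 3.0, seed=seed)
            pheno = b.observed.phenotype
            block = b.observed.dosages.column(ghost_spec.ids("block")[0])
            crude = A.dose_logistic(block, pheno)
            crude_sig += crude.p < 1e-4
            truth = A.conditional_logistic(block, b.truth.causal_genotype.astype(float), pheno)
            truth_null += truth.p > 0.05
            poor = synth.degrade_to_dosage(b.truth.causal_genotype.astype(float),
                                           0.2, seed=seed)
            dose = A.conditional_logistic(block, poor, pheno)
            dose_sig += dose.p < 1e-3
        assert crude_sig >= 0.75 * reps
        assert truth_null >= 0.8 * reps
        assert dose_sig >= 0.8 * reps

    def test_constant_adjustment_column_is_dropped(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, 300).astype(float)
        y = (rng.random(300) < 0.4).astype(int)
        pheno = make_pheno(y)
        plain = A.dose_logistic(g, pheno)
        cond = A.conditional_logistic(g, np.ones(300), pheno)
        assert cond.log_or == pytest.approx(plain.log_or, abs=1e-10)
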