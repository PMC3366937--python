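"""Haplotype EM/SEM inference, haplotype logistic models and the AIC scan."""

import numpy as np
import pytest

from hapghost import haplotypes as H
from hapghost import ld
from hapghost.errors import CapacityError, ValidationError

from conftest import (
    TABLE2_CONTROL_FREQS,
    TABLE2_CASE_FREQS,
    TABLE2_HAPS,
    genotypes_from_haplotypes,
    make_gm,
    make_pheno,
)


def freq_lookup(result):
    return {tuple(int(a) for a in h): f
            for h, f in zip(result.haplotypes, result.freqs)}


class TestEmHaplotypes:
    def test_single_snp_equals_allele_frequency(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.27, 1000)[:, None]
        res = H.em_haplotypes(g)
        d = freq_lookup(res)
        assert d[(1,)] == pytest.approx(g.mean() / 2, abs=1e-10)

    def test_two_snps_match_two_locus_em(self):
        rng = np.random.default_rng(1)
        calls = genotypes_from_haplotypes(
            np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
            np.array([0.4, 0.2, 0.1, 0.3]), 800, rng)
        res = H.em_haplotypes(calls)
        tl = ld.two_locus_em(calls[:, 0], calls[:, 1])
        d = freq_lookup(res)
        assert d[(1, 1)] == pytest.approx(tl.f_AB, abs=1e-8)
        assert d[(1, 0)] == pytest.approx(tl.f_Ab, abs=1e-8)
        assert d[(0, 1)] == pytest.approx(tl.f_aB, abs=1e-8)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 600, rng)
        res = H.em_haplotypes(calls, prune_threshold=0.0)
        assert np.all(np.diff(res.loglik_trace) >= -1e-9)

    def test_posterior_counts_sum_to_two(self):
        rng = np.random.default_rng(3)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 400, rng)
        calls[rng.random(calls.shape) < 0.03] = -1
        res = H.em_haplotypes(calls)
        E = res.posterior.expected_counts()
        np.testing.assert_allclose(E.sum(axis=1), 2.0, atol=1e-9)

    def test_recovers_control_arm_frequencies(self):
        """3-SNP frequencies at the published control-arm scale are recovered
        within 0.015 at n = 5000."""
        rng = np.random.default_rng(4)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 5000, rng)
        res = H.em_haplotypes(calls)
        d = freq_lookup(res)
        for hap, f_true in zip(TABLE2_HAPS, TABLE2_CONTROL_FREQS):
            assert d.get(tuple(hap), 0.0) == pytest.approx(f_true, abs=0.015)

    def test_phase_known_data_equals_counting(self):
        """With no heterozygote ambiguity the EM reduces to direct counting."""
        rng = np.random.default_rng(5)
        hap = rng.choice(2, size=(500, 1))
        calls = (2 * hap).astype(np.int8)  # only homozygotes
        res = H.em_haplotypes(calls)
        d = freq_lookup(res)
        assert d[(1,)] == pytest.approx(hap.mean(), abs=1e-12)

    def test_capacity_error_above_twelve_snps(self):
        calls = np.zeros((20, 13), dtype=np.int8)
        with pytest.raises(CapacityError):
            H.em_haplotypes(calls)

    def test_all_missing_sample_skipped_with_count(self):
        rng = np.random.default_rng(6)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 100, rng)
        calls[0, :] = -1
        res = H.em_haplotypes(calls)
        assert res.n_skipped == 1
        # the skipped sample still gets its prior expectation
        E = res.posterior.expected_counts()
        np.testing.assert_allclose(E[0], 2 * res.freqs, atol=1e-12)


class TestSemHaplotypes:
    def test_single_snp_is_exact_across_seeds(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, 500)[:, None]
        res1 = H.sem_haplotypes(g, n_iter=200, burn_in=50, seed=1)
        res2 = H.sem_haplotypes(g, n_iter=200, burn_in=50, seed=99)
        d1, d2 = freq_lookup(res1), freq_lookup(res2)
        # no phase ambiguity: zero Monte-Carlo variance beyond quantization
        assert d1[(1,)] == pytest.approx(g.mean() / 2, abs=1e-12)
        assert d1[(1,)] == pytest.approx(d2[(1,)], abs=1e-12)

    def test_sem_agrees_with_em_within_mc_error(self):
        rng = np.random.default_rng(8)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 3000, rng)
        em = H.em_haplotypes(calls)
        sem = H.sem_haplotypes(calls, n_iter=500, burn_in=100, seed=11)
        d_em, d_sem = freq_lookup(em), freq_lookup(sem)
        sd_iter = sem.mc_se * np.sqrt(500 - 100)  # per-iteration MC sd
        sd = {tuple(int(a) for a in h): s for h, s in zip(sem.haplotypes, sd_iter)}
        for hap in map(tuple, TABLE2_HAPS):
            gap = abs(d_sem.get(hap, 0) - d_em.get(hap, 0))
            assert gap < max(3 * sd.get(hap, 0.0), 3e-3)

    def test_seed_stability_within_mc_error(self):
        rng = np.random.default_rng(9)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 1500, rng)
        a = H.sem_haplotypes(calls, n_iter=400, burn_in=100, seed=5)
        b = H.sem_haplotypes(calls, n_iter=400, burn_in=100, seed=6)
        da, db = freq_lookup(a), freq_lookup(b)
        sd_a = {tuple(int(x) for x in h): s * np.sqrt(300)
                for h, s in zip(a.haplotypes, a.mc_se)}
        for hap in map(tuple, TABLE2_HAPS):
            comb = np.hypot(sd_a.get(hap, 0.0), sd_a.get(hap, 0.0))
            assert abs(da.get(hap, 0) - db.get(hap, 0)) < max(2 * comb, 3e-3)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValidationError):
            H.sem_haplotypes(np.zeros((20, 1), dtype=np.int8), seed=None)


class TestHaplotypeLogistic:
    def _phased_cohort(self, rng, n_controls, n_cases,
                       control_freqs=TABLE2_CONTROL_FREQS,
                       case_freqs=TABLE2_CASE_FREQS):
        calls = np.vstack([
            genotypes_from_haplotypes(TABLE2_HAPS, control_freqs, n_controls, rng),
            genotypes_from_haplotypes(TABLE2_HAPS, case_freqs, n_cases, rng),
        ])
        status = np.r_[np.zeros(n_controls, dtype=int), np.ones(n_cases, dtype=int)]
        return make_gm(calls), make_pheno(status)

    def test_risk_haplotype_or_recovered_at_published_scale(self):
        """The rare risk haplotype (control freq 0.021, case freq 0.058)
        carries an OR inside [2.0, 4.4] in nearly all replicates."""
        hits = 0
        reps = 15
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            gm, pheno = self._phased_cohort(rng, 1002, 1542)
            phase = H.em_haplotypes(gm)
            model = H.haplotype_logistic(phase, pheno, snps=gm.snps)
            risk = next(e for e in model.effects if e.haplotype == "BAA")
            hits += 2.0 <= risk.odds_ratio <= 4.4
        assert hits >= 0.8 * reps

    def test_mirror_design_gives_zero_global_chi2(self):
        """Duplicating every individual once as case and once as control
        makes all haplotype effects exactly zero."""
        rng = np.random.default_rng(10)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 300, rng)
        gm = make_gm(np.vstack([calls, calls]))
        pheno = make_pheno(np.r_[np.ones(300, dtype=int), np.zeros(300, dtype=int)])
        phase = H.em_haplotypes(gm)
        model = H.haplotype_logistic(phase, pheno, snps=gm.snps)
        assert model.global_chi2 == pytest.approx(0.0, abs=1e-6)
        assert model.global_p == pytest.approx(1.0, abs=1e-6)

    def test_global_df_is_modelled_haplotypes_minus_one(self):
        rng = np.random.default_rng(11)
        gm, pheno = self._phased_cohort(rng, 500, 500)
        model = H.haplotype_logistic(H.em_haplotypes(gm), pheno, snps=gm.snps)
        assert model.global_df == model.n_modelled - 1
        assert sum(model.freqs.values()) == pytest.approx(1.0, abs=0.02)

    def test_reference_is_most_frequent(self):
        rng = np.random.default_rng(12)
        gm, pheno = self._phased_cohort(rng, 400, 400)
        model = H.haplotype_logistic(H.em_haplotypes(gm), pheno, snps=gm.snps)
        assert model.freqs[model.reference] == max(model.freqs.values())

    def test_aic_counts_all_free_parameters(self):
        rng = np.random.default_rng(13)
        gm, pheno = self._phased_cohort(rng, 400, 400)
        phase = H.em_haplotypes(gm)
        model = H.haplotype_logistic(phase, pheno, snps=gm.snps)
        n_freq = int((phase.freqs > 0).sum()) - 1
        expected_k = 1 + len(model.effects) + n_freq
        assert model.k_params == expected_k
        assert model.aic == pytest.approx(2 * expected_k - 2 * model.loglik)


class TestHaplotypeConditional:
    def test_constant_adjustment_equals_unadjusted(self):
        rng = np.random.default_rng(14)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 500, rng)
        gm = make_gm(calls)
        pheno = make_pheno((rng.random(500) < 0.4).astype(int))
        phase = H.em_haplotypes(gm)
        plain = H.haplotype_logistic(phase, pheno, snps=gm.snps)
        adj = H.haplotype_conditional(phase, pheno, np.ones(500), snps=gm.snps)
        for e1, e2 in zip(plain.effects, adj.effects):
            assert e1.log_or == pytest.approx(e2.log_or, abs=1e-9)

    def test_independent_adjustment_leaves_effects_unchanged(self):
        rng = np.random.default_rng(15)
        calls = genotypes_from_haplotypes(TABLE2_HAPS, TABLE2_CONTROL_FREQS, 2000, rng)
        gm = make_gm(calls)
        pheno = make_pheno((rng.random(2000) < 0.4).astype(int))
        phase = H.em_haplotypes(gm)
        plain = H.haplotype_logistic(phase, pheno, snps=gm.snps)
        adj = H.haplotype_conditional(phase, pheno, rng.uniform(0, 2, 2000),
                                      snps=gm.snps)
        for e1, e2 in zip(plain.effects, adj.effects):
            assert e1.log_or == pytest.approx(e2.log_or, abs=3 * e1.se)

    def test_risk_haplotype_collapses_under_block_dose(self, ghost_spec):
        """Adjusting the risk-haplotype model on a block-SNP dose collapses
        its OR toward 1 (the published 2.99 -> 0.96 pattern) in most
        replicates."""
        from hapghost import synthetic_data as synth

        collapsed = strong_crude = 0
        reps = 10
        for seed in range(400, 400 + reps):
            b = synth.simulate_cohort(ghost_spec, 1500, 1200, 3.0, seed=seed)
            gm = b.observed.genotypes.subset(ghost_spec.ids("tag")[:2])
            pheno = b.observed.phenotype
            phase = H.em_haplotypes(gm)
            crude = H.haplotype_logistic(phase, pheno, snps=gm.snps)
            adj = H.haplotype_conditional(
                phase, pheno, b.observed.dosages.column(ghost_spec.ids("block")[0]),
                snps=gm.snps)
            risk_crude = next(e for e in crude.effects if e.haplotype == "AG")
            risk_adj = next(e for e in adj.effects if e.haplotype == "AG")
            strong_crude += risk_crude.odds_ratio > 1.8
            collapsed += 0.5 <= risk_adj.odds_ratio <= 1.7
        assert strong_crude >= 0.8 * reps
        assert collapsed >= 0.8 * reps


class TestAicScan:
    def test_enumeration_count(self):
        rng = np.random.default_rng(16)
        calls = np.column_stack([rng.binomial(2, p, 300)
                                 for p in (0.2, 0.3, 0.4, 0.25, 0.35)])
        gm = make_gm(calls)
        pheno = make_pheno((rng.random(300) < 0.5).astype(int))
        res = H.aic_scan(gm, pheno, max_size=4)
        from math import comb
        assert res.n_models == comb(5, 1) + comb(5, 2) + comb(5, 3) + comb(5, 4)

    def test_scan_cap_enforced(self):
        rng = np.random.default_rng(17)
        calls = rng.binomial(2, 0.3, (50, 30)).astype(np.int8)
        gm = make_gm(calls)
        pheno = make_pheno(rng.integers(0, 2, 50))
        with pytest.raises(CapacityError):
            H.aic_scan(gm, pheno, scan_cap=25)

    def test_all_null_scan_prefers_one_snp_model(self):
        """With no true association the parsimony rule keeps 1-SNP winners
        whose global test is null."""
        small_p, one_snp = 0, 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            calls = np.column_stack([rng.binomial(2, p, 1200)
                                     for p in (0.2, 0.3, 0.4, 0.25, 0.35, 0.15)])
            gm = make_gm(calls)
            pheno = make_pheno((rng.random(1200) < 0.5).astype(int))
            res = H.aic_scan(gm, pheno, max_size=3)
            one_snp += len(res.best_snps) == 1
            small_p += res.best_model.global_p > 0.05
        assert one_snp >= 0.8 * reps
        assert small_p >= 0.6 * reps

    def test_ghost_scan_isolates_rare_risk_haplotype(self, ghost_report):
        """On the ghost cohort the winning typed-SNP model contains a rare
        haplotype (control frequency < 0.05) with OR > 2."""
        model = ghost_report.haplotype_model
        rare_risky = [e for e in model.effects
                      if e.control_freq < 0.05 and e.odds_ratio > 2.0
                      and e.haplotype != "rare-pooled"]
        assert rare_risky, [(e.haplotype, e.control_freq, e.odds_ratio)
                            for e in model.effects]
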