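"""The ghost-scenario cohort generator: spec algebra, determinism, realism."""

import numpy as np
import pytest

from hapghost import synthetic_data as synth
from hapghost.errors import ValidationError


class TestPanelSpec:
    def test_default_spec_satisfies_invariants(self, ghost_spec):
        assert sum(c.frequency for c in ghost_spec.classes) == pytest.approx(1.0)
        assert all(0 <= c.causal_carriage <= 1 for c in ghost_spec.classes)
        causal_pos = ghost_spec.snps[[s.role for s in ghost_spec.snps].index("causal")].pos
        far = max(abs(s.pos - causal_pos) for s in ghost_spec.snps if s.role == "block")
        assert far >= 1_000_000
        assert len(ghost_spec.ids("block")) == 12
        assert len(ghost_spec.ids("tag")) == 3
        assert len(ghost_spec.ids("background")) >= 100

    def test_analytic_causal_block_r2_in_observed_range(self, ghost_spec):
        """The class algebra implies causal-block r2 inside the 0.2-0.7
        range the published data showed."""
        assert 0.2 <= ghost_spec.implied_causal_block_r2() <= 0.7

    def test_causal_mainly_on_risk_haplotype(self, ghost_spec):
        """Most causal copies ride the risk (AGT-analog) class."""
        assert ghost_spec.risk_class_share_of_causal() > 0.6

    def test_proxy_r2_matches_weak_tag_regime(self, ghost_spec):
        assert 0.1 <= ghost_spec.implied_causal_proxy_r2() <= 0.2

    def test_class_frequencies_must_sum_to_one(self, ghost_spec):
        bad = [synth.HaplotypeClass("x", (0, 0, 0), 0, 0.5, 0.0)]
        with pytest.raises(ValidationError):
            synth.PanelSpec(snps=ghost_spec.snps, classes=bad,
                            proxy_id=ghost_spec.proxy_id, proxy_freq=0.08,
                            proxy_carry_given_causal=0.5, background_rho=0.9)


class TestSimulateCohort:
    def test_seed_fully_determines_output(self, ghost_spec):
        a = synth.simulate_cohort(ghost_spec, 120, 120, 3.0, seed=42)
        b = synth.simulate_cohort(ghost_spec, 120, 120, 3.0, seed=42)
        np.testing.assert_array_equal(a.truth.phased, b.truth.phased)
        np.testing.assert_array_equal(a.observed.genotypes.calls,
                                      b.observed.genotypes.calls)
        np.testing.assert_array_equal(a.observed.dosages.dose, b.observed.dosages.dose)
        np.testing.assert_array_equal(a.observed.phenotype.status,
                                      b.observed.phenotype.status)

    def test_quotas_and_causal_withheld(self, small_bundle):
        pheno = small_bundle.observed.phenotype
        assert pheno.n_cases == 150 and pheno.n_controls == 150
        assert small_bundle.spec.causal_id not in small_bundle.observed.genotypes.snp_ids
        assert small_bundle.spec.causal_id in small_bundle.observed.dosages.snp_ids
        blocks = set(small_bundle.spec.ids("block"))
        assert not blocks & set(small_bundle.observed.genotypes.snp_ids)

    def test_null_or_gives_matching_case_control_maf(self, ghost_spec):
        b = synth.simulate_cohort(ghost_spec, 800, 800, or_causal=1.0, seed=9)
        status = b.observed.phenotype.status
        g = b.truth.causal_genotype
        diff = abs(g[status == 1].mean() / 2 - g[status == 0].mean() / 2)
        assert diff < 3.0 / np.sqrt(800)

    def test_default_cohort_hits_published_frequency_regime(self, ghost_bundle):
        """Causal control/case MAFs land in the rare-variant regime of the
        published tables (seed 1, n = 1500/1200, OR 3)."""
        status = ghost_bundle.observed.phenotype.status
        g = ghost_bundle.truth.causal_genotype
        assert 0.008 <= g[status == 0].mean() / 2 <= 0.025
        assert 0.03 <= g[status == 1].mean() / 2 <= 0.07

    def test_truth_class_frequencies_recovered_by_counting(self, ghost_spec):
        b = synth.simulate_cohort(ghost_spec, 500, 2000, or_causal=1.0, seed=13)
        phased = b.truth.phased
        snp_idx = {s.id: j for j, s in enumerate(b.truth.genotypes.snps)}
        tag_cols = [snp_idx[i] for i in ghost_spec.ids("tag")]
        haps = phased.reshape(-1, phased.shape[2])[:, tag_cols]
        n2 = len(haps)
        tag_freq = {}
        for row in haps:
            tag_freq[tuple(row)] = tag_freq.get(tuple(row), 0) + 1 / n2
        for cls in ghost_spec.classes:
            f_class = sum(c.frequency for c in ghost_spec.classes
                          if c.tag_alleles == cls.tag_alleles)
            assert tag_freq.get(cls.tag_alleles, 0.0) == pytest.approx(
                f_class, abs=3.0 / np.sqrt(n2))

    def test_block_snps_in_perfect_truth_ld(self, small_bundle):
        phased = small_bundle.truth.phased.reshape(-1, small_bundle.truth.phased.shape[2])
        idx = {s.id: j for j, s in enumerate(small_bundle.truth.genotypes.snps)}
        cols = [idx[i] for i in small_bundle.spec.ids("block")]
        block = phased[:, cols].astype(float)
        r = np.corrcoef(block.T)
        assert (r ** 2).min() > 0.8

    def test_unattainable_quota_raises(self, ghost_spec):
        with pytest.raises(ValidationError, match="quota"):
            synth.simulate_cohort(ghost_spec, 10 ** 6, 10, 3.0, seed=1,
                                  max_batches=1)

    def test_dosage_quality_degrades_with_maf(self, ghost_bundle):
        """The imputation-quality curve falls with rarity, and the rare
        causal variant is the worst-imputed SNP in the cohort."""
        curve = [synth._quality_curve(m) for m in (0.005, 0.02, 0.05, 0.2)]
        assert curve == sorted(curve)
        assert curve[0] < 0.4 < curve[-1]
        dos = ghost_bundle.observed.dosages
        causal_q = dos.snp_quality(ghost_bundle.spec.causal_id)
        others = [dos.quality[j] for j, s in enumerate(dos.snps)
                  if s.role == "background"]
        assert causal_q < np.percentile(others, 5)


class TestCarrierEnrichedControls:
    def test_zero_fraction_matches_plain_controls(self, ghost_spec):
        enr = synth.carrier_enriched_controls(ghost_spec, 400, 0.0, seed=21)
        plain = synth.simulate_cohort(ghost_spec, 50, 400, 3.0, seed=21)
        f_enr = enr.truth.causal_genotype.mean() / 2
        status = plain.observed.phenotype.status
        f_plain = plain.truth.causal_genotype[status == 0].mean() / 2
        assert f_enr == pytest.approx(f_plain, abs=0.02)

    def test_enrichment_reproduces_carrier_stratified_maf_contrast(self, ghost_spec):
        """40% carrier controls: block-SNP MAF > 0.2 among causal carriers
        and < 0.03 among non-carriers (the stratified-MAF signature)."""
        enr = synth.carrier_enriched_controls(ghost_spec, 800, 0.4, seed=22)
        block = enr.truth.genotypes.column(ghost_spec.ids("block")[0])
        carrier = enr.truth.causal_genotype >= 1
        assert carrier.mean() == pytest.approx(0.4, abs=0.05)
        assert block[carrier].mean() / 2 > 0.2
        assert block[~carrier].mean() / 2 < 0.03

    def test_full_fraction_all_heterozygous(self, ghost_spec):
        enr = synth.carrier_enriched_controls(ghost_spec, 100, 1.0, seed=23)
        assert (enr.truth.causal_genotype == 1).all()


class TestDegradeToDosage:
    def test_unit_target_returns_genotypes_exactly(self):
        rng = np.random.default_rng(30)
        g = rng.binomial(2, 0.2, 500).astype(float)
        np.testing.assert_array_equal(synth.degrade_to_dosage(g, 1.0, seed=1), g)

    def test_zero_target_rejected(self):
        with pytest.raises(ValidationError):
            synth.degrade_to_dosage(np.zeros(10), 0.0, seed=1)

    def test_rare_variant_calibration_run(self):
        """Target quality 0.27 at MAF 0.015 (n = 2500) lands in the published
        poor-imputation regime: measured r2 in [0.2, 0.35], Spearman in
        [0.3, 0.6]."""
        from hapghost.imputation import concordance, dosage_quality

        rng = np.random.default_rng(31)
        g = rng.binomial(2, 0.015, 2500).astype(float)
        d = synth.degrade_to_dosage(g, 0.27, seed=32)
        assert 0.2 <= dosage_quality(d).rsq_hat <= 0.35
        assert 0.3 <= concordance(d, g.astype(int)).spearman_rho <= 0.6

    def test_truth_ordering_of_dose_medians(self):
        """Doses are stochastically ordered by the true genotype."""
        rng = np.random.default_rng(33)
        g = rng.binomial(2, 0.1, 20_000).astype(float)
        d = synth.degrade_to_dosage(g, 0.4, seed=34)
        assert np.median(d[g == 0]) < np.median(d[g == 1])
        assert d[g == 1].mean() < d[g == 2].mean()

    def test_quality_monotone_in_target(self):
        rng = np.random.default_rng(35)
        from hapghost.imputation import dosage_quality

        g = rng.binomial(2, 0.3, 5000).astype(float)
        q = [dosage_quality(synth.degrade_to_dosage(g, t, seed=36)).rsq_hat
             for t in (0.2, 0.5, 0.9)]
        assert q[0] < q[1] < q[2]
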