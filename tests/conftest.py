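import numpy as np
import pytest

from hapghost import synthetic_data as synth
from hapghost.io_formats import GenotypeMatrix, PhenotypeTable, SnpRecord

TABLE2_HAPS = np.array([
    [0, 0, 0],   # GGT
    [0, 1, 0],   # GAT
    [0, 1, 1],   # GAC
    [1, 0, 0],   # AGT (risk)
    [1, 1, 1],   # AAC
    [1, 1, 0],   # AAT
])
# control-arm haplotype frequencies of the three-SNP system (normalized)
TABLE2_CONTROL_FREQS = np.array([0.356, 0.282, 0.049, 0.021, 0.260, 0.019])
TABLE2_CONTROL_FREQS = TABLE2_CONTROL_FREQS / TABLE2_CONTROL_FREQS.sum()
TABLE2_CASE_FREQS = np.array([0.329, 0.283, 0.041, 0.058, 0.260, 0.017])
TABLE2_CASE_FREQS = TABLE2_CASE_FREQS / TABLE2_CASE_FREQS.sum()


def make_snps(k, chrom="1", start=1000, step=1000):
    return [SnpRecord(id=f"s{j}", chrom=chrom, pos=start + j * step,
                      ref_allele="A", alt_allele="B") for j in range(k)]


def genotypes_from_haplotypes(haps, freqs, n, rng):
    """Unphased genotype matrix from i.i.d. haplotype draws."""
    idx = rng.choice(len(freqs), size=(n, 2), p=freqs)
    return (haps[idx[:, 0]] + haps[idx[:, 1]]).astype(np.int8)


def make_gm(calls, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix([f"i{i}" for i in range(calls.shape[0])],
                          make_snps(calls.shape[1], chrom=chrom), calls)


def make_pheno(status, covariates=None):
    status = np.asarray(status, dtype=int)
    import pandas as pd
    cov = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame()
    return PhenotypeTable([f"i{i}" for i in range(len(status))], status, cov)


@pytest.fixture(scope="session")
def ghost_spec():
    return synth.default_ghost_spec()


@pytest.fixture(scope="session")
def ghost_bundle(ghost_spec):
    """One default-sized ghost cohort, shared across tests (seed 1)."""
    return synth.simulate_cohort(ghost_spec, n_cases=1500, n_controls=1200,
                                 or_causal=3.0, seed=1)


@pytest.fixture(scope="session")
def small_bundle(ghost_spec):
    """A small, fast cohort for I/O and plumbing tests."""
    return synth.simulate_cohort(ghost_spec, n_cases=150, n_controls=150,
                                 or_causal=3.0, seed=7)


@pytest.fixture(scope="session")
def ghost_report():
    """Full pipeline report for the ghost preset, seed 1 (shared)."""
    from hapghost.pipeline import ScenarioConfig, run_ghost_analysis

    return run_ghost_analysis(ScenarioConfig(preset="ghost", seed=1))
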