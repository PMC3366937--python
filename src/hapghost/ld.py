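"""Pairwise linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated by the
standard two-locus EM over the double-heterozygote phase ambiguity, assuming
Hardy-Weinberg equilibrium; D, signed D' and r^2 follow from the fitted
frequencies.  Counted ("A"/"B") alleles are the ALT alleles of the two
genotype columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateLocusError, EmptyRegionError, ValidationError
from .io_formats import MISSING, GenotypeMatrix

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class TwoLocusFreqs:
    """Haplotype frequencies (f_AB, f_Ab, f_aB, f_ab) for two biallelic loci."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float

    def __post_init__(self):
        f = np.array([self.f_AB, self.f_Ab, self.f_aB, self.f_ab])
        if (f < -1e-12).any():
            raise ValidationError("haplotype frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError(f"haplotype frequencies sum to {f.sum()}, not 1")

    @property
    def p_A(self):
        return self.f_AB + self.f_Ab

    @property
    def p_B(self):
        return self.f_AB + self.f_aB


@dataclass(frozen=True)
class LDStats:
    """Gametic disequilibrium D, signed D' and squared correlation r^2."""

    D: float
    d_prime: float
    r2: float


def genotype_table(g1, g2) -> np.ndarray:
    """3x3 joint genotype counts over pairwise-complete samples."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValidationError("genotype columns must cover the same samples")
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    if g1.size < 2:
        raise ValidationError("need at least 2 pairwise non-missing samples")
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (g1.astype(int), g2.astype(int)), 1)
    return table


def two_locus_em(g1, g2, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER) -> TwoLocusFreqs:
    """EM haplotype-frequency estimate for two loci from unphased genotypes.

    Maximizes the HWE multinomial likelihood of the 3x3 genotype table; the
    log-likelihood is non-decreasing across iterations.  Initialization is at
    linkage equilibrium.  Monomorphic loci raise
    :class:`~hapghost.errors.DegenerateLocusError`.
    """
    table = genotype_table(g1, g2)
    return em_from_table(table, tol=tol, max_iter=max_iter)


def em_from_table(table, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER) -> TwoLocusFreqs:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    p_A = (row[1] + 2 * row[2]) / (2 * n)
    p_B = (col[1] + 2 * col[2]) / (2 * n)
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        raise DegenerateLocusError("monomorphic locus: LD undefined")

    # known haplotype contributions from all cells except the double het
    base = np.zeros(4)  # AB, Ab, aB, ab
    cells = {
        (0, 0): [(3, 2)], (0, 1): [(2, 1), (3, 1)], (0, 2): [(2, 2)],
        (1, 0): [(1, 1), (3, 1)], (1, 2): [(0, 1), (2, 1)],
        (2, 0): [(1, 2)], (2, 1): [(0, 1), (1, 1)], (2, 2): [(0, 2)],
    }
    for (i, j), contribs in cells.items():
        for hap, k in contribs:
            base[hap] += table[i, j] * k
    n_dh = table[1, 1]

    f = np.array([p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    for _ in range(max_iter):
        # E-step: resolve double heterozygotes between AB/ab and Ab/aB phase
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        counts = base.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        f_new = counts / (2 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return TwoLocusFreqs(*[float(x) for x in f])


def loglik_from_table(table, freqs: TwoLocusFreqs) -> float:
    """HWE multinomial log-likelihood of a 3x3 genotype table (up to constants)."""
    f_AB, f_Ab, f_aB, f_ab = freqs.f_AB, freqs.f_Ab, freqs.f_aB, freqs.f_ab
    probs = np.array([
        [f_ab ** 2, 2 * f_ab * f_aB, f_aB ** 2],
        [2 * f_Ab * f_ab, 2 * (f_AB * f_ab + f_Ab * f_aB), 2 * f_AB * f_aB],
        [f_Ab ** 2, 2 * f_AB * f_Ab, f_AB ** 2],
    ])
    table = np.asarray(table, dtype=float)
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    lp[table == 0] = 0.0  # 0 * log 0 := 0
    if np.any((table > 0) & ~np.isfinite(lp)):
        return -np.inf
    return float(np.sum(table * lp))


def ld_stats(freqs: TwoLocusFreqs) -> LDStats:
    """D, signed D' and r^2 from fitted two-locus haplotype frequencies."""
    p_A, p_B = freqs.p_A, freqs.p_B
    if min(p_A, p_B) <= 0.0 or max(p_A, p_B) >= 1.0:
        raise DegenerateLocusError("allele frequency at 0 or 1: LD undefined")
    D = freqs.f_AB - p_A * p_B
    if D > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    d_prime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    return LDStats(D=float(D), d_prime=float(d_prime), r2=float(r2))


@dataclass
class LDMatrix:
    """Symmetric pairwise LD over a SNP set, plus r^2 distribution summaries."""

    snp_ids: list
    D: np.ndarray
    d_prime: np.ndarray
    r2: np.ndarray
    median_r2: float
    p90_r2: float

    def to_long(self) -> pd.DataFrame:
        rows = []
        m = len(self.snp_ids)
        for i in range(m):
            for j in range(i + 1, m):
                rows.append((self.snp_ids[i], self.snp_ids[j],
                             self.D[i, j], self.d_prime[i, j], self.r2[i, j]))
        return pd.DataFrame(rows, columns=["snp_i", "snp_j", "D", "Dprime", "r2"])


def ld_matrix(genotypes: GenotypeMatrix, region=None,
              tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER) -> LDMatrix:
    """All-pairs LD for the (polymorphic) SNPs of a genotype matrix.

    ``region`` is an optional ``(chrom, start, end)`` closed interval.
    Summary percentiles (median, 90th) of r^2 are taken over the strict upper
    triangle with linear interpolation between order statistics.
    """
    if region is not None:
        ids = genotypes.region_ids(*region)
        if not ids:
            raise EmptyRegionError(f"no SNPs in region {region}")
        genotypes = genotypes.subset(ids)
    poly = []
    for s in genotypes.snps:
        col = genotypes.column(s.id)
        col = col[col != MISSING]
        if col.size and 0.0 < col.mean() / 2.0 < 1.0:
            poly.append(s.id)
    if len(poly) < 2:
        raise EmptyRegionError("fewer than 2 polymorphic SNPs available")
    gm = genotypes.subset(poly)
    m = gm.n_snps
    D = np.zeros((m, m))
    dp = np.zeros((m, m))
    r2 = np.eye(m)
    np.fill_diagonal(dp, 1.0)
    for i in range(m):
        gi = gm.calls[:, i]
        for j in range(i + 1, m):
            stats = ld_stats(two_locus_em(gi, gm.calls[:, j], tol=tol, max_iter=max_iter))
            D[i, j] = D[j, i] = stats.D
            dp[i, j] = dp[j, i] = stats.d_prime
            r2[i, j] = r2[j, i] = stats.r2
    iu = np.triu_indices(m, k=1)
    upper = r2[iu]
    return LDMatrix(
        snp_ids=poly, D=D, d_prime=dp, r2=r2,
        median_r2=float(np.percentile(upper, 50)),
        p90_r2=float(np.percentile(upper, 90)),
    )
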