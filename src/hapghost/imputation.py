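"""Imputation-dosage quality diagnostics and a minimal tag-based imputer.

Quality is the MACH-style ratio of the empirical dosage variance to the
binomial variance 2p(1-p) of a perfectly observed variant; values above
:data:`QUALITY_MIN` (0.3) are the conventional inclusion filter.  Where true
genotypes are available, concordance is summarized by the Spearman rank
correlation between dose and truth plus per-genotype dose quartiles (the
box-plot view).  ``tag_impute`` is a deliberately simple haplotype-
conditional imputer: it estimates joint (tags, target) haplotype frequencies
from a phased reference panel by counting and returns the HWE posterior
expected target-allele count given each study individual's unphased tag
genotypes.  Its purpose is mechanistic: it shows *why* a rare variant in
weak LD with its neighbours imputes poorly from a small panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import spearmanr

from .errors import DegenerateLocusError, ValidationError
from .io_formats import MISSING, GenotypeMatrix

QUALITY_MIN = 0.3  # conventional imputation-quality inclusion threshold


@dataclass
class QualityReport:
    snp_id: str
    rsq_hat: float          # capped at 1
    rsq_raw: float          # uncapped variance ratio
    maf_hat: float          # dosage-implied minor allele frequency
    spearman_rho: float | None = None


def dosage_quality(dose, snp_id="snp") -> QualityReport:
    """MACH-style imputation quality: Var(dose) / (2 p (1-p)), p = mean(dose)/2.

    The variance uses the population (1/n) denominator.  A fixed dose
    (p in {0, 1}) has undefined quality, reported as NaN.
    """
    dose = np.asarray(dose, dtype=float)
    if dose.size < 2:
        raise ValidationError("need at least 2 samples for dosage quality")
    p = float(dose.mean()) / 2.0
    maf_hat = min(p, 1.0 - p)
    if p <= 0.0 or p >= 1.0:
        return QualityReport(snp_id=snp_id, rsq_hat=float("nan"),
                             rsq_raw=float("nan"), maf_hat=maf_hat)
    raw = float(dose.var() / (2.0 * p * (1.0 - p)))
    return QualityReport(snp_id=snp_id, rsq_hat=min(raw, 1.0), rsq_raw=raw, maf_hat=maf_hat)


@dataclass
class ConcordanceReport:
    spearman_rho: float
    n: int
    # per truth class (0/1/2): (q1, median, q3, count); classes with < 2
    # observations are excluded
    box_summary: dict = field(default_factory=dict)


def concordance(dose, truth) -> ConcordanceReport:
    """Spearman correlation (average ranks for ties) between imputed dose and
    true genotype, with per-genotype dose quartiles."""
    dose = np.asarray(dose, dtype=float)
    truth = np.asarray(truth)
    if dose.shape != truth.shape:
        raise ValidationError("dose and truth must cover the same samples")
    keep = (truth != MISSING) & np.isfinite(dose)
    dose, truth = dose[keep], truth[keep]
    if dose.size < 3:
        raise ValidationError("need at least 3 overlapping non-missing samples")
    if np.ptp(truth) == 0:
        raise DegenerateLocusError("constant truth genotype: correlation undefined")
    rho = float(spearmanr(dose, truth).statistic)
    box = {}
    for g in (0, 1, 2):
        vals = dose[truth == g]
        if vals.size >= 2:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            box[g] = (float(q1), float(med), float(q3), int(vals.size))
    return ConcordanceReport(spearman_rho=rho, n=int(dose.size), box_summary=box)


@dataclass
class TagImputeResult:
    dose: np.ndarray
    quality: QualityReport
    panel_target_freq: float
    n_fallback: int          # study tag-haplotype configurations absent from the panel


def tag_impute(panel_tags, panel_target, study: GenotypeMatrix | np.ndarray,
               snp_id="imputed") -> TagImputeResult:
    """Impute a target variant from unphased tag genotypes via a phased panel.

    ``panel_tags``: H x T array of phased panel haplotypes over the tag SNPs
    (0/1 alleles); ``panel_target``: length-H target alleles on the same
    haplotypes.  ``study``: n x T unphased tag genotypes (or a
    GenotypeMatrix over the tags).

    Joint haplotype frequencies are counted from the panel; per tag
    haplotype h the conditional target-allele probability is
    q_h = count(h, target=1)/count(h).  Each study individual's dose is the
    HWE posterior expectation of q_h1 + q_h2 over tag-haplotype pairs
    compatible with their genotypes.  Tag haplotypes seen in the study but
    absent from the panel contribute the panel target allele frequency (with
    a pseudo-frequency weight); such fallbacks are counted and reported.
    """
    panel_tags = np.asarray(panel_tags, dtype=np.int8)
    panel_target = np.asarray(panel_target, dtype=np.int8)
    H, T = panel_tags.shape
    if panel_target.shape != (H,):
        raise ValidationError("panel target must have one allele per panel haplotype")
    p_target = float(panel_target.mean())
    if p_target in (0.0, 1.0):
        raise DegenerateLocusError("panel is monomorphic at the target")

    calls = study.calls if isinstance(study, GenotypeMatrix) else np.asarray(study)
    if calls.shape[1] != T:
        raise ValidationError("study tag count does not match panel")

    # panel haplotype catalogue
    keys = [tuple(row) for row in panel_tags]
    freq, carry = {}, {}
    for k, a in zip(keys, panel_target):
        freq[k] = freq.get(k, 0) + 1
        carry[k] = carry.get(k, 0) + int(a)
    total = float(H)
    eps = 0.5 / total  # pseudo-frequency for unseen tag haplotypes

    site_pairs = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)],
                  MISSING: [(0, 0), (0, 1), (1, 0), (1, 1)]}

    uniq, inverse = np.unique(calls, axis=0, return_inverse=True)
    doses = np.empty(len(uniq))
    n_fallback = 0
    for u, row in enumerate(uniq):
        num = den = 0.0
        used_fallback = False
        for combo in product(*[site_pairs[int(g)] for g in row]):
            h1 = tuple(c[0] for c in combo)
            h2 = tuple(c[1] for c in combo)
            f1 = freq.get(h1, 0) / total
            f2 = freq.get(h2, 0) / total
            q1 = carry[h1] / freq[h1] if h1 in freq else p_target
            q2 = carry[h2] / freq[h2] if h2 in freq else p_target
            if h1 not in freq:
                f1, used_fallback = eps, True
            if h2 not in freq:
                f2, used_fallback = eps, True
            w = f1 * f2
            num += w * (q1 + q2)
            den += w
        doses[u] = num / den if den > 0 else 2.0 * p_target
        if used_fallback:
            n_fallback += int(np.sum(inverse == u))
    dose = np.clip(doses[inverse], 0.0, 2.0)
    quality = (dosage_quality(dose, snp_id=snp_id) if dose.size >= 2
               else QualityReport(snp_id=snp_id, rsq_hat=float("nan"),
                                  rsq_raw=float("nan"), maf_hat=float("nan")))
    return TagImputeResult(
        dose=dose,
        quality=quality,
        panel_target_freq=p_target,
        n_fallback=n_fallback,
    )
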