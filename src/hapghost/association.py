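"""Single-SNP case-control association.

Covers the analyses a dosage-based GWAS runs per SNP: logistic regression of
case/control status on imputed allele dosage with covariate adjustment
(default reported p-value from the likelihood-ratio test, Wald retained for
meta-analysis), conditional analyses with other SNPs entered as covariates,
the Cochran-Armitage trend test on genotype-count tables, allelic odds
ratios with Woolf confidence intervals, and minor-allele frequencies.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm

from ._logistic import fit_logistic, lrt_pvalue
from .errors import (
    CollinearityError,
    DegeneratePredictorError,
    ValidationError,
)
from .io_formats import PhenotypeTable

COLLINEARITY_R2 = 1.0 - 1e-8


@dataclass
class AssociationResult:
    """Per-SNP effect on the log-odds scale, per copy of the counted allele."""

    snp_id: str
    log_or: float
    se: float
    p: float
    test: str = "lrt"
    p_wald: float | None = None
    p_lrt: float | None = None
    conditioned_on: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    n: int = 0

    @property
    def odds_ratio(self):
        return float(np.exp(self.log_or))

    def ci(self, level=0.95):
        z = norm.ppf(0.5 + level / 2.0)
        return (float(np.exp(self.log_or - z * self.se)),
                float(np.exp(self.log_or + z * self.se)))


@dataclass(frozen=True)
class GenotypeTable2x3:
    """Genotype counts (AA, Aa, aa) for controls and cases, in minor-allele
    count order (0, 1, 2 copies)."""

    control_counts: tuple
    case_counts: tuple

    def __post_init__(self):
        for row in (self.control_counts, self.case_counts):
            if len(row) != 3 or any(c < 0 for c in row):
                raise ValidationError("genotype rows must be 3 non-negative counts")
            if sum(row) == 0:
                raise ValidationError("empty genotype row")

    def allele_2x2(self):
        """Collapse to allele counts: rows (controls, cases), cols (major, minor)."""
        out = np.zeros((2, 2), dtype=np.int64)
        for i, row in enumerate((self.control_counts, self.case_counts)):
            out[i, 0] = 2 * row[0] + row[1]
            out[i, 1] = row[1] + 2 * row[2]
        return out


def _design(dose, phenotype: PhenotypeTable, covariates, extra=None):
    dose = np.asarray(dose, dtype=float)
    if dose.shape != (len(phenotype.samples),):
        raise ValidationError("dose column does not match phenotype samples")
    cols = [np.ones_like(dose), dose]
    names = ["intercept", "dose"]
    cov = phenotype.covariate_matrix(covariates)
    for k, name in enumerate(covariates):
        cols.append(cov[:, k])
        names.append(name)
    if extra is not None:
        for name, col in extra:
            cols.append(np.asarray(col, dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def dose_logistic(dose, phenotype: PhenotypeTable, covariates=(), snp_id="snp",
                  test="lrt") -> AssociationResult:
    """Logistic regression of status on an allele dosage (0..2) with covariates.

    Returns the per-copy log-OR with its observed-information (Wald) standard
    error; the default reported p is the likelihood-ratio test of the dosage
    term, with the Wald p retained alongside.
    """
    covariates = list(covariates)
    y = phenotype.status
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValidationError("need at least one case and one control")
    dose = np.asarray(dose, dtype=float)
    if np.ptp(dose) == 0.0:
        raise DegeneratePredictorError(f"{snp_id}: constant dose column")
    X, _ = _design(dose, phenotype, covariates)
    fit = fit_logistic(X, y)
    null = fit_logistic(np.delete(X, 1, axis=1), y)
    _, p_lrt = lrt_pvalue(fit.loglik, null.loglik, df=1)
    beta, se = float(fit.beta[1]), float(fit.se[1])
    p_wald = float(2.0 * norm.sf(abs(beta / se)))
    return AssociationResult(
        snp_id=snp_id, log_or=beta, se=se,
        p=p_lrt if test == "lrt" else p_wald, test=test,
        p_wald=p_wald, p_lrt=p_lrt,
        covariates=covariates, n=len(y),
    )


def conditional_logistic(target_dose, adjust_doses, phenotype: PhenotypeTable,
                         covariates=(), snp_id="snp", adjust_ids=None,
                         test="lrt") -> AssociationResult:
    """Association of ``target_dose`` with the adjustment columns entered as
    covariates (conditional analysis).

    ``adjust_doses`` is one column or a list of columns aligned to the
    phenotype samples; mixed sources (e.g. imputed dose in controls, hard
    genotype in cases) are supported by passing the merged column.  A target
    that is numerically collinear with the adjustment set (R^2 > 1 - 1e-8)
    raises :class:`~hapghost.errors.CollinearityError`.  Constant adjustment
    columns carry no information and are dropped.
    """
    covariates = list(covariates)
    adjust = np.asarray(adjust_doses, dtype=float)
    if adjust.ndim == 1:
        adjust = adjust[:, None]
    else:
        adjust = adjust.T if adjust.shape[0] != len(phenotype.samples) else adjust
    if adjust_ids is None:
        adjust_ids = [f"adjust{k}" for k in range(adjust.shape[1])]
    keep = [k for k in range(adjust.shape[1]) if np.ptp(adjust[:, k]) > 0]
    adjust = adjust[:, keep]
    adjust_ids_kept = [adjust_ids[k] for k in keep]

    target = np.asarray(target_dose, dtype=float)
    if adjust.shape[1]:
        # R^2 of the target on the adjustment set
        A = np.column_stack([np.ones(len(target)), adjust])
        resid = target - A @ np.linalg.lstsq(A, target, rcond=None)[0]
        tot = np.sum((target - target.mean()) ** 2)
        if tot > 0 and 1.0 - resid @ resid / tot > COLLINEARITY_R2:
            raise CollinearityError(
                f"{snp_id}: target is collinear with adjustment set {adjust_ids_kept}"
            )
    extra = [(adjust_ids_kept[k], adjust[:, k]) for k in range(adjust.shape[1])]
    X, _ = _design(target, phenotype, covariates, extra=extra)
    y = phenotype.status
    fit = fit_logistic(X, y)
    null = fit_logistic(np.delete(X, 1, axis=1), y)
    _, p_lrt = lrt_pvalue(fit.loglik, null.loglik, df=1)
    beta, se = float(fit.beta[1]), float(fit.se[1])
    p_wald = float(2.0 * norm.sf(abs(beta / se)))
    return AssociationResult(
        snp_id=snp_id, log_or=beta, se=se,
        p=p_lrt if test == "lrt" else p_wald, test=test,
        p_wald=p_wald, p_lrt=p_lrt,
        conditioned_on=list(adjust_ids), covariates=covariates, n=len(y),
    )


@dataclass(frozen=True)
class TrendResult:
    z: float
    chi2: float
    p: float


def trend_test(table: GenotypeTable2x3) -> TrendResult:
    """Cochran-Armitage trend test with scores (0, 1, 2).

    Z = sum_j s_j (r_j - R n_j / N) / sqrt((R(N-R)/N^2) * (N sum n_j s_j^2 -
    (sum n_j s_j)^2) / N); two-sided p from the normal distribution.
    """
    s = np.array([0.0, 1.0, 2.0])
    r = np.asarray(table.case_counts, dtype=float)       # cases per genotype
    n = r + np.asarray(table.control_counts, dtype=float)
    N = n.sum()
    R = r.sum()
    num = float(np.sum(s * (r - R * n / N)))
    var = (R * (N - R) / N ** 2) * (np.sum(n * s ** 2) - (np.sum(n * s)) ** 2 / N)
    if var <= 0:
        return TrendResult(z=0.0, chi2=0.0, p=1.0)
    z = num / np.sqrt(var)
    return TrendResult(z=float(z), chi2=float(z * z), p=float(2.0 * norm.sf(abs(z))))


@dataclass(frozen=True)
class AllelicOR:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def allelic_or(table: GenotypeTable2x3, continuity=False, level=0.95) -> AllelicOR:
    """Allelic odds ratio from the collapsed 2x2 allele table.

    Woolf (log-scale) confidence interval exp(ln OR +/- z * sqrt(sum 1/cell));
    p from the log-scale Wald Z.  A zero cell raises a validation error unless
    ``continuity=True`` adds 0.5 to every cell.
    """
    t = table.allele_2x2().astype(float)
    if (t == 0).any():
        if not continuity:
            raise ValidationError(
                "zero allele-count cell; re-run with continuity=True to add 0.5 to each cell"
            )
        t = t + 0.5
    # rows: controls, cases; cols: major, minor
    or_ = (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])
    se = float(np.sqrt((1.0 / t).sum()))
    z = norm.ppf(0.5 + level / 2.0)
    log_or = float(np.log(or_))
    return AllelicOR(
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p=float(2.0 * norm.sf(abs(log_or / se))),
    )


def maf(counts) -> float:
    """Counted-allele frequency from a genotype-count triple (AA, Aa, aa):
    (het + 2 * hom_minor) / (2 n).  May exceed 0.5 if the counted allele is
    actually major; see :func:`fold_maf`."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3,) or counts.sum() <= 0:
        raise ValidationError("need a genotype-count triple with positive total")
    return float((counts[1] + 2 * counts[2]) / (2 * counts.sum()))


def fold_maf(counts):
    """Minor-allele frequency folded into [0, 0.5].

    Returns ``(maf, flipped)`` where ``flipped`` is True when the counted
    allele was the major one (frequency > 0.5), i.e. allele orientation was
    reversed to report a true MAF."""
    f = maf(counts)
    if f > 0.5:
        return 1.0 - f, True
    return f, False


def score_trend_chi2(table: GenotypeTable2x3) -> float:
    """Score-test chi^2 of the genotype-scored logistic model (equals the
    Cochran-Armitage chi^2); exposed for cross-checking."""
    t = trend_test(table)
    return t.chi2
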