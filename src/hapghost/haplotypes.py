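"""Multi-SNP haplotype inference and haplotype-based association.

Haplotype frequencies over a small SNP subset (k <= 12) are estimated from
unphased genotypes under Hardy-Weinberg equilibrium, either by deterministic
EM (monotone in the multinomial log-likelihood) or by the stochastic EM
(SEM) variant, in which each iteration samples one compatible haplotype pair
per individual from the current posterior and re-counts; the SEM point
estimate is the mean over post-burn-in iterations.

Haplotype effects on case/control status are fitted by
expectation-substitution logistic regression: each individual's posterior
*expected* count of haplotype h (0..2) enters a plain logistic model as a
dosage, with the most frequent haplotype as reference, rare haplotypes
pooled, a Wald OR per non-reference haplotype, and a likelihood-ratio global
test with (modelled haplotypes - 1) degrees of freedom.

``aic_scan`` reproduces the exhaustive model-selection strategy: every SNP
subset of size 1..4 in a region is fitted, models within 2 rescaled-AIC
units of the best are deemed equivalent, and the most parsimonious
equivalent model (fewest SNPs, then fewest haplotypes, then leftmost
positions) wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._logistic import fit_logistic, lrt_pvalue
from .errors import (
    CapacityError,
    CollinearityError,
    ConvergenceError,
    EmptyRegionError,
    ValidationError,
)
from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable

MAX_SNPS = 12
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000
PRUNE_THRESHOLD = 1e-4   # haplotypes dropped from the EM enumeration
POOL_THRESHOLD = 0.01    # haplotypes pooled into one term in the disease model

_SITE_PAIRS = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)],
               MISSING: [(0, 0), (0, 1), (1, 0), (1, 1)]}


class PhasePosterior:
    """Posterior distribution over compatible ordered haplotype pairs.

    Stores a sparse (unique-genotype-row, pair) structure so per-sample
    expected haplotype counts and pair posteriors can be materialized on
    demand.  Per-sample posteriors sum to 1 and expected counts sum to 2.
    """

    def __init__(self, haplotypes, freqs, pair_row, pair_h1, pair_h2,
                 post, row_of_sample, n_rows):
        self.haplotypes = haplotypes        # H x k alleles (0/1)
        self.freqs = freqs                  # length H
        self._pair_row = pair_row
        self._pair_h1 = pair_h1
        self._pair_h2 = pair_h2
        self._post = post                   # posterior per (row, pair) entry
        self._row_of_sample = row_of_sample  # -1 for skipped (all-missing) samples
        self._n_rows = n_rows

    @property
    def n_haplotypes(self):
        return len(self.freqs)

    def expected_counts(self) -> np.ndarray:
        """n_samples x H posterior expected haplotype counts (rows sum to 2).

        Samples skipped during inference (all calls missing) receive their
        prior expectation 2 * freqs.
        """
        H = self.n_haplotypes
        per_row = np.zeros((self._n_rows, H))
        np.add.at(per_row, (self._pair_row, self._pair_h1), self._post)
        np.add.at(per_row, (self._pair_row, self._pair_h2), self._post)
        out = np.empty((len(self._row_of_sample), H))
        known = self._row_of_sample >= 0
        out[known] = per_row[self._row_of_sample[known]]
        out[~known] = 2.0 * self.freqs
        return out

    def sample_pairs(self, i):
        """[(h1_index, h2_index, probability), ...] for sample i (ordered pairs)."""
        r = self._row_of_sample[i]
        if r < 0:
            raise ValidationError(f"sample {i} was skipped (all genotypes missing)")
        sel = self._pair_row == r
        return list(zip(self._pair_h1[sel], self._pair_h2[sel], self._post[sel]))


@dataclass
class HaplotypeFreqs:
    """EM/SEM output: haplotype catalogue, frequencies and phase posterior."""

    haplotypes: np.ndarray          # H x k
    freqs: np.ndarray               # length H, sums to 1
    posterior: PhasePosterior
    loglik: float
    n_iter: int
    converged: bool
    n_skipped: int = 0
    mc_se: np.ndarray | None = None  # SEM only: Monte-Carlo se per haplotype

    def labels(self, snps=None):
        """Allele-string labels, using SNP ref/alt letters when provided."""
        out = []
        for hap in self.haplotypes:
            if snps is not None:
                out.append("".join(s.alt_allele if a else s.ref_allele
                                   for s, a in zip(snps, hap)))
            else:
                out.append("".join(str(int(a)) for a in hap))
        return out


def _as_calls(genotypes):
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.calls, genotypes.snps
    return np.asarray(genotypes, dtype=np.int8), None


def _pair_structure(calls):
    """Sparse enumeration of ordered compatible haplotype pairs per unique row."""
    n, k = calls.shape
    if k > MAX_SNPS:
        raise CapacityError(f"{k} SNPs exceed the {MAX_SNPS}-SNP haplotype capacity")
    all_missing = (calls == MISSING).all(axis=1)
    kept = ~all_missing
    uniq, inverse = np.unique(calls[kept], axis=0, return_inverse=True)
    row_of_sample = np.full(n, -1, dtype=np.int64)
    row_of_sample[kept] = inverse
    row_counts = np.bincount(inverse, minlength=len(uniq)).astype(float)

    hap_index = {}
    haps = []

    def hap_id(h):
        if h not in hap_index:
            hap_index[h] = len(haps)
            haps.append(h)
        return hap_index[h]

    pair_row, pair_h1, pair_h2 = [], [], []
    for r, row in enumerate(uniq):
        for combo in product(*[_SITE_PAIRS[int(g)] for g in row]):
            h1 = tuple(c[0] for c in combo)
            h2 = tuple(c[1] for c in combo)
            pair_row.append(r)
            pair_h1.append(hap_id(h1))
            pair_h2.append(hap_id(h2))
    return (np.array(pair_row), np.array(pair_h1), np.array(pair_h2),
            np.array(haps, dtype=np.int8), row_counts, row_of_sample,
            int(all_missing.sum()))


def _em_core(pair_row, pair_h1, pair_h2, row_counts, f0, tol, max_iter,
             prune_threshold):
    """Run EM; returns (freqs, loglik, n_iter, converged, keep_mask, posterior)."""
    n_rows = len(row_counts)
    n_eff = row_counts.sum()
    f = f0.copy()
    active = np.ones(len(f), dtype=bool)
    keep_pairs = np.ones(len(pair_row), dtype=bool)
    loglik = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.where(keep_pairs, f[pair_h1] * f[pair_h2], 0.0)
        s_row = np.bincount(pair_row, weights=w, minlength=n_rows)
        post = w / s_row[pair_row]
        weighted = post * row_counts[pair_row]
        counts = (np.bincount(pair_h1, weights=weighted, minlength=len(f))
                  + np.bincount(pair_h2, weights=weighted, minlength=len(f)))
        f_new = counts / (2.0 * n_eff)
        loglik = float(np.sum(row_counts * np.log(s_row)))
        trace.append(loglik)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
        # prune vanishing haplotypes, but never empty a genotype row
        if prune_threshold > 0:
            prune = active & (f < prune_threshold) & (f > 0)
            if prune.any():
                cand = keep_pairs & ~(prune[pair_h1] | prune[pair_h2])
                alive = np.bincount(pair_row[cand], minlength=n_rows)
                if (alive > 0).all():
                    keep_pairs = cand
                    active &= ~prune
                    f = np.where(prune, 0.0, f)
                    tot = f.sum()
                    if tot > 0:
                        f = f / tot
    w = np.where(keep_pairs, f[pair_h1] * f[pair_h2], 0.0)
    s_row = np.bincount(pair_row, weights=w, minlength=n_rows)
    post = np.where(s_row[pair_row] > 0, w / s_row[pair_row], 0.0)
    loglik = float(np.sum(row_counts * np.log(s_row)))
    return f, loglik, it, converged, post, trace


def em_haplotypes(genotypes, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER,
                  prune_threshold=PRUNE_THRESHOLD) -> HaplotypeFreqs:
    """Deterministic EM haplotype-frequency estimation under HWE.

    The log-likelihood is non-decreasing across iterations; haplotypes whose
    frequency falls below ``prune_threshold`` are dropped from the
    enumeration between iterations (unless that would leave a genotype row
    with no compatible pair).  Samples with all calls missing are skipped and
    counted in ``n_skipped``.
    """
    calls, _ = _as_calls(genotypes)
    if calls.shape[0] - int((calls == MISSING).all(axis=1).sum()) < 2:
        raise ValidationError("need at least 2 samples with observed genotypes")
    (pair_row, pair_h1, pair_h2, haps, row_counts,
     row_of_sample, n_skipped) = _pair_structure(calls)
    # initialize at linkage equilibrium from observed allele frequencies
    k = calls.shape[1]
    p = np.empty(k)
    for j in range(k):
        col = calls[:, j]
        col = col[col != MISSING]
        p[j] = col.mean() / 2.0 if col.size else 0.5
    f0 = np.array([np.prod(np.where(h == 1, p, 1 - p)) for h in haps])
    f0 = np.clip(f0, 1e-12, None)
    f0 /= f0.sum()
    f, loglik, it, converged, post, trace = _em_core(
        pair_row, pair_h1, pair_h2, row_counts, f0, tol, max_iter, prune_threshold)
    posterior = PhasePosterior(haps, f, pair_row, pair_h1, pair_h2, post,
                               row_of_sample, len(row_counts))
    out = HaplotypeFreqs(haplotypes=haps, freqs=f, posterior=posterior,
                         loglik=loglik, n_iter=it, converged=converged,
                         n_skipped=n_skipped)
    out.loglik_trace = trace
    return out


def sem_haplotypes(genotypes, n_iter=500, burn_in=100, seed=None,
                   prune_threshold=PRUNE_THRESHOLD) -> HaplotypeFreqs:
    """Stochastic EM: the E-step samples one compatible haplotype pair per
    individual; the M-step sets frequencies to sampled counts / 2n.

    The returned frequencies are the mean over post-burn-in iterations, with
    a naive Monte-Carlo standard error (iteration sd / sqrt(kept));
    ``seed`` is mandatory so runs are reproducible.
    """
    if seed is None:
        raise ValidationError("sem_haplotypes requires an explicit seed")
    if burn_in >= n_iter:
        raise ValidationError("burn_in must be smaller than n_iter")
    calls, _ = _as_calls(genotypes)
    (pair_row, pair_h1, pair_h2, haps, row_counts,
     row_of_sample, n_skipped) = _pair_structure(calls)
    rng = np.random.default_rng(seed)
    n_rows = len(row_counts)
    n_eff = row_counts.sum()
    H = len(haps)
    # start from the linkage-equilibrium initialization as in the EM
    k = calls.shape[1]
    p = np.empty(k)
    for j in range(k):
        col = calls[:, j]
        col = col[col != MISSING]
        p[j] = col.mean() / 2.0 if col.size else 0.5
    f = np.array([np.prod(np.where(h == 1, p, 1 - p)) for h in haps])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    # per-row entry slices (pair_row is sorted by construction)
    starts = np.searchsorted(pair_row, np.arange(n_rows))
    stops = np.searchsorted(pair_row, np.arange(n_rows) + 1)

    kept = []
    for _ in range(n_iter):
        w = f[pair_h1] * f[pair_h2]
        counts = np.zeros(H)
        for r in range(n_rows):
            sl = slice(starts[r], stops[r])
            pr = w[sl]
            tot = pr.sum()
            pr = pr / tot if tot > 0 else np.full(len(pr), 1.0 / len(pr))
            draw = rng.multinomial(int(row_counts[r]), pr)
            np.add.at(counts, pair_h1[sl], draw)
            np.add.at(counts, pair_h2[sl], draw)
        f = counts / (2.0 * n_eff)
        kept.append(f.copy())
    kept = np.array(kept[burn_in:])
    f_hat = kept.mean(axis=0)
    mc_se = kept.std(axis=0, ddof=1) / np.sqrt(len(kept))
    # posterior and log-likelihood evaluated at the SEM point estimate
    fsafe = np.clip(f_hat, 0.0, None)
    w = fsafe[pair_h1] * fsafe[pair_h2]
    s_row = np.bincount(pair_row, weights=w, minlength=n_rows)
    post = np.where(s_row[pair_row] > 0, w / s_row[pair_row], 0.0)
    with np.errstate(divide="ignore"):
        loglik = float(np.sum(row_counts * np.log(np.clip(s_row, 1e-300, None))))
    posterior = PhasePosterior(haps, f_hat, pair_row, pair_h1, pair_h2, post,
                               row_of_sample, n_rows)
    return HaplotypeFreqs(haplotypes=haps, freqs=f_hat, posterior=posterior,
                          loglik=loglik, n_iter=n_iter, converged=True,
                          n_skipped=n_skipped, mc_se=mc_se)


@dataclass
class HaplotypeEffect:
    haplotype: str
    freq: float
    control_freq: float
    case_freq: float
    log_or: float
    se: float
    p: float

    @property
    def odds_ratio(self):
        return float(np.exp(self.log_or))

    def ci(self, level=0.95):
        z = norm.ppf(0.5 + level / 2.0)
        return (float(np.exp(self.log_or - z * self.se)),
                float(np.exp(self.log_or + z * self.se)))


@dataclass
class HaplotypeModel:
    """Fitted haplotype-effect logistic model over one SNP subset."""

    snp_ids: list
    haplotypes: list                 # labels of modelled haplotypes (incl. reference)
    freqs: dict                      # label -> overall frequency
    control_freqs: dict
    case_freqs: dict
    reference: str
    effects: list                    # HaplotypeEffect per non-reference term
    pooled: list                     # labels pooled into the rare term (possibly empty)
    loglik: float
    aic: float
    k_params: int
    global_chi2: float
    global_df: int
    global_p: float
    covariates: list = field(default_factory=list)
    conditioned_on: list = field(default_factory=list)

    @property
    def n_modelled(self):
        return len(self.effects) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [{"haplotype": self.reference, "freq_controls":
                 self.control_freqs.get(self.reference), "freq_cases":
                 self.case_freqs.get(self.reference), "OR": 1.0, "ci_low": None,
                 "ci_high": None, "p": None, "term": "reference"}]
        for e in self.effects:
            lo, hi = e.ci()
            rows.append({"haplotype": e.haplotype, "freq_controls": e.control_freq,
                         "freq_cases": e.case_freq, "OR": e.odds_ratio,
                         "ci_low": lo, "ci_high": hi, "p": e.p, "term": "effect"})
        return pd.DataFrame(rows)


RARE_LABEL = "rare-pooled"


def haplotype_logistic(haps: HaplotypeFreqs, phenotype: PhenotypeTable,
                       covariates=(), pool_threshold=POOL_THRESHOLD,
                       snps=None, extra_covariates=(),
                       conditioned_on=()) -> HaplotypeModel:
    """Expectation-substitution haplotype logistic regression.

    logit P(case) = a + sum_{h != ref} b_h E[n_h | genotype] + c'covariates,
    with the posterior expected count E[n_h|.] in [0, 2] as the haplotype
    dosage.  The reference is the most frequent haplotype (ties broken
    lexicographically, with a warning); haplotypes rarer than
    ``pool_threshold`` are merged into one pooled term.  The global test is
    the LRT of all haplotype effects jointly, df = modelled haplotypes - 1.
    """
    covariates = list(covariates)
    E = haps.posterior.expected_counts()
    labels = haps.labels(snps)
    f = haps.freqs
    y = phenotype.status
    if E.shape[0] != len(y):
        raise ValidationError("phase posterior does not match phenotype samples")

    present = np.where(f > 0)[0]
    modelled = [int(j) for j in present if f[j] >= pool_threshold]
    pooled = [int(j) for j in present if f[j] < pool_threshold]
    if not modelled:
        raise ValidationError("no haplotype reaches the pooling threshold")
    top = max(f[modelled])
    ties = sorted([j for j in modelled if f[j] == top], key=lambda j: labels[j])
    if len(ties) > 1:
        warnings.warn("reference haplotype tie resolved lexicographically")
    ref = ties[0]

    cols, col_labels = [], []
    for j in modelled:
        if j != ref:
            cols.append(E[:, j])
            col_labels.append(labels[j])
    if pooled:
        cols.append(E[:, pooled].sum(axis=1))
        col_labels.append(RARE_LABEL)

    cov = phenotype.covariate_matrix(covariates)
    extra_names = [name for name, _ in extra_covariates]
    extra_cols = [np.asarray(c, dtype=float) for name, c in extra_covariates
                  if np.ptp(np.asarray(c, dtype=float)) > 0]
    extra_names = [name for name, c in extra_covariates
                   if np.ptp(np.asarray(c, dtype=float)) > 0]
    n = len(y)
    X_null = np.column_stack([np.ones(n), cov] + extra_cols) if (len(covariates) or extra_cols) \
        else np.ones((n, 1))
    X_full = np.column_stack([X_null] + cols)

    fit = fit_logistic(X_full, y)
    null = fit_logistic(X_null, y)
    df = len(cols)
    chi2_stat, global_p = lrt_pvalue(fit.loglik, null.loglik, df)

    ctrl = y == 0
    case = y == 1
    control_freq = E[ctrl].mean(axis=0) / 2.0
    case_freq = E[case].mean(axis=0) / 2.0

    off = X_null.shape[1]
    effects = []
    for c, lab in enumerate(col_labels):
        beta = float(fit.beta[off + c])
        se = float(fit.se[off + c])
        if lab == RARE_LABEL:
            fr = float(f[pooled].sum())
            cf = float(control_freq[pooled].sum())
            af = float(case_freq[pooled].sum())
        else:
            j = labels.index(lab)
            fr, cf, af = float(f[j]), float(control_freq[j]), float(case_freq[j])
        effects.append(HaplotypeEffect(
            haplotype=lab, freq=fr, control_freq=cf, case_freq=af,
            log_or=beta, se=se, p=float(2.0 * norm.sf(abs(beta / se)))))

    model_labels = [labels[j] for j in modelled] + ([RARE_LABEL] if pooled else [])
    freqs = {labels[j]: float(f[j]) for j in modelled}
    cfr = {labels[j]: float(control_freq[j]) for j in modelled}
    afr = {labels[j]: float(case_freq[j]) for j in modelled}
    if pooled:
        freqs[RARE_LABEL] = float(f[pooled].sum())
        cfr[RARE_LABEL] = float(control_freq[pooled].sum())
        afr[RARE_LABEL] = float(case_freq[pooled].sum())

    # AIC counts every free parameter the model estimates: regression
    # coefficients plus the (active haplotypes - 1) frequency parameters the
    # EM fitted.  Penalizing frequencies matters for cross-subset model
    # selection: without it, superset models are under-penalized and the
    # parsimony rule loses its bite.
    n_freq = max(int((f > 0).sum()) - 1, 0)
    k = X_full.shape[1] + n_freq
    return HaplotypeModel(
        snp_ids=[s.id for s in snps] if snps is not None else
                [f"snp{j}" for j in range(haps.haplotypes.shape[1])],
        haplotypes=model_labels, freqs=freqs, control_freqs=cfr, case_freqs=afr,
        reference=labels[ref], effects=effects,
        pooled=[labels[j] for j in pooled],
        loglik=float(fit.loglik), aic=float(2 * k - 2 * fit.loglik), k_params=k,
        global_chi2=float(chi2_stat), global_df=df, global_p=float(global_p),
        covariates=covariates, conditioned_on=list(conditioned_on),
    )


def haplotype_conditional(haps: HaplotypeFreqs, phenotype: PhenotypeTable,
                          adjust_dose, covariates=(), snps=None,
                          pool_threshold=POOL_THRESHOLD,
                          adjust_id="adjustment") -> HaplotypeModel:
    """Haplotype logistic model with an adjustment dosage entered as a
    covariate (constant adjustment columns are dropped, leaving the
    unadjusted fit)."""
    adjust = np.asarray(adjust_dose, dtype=float)
    if adjust.ndim == 1:
        extra = [(adjust_id, adjust)]
    else:
        extra = [(f"{adjust_id}{k}", adjust[:, k]) for k in range(adjust.shape[1])]
    return haplotype_logistic(haps, phenotype, covariates=covariates,
                              pool_threshold=pool_threshold, snps=snps,
                              extra_covariates=extra,
                              conditioned_on=[adjust_id])


@dataclass
class ScanResult:
    """Exhaustive 1..max_size SNP-subset scan ranked by rescaled AIC."""

    table: pd.DataFrame          # one row per model: snps, size, n_haps, aic, delta_aic, ...
    best_snps: list
    best_model: HaplotypeModel
    equivalence: pd.DataFrame    # models with delta_aic <= 2

    @property
    def n_models(self):
        return len(self.table)


def aic_scan(genotypes: GenotypeMatrix, phenotype: PhenotypeTable, region=None,
             max_size=4, covariates=(), scan_cap=25,
             pool_threshold=POOL_THRESHOLD, tol=DEFAULT_TOL,
             max_iter=DEFAULT_MAX_ITER) -> ScanResult:
    """Fit every haplotype model over 1..max_size SNPs and select the most
    parsimonious model within 2 rescaled-AIC units of the best.

    AIC = 2k - 2 loglik with k counting every estimated parameter (intercept,
    covariates, haplotype effects and haplotype frequencies); the covariate
    count is constant across models so it does not affect ranking.
    Winner: fewest SNPs within the equivalence set,
    ties broken by fewest modelled haplotypes, then leftmost positions.
    """
    if region is not None:
        ids = genotypes.region_ids(*region)
        if not ids:
            raise EmptyRegionError(f"no SNPs in region {region}")
        genotypes = genotypes.subset(ids)
    order = np.argsort([s.pos for s in genotypes.snps], kind="stable")
    genotypes = genotypes.subset([genotypes.snps[j].id for j in order])
    m = genotypes.n_snps
    if m > scan_cap:
        raise CapacityError(
            f"{m} region SNPs exceed scan_cap={scan_cap}; raise the cap or pre-filter"
        )
    rows = []
    fits = {}
    for size in range(1, max_size + 1):
        for subset in combinations(range(m), size):
            sub = genotypes.subset([genotypes.snps[j].id for j in subset])
            haps = em_haplotypes(sub, tol=tol, max_iter=max_iter)
            if int((haps.freqs >= pool_threshold).sum()) < 2:
                continue  # no haplotype contrast to model
            try:
                model = haplotype_logistic(haps, phenotype, covariates=covariates,
                                           pool_threshold=pool_threshold, snps=sub.snps)
            except (ConvergenceError, CollinearityError):
                continue  # separated or degenerate model: not a usable candidate
            key = tuple(subset)
            fits[key] = model
            rows.append({
                "snps": ",".join(sub.snp_ids), "size": size,
                "positions": tuple(s.pos for s in sub.snps),
                "n_haplotypes": model.n_modelled, "loglik": model.loglik,
                "aic": model.aic, "global_p": model.global_p, "_key": key,
            })
    if not rows:
        raise ValidationError("no polymorphic SNP subset could be modelled")
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    equiv = table[table["delta_aic"] <= 2.0].copy()
    equiv = equiv.sort_values(["size", "n_haplotypes", "positions"],
                              kind="stable").reset_index(drop=True)
    best_key = equiv.iloc[0]["_key"]
    best_model = fits[best_key]
    out_cols = [c for c in table.columns if c != "_key"]
    return ScanResult(table=table[out_cols + ["_key"]].drop(columns="_key"),
                      best_snps=list(equiv.iloc[0]["snps"].split(",")),
                      best_model=best_model,
                      equivalence=equiv[out_cols])
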