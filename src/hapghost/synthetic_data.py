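"""Synthetic case-control cohorts with a long-range "ghost" association.

The generator emulates the statistical anatomy of a spurious imputed GWAS
hit: a rare causal variant (FII G20210A-like, population allele frequency
0.02, OR 3) sits ~0.6-1.3 Mb away from a 12-SNP block of rare alleles in
near-perfect mutual LD that ride the same long-range haplotype.  Three
common tag SNPs form a 6-haplotype system whose rare risk class
(an "AGT"-analog, frequency 0.02) carries the causal allele 90% of the
time.  The causal variant is absent from the genotyping array; it can only
be reached through imputation, and its only common proxy has r^2 ~ 0.15,
so a small reference panel imputes it poorly -- which is exactly what makes
the distant block, well-imputed because its alleles are faithfully tagged,
light up instead.

A background of ~110 common SNPs (MAF 0.05-0.5) in weak first-order LD
(median pairwise r^2 ~ 0.1) provides the null genomic context.  Disease is
assigned through logit P(case) = alpha + ln(OR) * g_causal with alpha set
for a population prevalence of 0.05, and case/control quotas are filled by
rejection sampling.  Everything is driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .errors import ValidationError
from .io_formats import DosageMatrix, GenotypeMatrix, PhenotypeTable, SnpRecord
from .imputation import dosage_quality, tag_impute

CHROM = "11"
CAUSAL_POS = 46761055            # F2 G20210A-like coordinate (hg19 flavour)
BLOCK_POSITIONS = (47373425, 47389771, 47565138, 47574081, 47598481, 47764906,
                   47783614, 47818310, 47920993, 47947894, 48052066, 48064194)
TAG_POSITIONS = (47310500, 47352000, 47401000)
PROXY_POS = 46791055             # nearest common partial proxy of the causal variant
REGION = (CHROM, 47300000, 48100000)   # the haplotype-scan interval
PREVALENCE = 0.05
DEFAULT_OR = 3.0
PANEL_HAPLOTYPES = 566
N_IMPUTE_TAGS = 1                # the causal variant has one usable weak proxy


@dataclass(frozen=True)
class HaplotypeClass:
    """One core-haplotype class: tag alleles, block-allele carriage, frequency
    and the probability that the causal allele rides this class."""

    label: str
    tag_alleles: tuple      # ALT (0/1) at the three tag SNPs
    block_allele: int       # 0/1 carried at every block SNP
    frequency: float
    causal_carriage: float


@dataclass
class PanelSpec:
    """Generating configuration: SNP panel, haplotype classes, LD knobs."""

    snps: list                        # SnpRecord with roles, position-sorted
    classes: list                     # HaplotypeClass
    proxy_id: str
    proxy_freq: float                 # population ALT frequency of the proxy
    proxy_carry_given_causal: float   # P(proxy ALT | haplotype carries causal)
    background_rho: float             # latent AR(1) correlation between adjacent SNPs
    prevalence: float = PREVALENCE
    region: tuple = REGION

    def __post_init__(self):
        tot = sum(c.frequency for c in self.classes)
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"class frequencies sum to {tot}, not 1")
        for c in self.classes:
            if not 0.0 <= c.causal_carriage <= 1.0:
                raise ValidationError(f"class {c.label}: carriage outside [0,1]")
        pos = {r: [s.pos for s in self.snps if s.role == r] for r in ("causal", "block")}
        if pos["causal"] and pos["block"]:
            span = max(abs(p - pos["causal"][0]) for p in pos["block"])
            if span < 1_000_000:
                raise ValidationError("causal-to-farthest-block span must be >= 1 Mb")

    # -- catalogue helpers -------------------------------------------------
    def ids(self, role) -> list:
        return [s.id for s in self.snps if s.role == role]

    @property
    def causal_id(self):
        return self.ids("causal")[0]

    @property
    def causal_freq(self) -> float:
        return sum(c.frequency * c.causal_carriage for c in self.classes)

    @property
    def block_freq(self) -> float:
        return sum(c.frequency * c.block_allele for c in self.classes)

    # -- analytic LD implied by the class algebra --------------------------
    def implied_causal_block_r2(self) -> float:
        """Haplotype-level r^2 between the causal allele and any block SNP."""
        p, q = self.causal_freq, self.block_freq
        f11 = sum(c.frequency * c.block_allele * c.causal_carriage for c in self.classes)
        D = f11 - p * q
        return D * D / (p * (1 - p) * q * (1 - q))

    def implied_causal_proxy_r2(self) -> float:
        p, q = self.causal_freq, self.proxy_freq
        f11 = p * self.proxy_carry_given_causal
        D = f11 - p * q
        return D * D / (p * (1 - p) * q * (1 - q))

    def risk_class_share_of_causal(self) -> float:
        """P(risk class | haplotype carries the causal allele)."""
        risk = max(self.classes, key=lambda c: c.causal_carriage)
        return risk.frequency * risk.causal_carriage / self.causal_freq


def _quality_curve(maf: float) -> float:
    """Imputation quality as a function of MAF: rare variants impute worse.

    Saturating curve calibrated so common SNPs reach ~0.95 and MAF ~0.03
    block SNPs land near the 0.65-0.97 range a real run reports."""
    return float(np.clip(0.97 * (1.0 - np.exp(-maf / 0.012)), 0.05, 0.97))


def default_ghost_spec() -> PanelSpec:
    """The reference ghost scenario.

    12 block SNPs (pop MAF 0.03) in perfect mutual truth LD, 3 tag SNPs
    forming a 6-haplotype system with a rare risk class at 0.02, one causal
    variant (pop MAF 0.02, 90% of copies on the risk class), one weak common
    proxy (r^2 ~ 0.15) and 109 weak-LD common background SNPs.
    """
    # Causal carriage is uniform (0.73) across the two block-carrying classes
    # so that conditioning on any block SNP absorbs the haplotype association
    # (the collapse that unmasks the ghost), with a small off-block component
    # keeping the causal variant imperfectly tagged by the block.
    classes = [
        HaplotypeClass("GGT", (0, 0, 0), 0, 0.369, 0.003),
        HaplotypeClass("GAT", (0, 1, 0), 0, 0.282, 0.0),
        HaplotypeClass("GAC", (0, 1, 1), 0, 0.049, 0.0),
        HaplotypeClass("AGT", (1, 0, 0), 1, 0.020, 0.73),   # the risk class
        HaplotypeClass("AAC", (1, 1, 1), 0, 0.260, 0.0),
        HaplotypeClass("AAT+block", (1, 1, 0), 1, 0.010, 0.73),
        HaplotypeClass("AAT", (1, 1, 0), 0, 0.010, 0.0),
    ]
    snps = [SnpRecord(id=f"{CHROM}:{CAUSAL_POS}", chrom=CHROM, pos=CAUSAL_POS,
                      ref_allele="G", alt_allele="A", maf=0.02, role="causal")]
    tag_alleles = [("G", "A"), ("G", "A"), ("T", "C")]
    for pos, (ref, alt) in zip(TAG_POSITIONS, tag_alleles):
        snps.append(SnpRecord(id=f"{CHROM}:{pos}", chrom=CHROM, pos=pos,
                              ref_allele=ref, alt_allele=alt, role="tag"))
    for pos in BLOCK_POSITIONS:
        snps.append(SnpRecord(id=f"{CHROM}:{pos}", chrom=CHROM, pos=pos,
                              ref_allele="A", alt_allele="G", maf=0.03, role="block"))
    proxy_freq = 0.08
    snps.append(SnpRecord(id=f"{CHROM}:{PROXY_POS}", chrom=CHROM, pos=PROXY_POS,
                          ref_allele="C", alt_allele="T", maf=proxy_freq,
                          role="background"))
    # background catalogue: fixed construction rng so the spec is one object
    bg_rng = np.random.default_rng(11047)
    out_pos = np.linspace(46_600_000, 47_295_000, 97).astype(int)
    in_pos = np.linspace(47_330_000, 48_090_000, 12).astype(int)
    for pos in np.concatenate([out_pos, in_pos]):
        maf = float(bg_rng.uniform(0.05, 0.5))
        snps.append(SnpRecord(id=f"{CHROM}:{int(pos)}", chrom=CHROM, pos=int(pos),
                              ref_allele="C", alt_allele="T", maf=maf,
                              role="background"))
    snps.sort(key=lambda s: s.pos)
    return PanelSpec(
        snps=snps, classes=classes,
        proxy_id=f"{CHROM}:{PROXY_POS}", proxy_freq=proxy_freq,
        proxy_carry_given_causal=0.75,
        background_rho=0.93,
    )


# ---------------------------------------------------------------------------
# haplotype drawing
# ---------------------------------------------------------------------------

def _core_allele_table(spec: PanelSpec) -> np.ndarray:
    """classes x core-SNP allele table, core SNPs = tags + blocks in position order."""
    core = [s for s in spec.snps if s.role in ("tag", "block")]
    tag_rank = {sid: k for k, sid in enumerate(spec.ids("tag"))}
    table = np.zeros((len(spec.classes), len(core)), dtype=np.int8)
    for ci, cls in enumerate(spec.classes):
        for j, s in enumerate(core):
            if s.role == "tag":
                table[ci, j] = cls.tag_alleles[tag_rank[s.id]]
            else:
                table[ci, j] = cls.block_allele
    return table


def draw_haplotypes(spec: PanelSpec, n_haplotypes: int, rng) -> np.ndarray:
    """Draw phased haplotypes over every SNP of the spec (position order).

    Classes are drawn i.i.d. from their frequencies; causal and proxy alleles
    follow the per-class carriage probabilities; background alleles come from
    a stationary latent-Gaussian AR(1) thresholded at each SNP's MAF.
    """
    freqs = np.array([c.frequency for c in spec.classes])
    carriage = np.array([c.causal_carriage for c in spec.classes])
    cls = rng.choice(len(freqs), size=n_haplotypes, p=freqs)
    causal = (rng.random(n_haplotypes) < carriage[cls]).astype(np.int8)
    return draw_conditional(spec, cls, causal, rng)


# ---------------------------------------------------------------------------
# dosage degradation
# ---------------------------------------------------------------------------

def degrade_to_dosage(genotypes, target_r2, seed, freq=None) -> np.ndarray:
    """Turn hard genotypes into imputation-like dosages of chosen quality.

    Observation model (a caricature of haplotype-mosaic imputation): each of
    an individual's two alleles is recovered correctly with probability
    c = sqrt(target_r2), and otherwise replaced by a fresh draw from the
    population at frequency p.  The returned dose is the posterior mean of
    the allele count given the observed alleles, which reduces to
    dose = 2 (1 - c) p + c (o1 + o2) and has expected MACH-style quality
    Var(dose)/(2 p (1 - p)) exactly equal to ``target_r2``.  Higher targets
    give stochastically higher concordance with truth; ``target_r2 = 1``
    returns the genotypes exactly.  Accepts a column or an n x m matrix
    (per-column targets allowed).
    """
    g = np.asarray(genotypes, dtype=float)
    single = g.ndim == 1
    if single:
        g = g[:, None]
    targets = np.broadcast_to(np.asarray(target_r2, dtype=float), (g.shape[1],))
    if np.any(targets <= 0.0) or np.any(targets > 1.0):
        raise ValidationError("target_r2 must lie in (0, 1]; use a constant dose "
                              "column explicitly for zero information")
    rng = np.random.default_rng(seed)
    out = np.empty_like(g)
    n = g.shape[0]
    for j in range(g.shape[1]):
        col = g[:, j]
        p = float(col.mean()) / 2.0 if freq is None \
            else float(np.atleast_1d(freq)[j if np.ndim(freq) else 0])
        if targets[j] >= 1.0 or p <= 0.0 or p >= 1.0:
            out[:, j] = col
            continue
        c = np.sqrt(targets[j])
        # split the genotype into two exchangeable alleles
        a1 = np.where(col == 1, rng.integers(0, 2, n), col / 2.0)
        a2 = col - a1
        o1 = np.where(rng.random(n) < c, a1, rng.random(n) < p)
        o2 = np.where(rng.random(n) < c, a2, rng.random(n) < p)
        out[:, j] = 2.0 * (1.0 - c) * p + c * (o1 + o2)
    dose = np.clip(out, 0.0, 2.0)
    return dose[:, 0] if single else dose


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class TruthData:
    """Ground truth: phased haplotypes and complete genotypes (causal included)."""

    genotypes: GenotypeMatrix        # all SNPs including the causal variant
    phased: np.ndarray               # n_samples x 2 x n_snps alleles
    causal_genotype: np.ndarray      # n_samples minor-allele counts at the causal SNP


@dataclass
class ObservedData:
    """What a study would actually have: array genotypes, dosages, phenotype."""

    genotypes: GenotypeMatrix        # typed SNPs only (causal withheld)
    dosages: DosageMatrix            # imputed dosages, causal included
    phenotype: PhenotypeTable


@dataclass
class CohortBundle:
    truth: TruthData
    observed: ObservedData
    spec: PanelSpec
    params: dict = field(default_factory=dict)


def _solve_alpha(p_causal, or_causal, prevalence):
    geno_p = np.array([(1 - p_causal) ** 2, 2 * p_causal * (1 - p_causal), p_causal ** 2])
    beta = np.log(or_causal)

    def prev(alpha):
        return float(np.sum(geno_p * expit(alpha + beta * np.array([0.0, 1.0, 2.0]))))

    return brentq(lambda a: prev(a) - prevalence, -30.0, 30.0)


def _genotype_matrix(spec, haplo, sample_ids, snp_filter):
    snps = [s for s in spec.snps if snp_filter(s)]
    idx = [j for j, s in enumerate(spec.snps) if snp_filter(s)]
    calls = (haplo[:, 0, :][:, idx] + haplo[:, 1, :][:, idx]).astype(np.int8)
    return GenotypeMatrix(sample_ids, snps, calls)


def impute_tag_ids(spec: PanelSpec, n_tags=N_IMPUTE_TAGS) -> list:
    """Imputation tags for the causal variant: its weak proxy and, if more
    than one tag is requested, the nearest common background SNPs (the
    'neighbourhood' a real imputation engine would lean on).  The default is
    the proxy alone: it is the only SNP carrying usable information."""
    causal_pos = [s.pos for s in spec.snps if s.role == "causal"][0]
    bg = [s for s in spec.snps if s.role == "background" and s.id != spec.proxy_id]
    bg.sort(key=lambda s: abs(s.pos - causal_pos))
    ids = [spec.proxy_id] + [s.id for s in bg[: n_tags - 1]]
    order = {s.id: s.pos for s in spec.snps}
    return sorted(ids, key=lambda i: order[i])


def simulate_cohort(spec: PanelSpec, n_cases=1500, n_controls=1200,
                    or_causal=DEFAULT_OR, seed=None, study_label="study1",
                    include_causal_on_array=False,
                    panel_haplotypes=PANEL_HAPLOTYPES,
                    max_batches=50) -> CohortBundle:
    """Simulate a retrospective case-control cohort under the ghost scenario.

    Individuals are built from two i.i.d. haplotypes; disease follows
    logit P = alpha + ln(or_causal) * g_causal with alpha set for the spec's
    population prevalence; sampling rejects until the case/control quotas are
    met.  The causal variant is withheld from the array (unless
    ``include_causal_on_array``) and re-enters only as a tag-imputed dosage;
    all other dosages are truth degraded to a MAF-dependent quality.
    The seed fully determines the output.
    """
    if seed is None:
        raise ValidationError("simulate_cohort requires an explicit seed")
    if n_cases <= 0 or n_controls <= 0 or or_causal <= 0:
        raise ValidationError("n_cases, n_controls and or_causal must be positive")
    ss = np.random.SeedSequence(seed)
    s_draw, s_dose, s_panel, s_cov = ss.spawn(4)
    rng = np.random.default_rng(s_draw)

    p_c = spec.causal_freq
    alpha = _solve_alpha(p_c, or_causal, spec.prevalence)
    beta = np.log(or_causal)
    freqs = np.array([c.frequency for c in spec.classes])
    carriage = np.array([c.causal_carriage for c in spec.classes])

    # stage 1: class/causal/disease only, until quotas are met
    need_cases, need_controls = n_cases, n_controls
    batch = min(int(1.4 * (n_cases / spec.prevalence
                       + n_controls / (1 - spec.prevalence))) + 1000,
            500_000)
    kept_cls, kept_causal, kept_status = [], [], []
    for _ in range(max_batches):
        if need_cases <= 0 and need_controls <= 0:
            break
        cls = rng.choice(len(freqs), size=(batch, 2), p=freqs)
        causal = (rng.random((batch, 2)) < carriage[cls]).astype(np.int8)
        gc = causal.sum(axis=1)
        case = rng.random(batch) < expit(alpha + beta * gc)
        take_case = np.where(case)[0][:need_cases]
        take_ctrl = np.where(~case)[0][:need_controls]
        for take, status in ((take_case, 1), (take_ctrl, 0)):
            if take.size:
                kept_cls.append(cls[take])
                kept_causal.append(causal[take])
                kept_status.append(np.full(take.size, status))
        need_cases -= take_case.size
        need_controls -= take_ctrl.size
    if need_cases > 0 or need_controls > 0:
        raise ValidationError(
            f"case/control quotas unattainable within {max_batches} batches "
            f"(prevalence {spec.prevalence}, OR {or_causal})"
        )
    cls = np.concatenate(kept_cls)
    causal = np.concatenate(kept_causal)
    status = np.concatenate(kept_status)
    n = len(status)
    order = rng.permutation(n)   # shuffle cases and controls together
    cls, causal, status = cls[order], causal[order], status[order]

    # stage 2: materialize full haplotypes for the retained individuals,
    # conditioning on the already-drawn class and causal alleles
    hap_rng = np.random.default_rng(s_draw.spawn(1)[0])
    flat = draw_conditional(spec, cls.reshape(-1), causal.reshape(-1), hap_rng)
    haplo = flat.reshape(n, 2, len(spec.snps))

    sample_ids = [f"S{i:05d}" for i in range(n)]
    truth_gm = _genotype_matrix(spec, haplo, sample_ids, lambda s: True)
    truth = TruthData(genotypes=truth_gm, phased=haplo,
                      causal_genotype=truth_gm.column(spec.causal_id).copy())

    typed = lambda s: s.role != "block" and (include_causal_on_array or s.role != "causal")
    observed_gm = _genotype_matrix(spec, haplo, sample_ids, typed)

    # dosages: degrade every non-causal SNP at its MAF-implied quality;
    # tag-impute the causal variant from a small phased panel
    dose_rng = np.random.default_rng(s_dose)
    dose_snps = list(spec.snps)
    dose_cols = np.empty((n, len(dose_snps)))
    qualities = np.empty(len(dose_snps))
    tag_ids = impute_tag_ids(spec)
    panel = draw_haplotypes(spec, panel_haplotypes, np.random.default_rng(s_panel))
    idx_of = {s.id: j for j, s in enumerate(spec.snps)}
    # Block SNPs sit on one shared haplotype segment, and a real imputation
    # engine reconstructs that segment once: their dose errors are therefore
    # correlated.  Model this by sharing the allele-recovery events (one
    # uniform draw per allele) across the block, with per-SNP replacement
    # noise -- conditioning on any one block dose then absorbs the whole
    # block signal, as observed in practice.
    u_shared = (dose_rng.random((n, 2)) if spec.ids("block") else None)
    for j, s in enumerate(dose_snps):
        col = truth_gm.column(s.id).astype(float)
        if s.role == "causal" and not include_causal_on_array:
            res = tag_impute(panel[:, [idx_of[i] for i in tag_ids]],
                             panel[:, idx_of[s.id]],
                             observed_gm.subset(tag_ids), snp_id=s.id)
            dose_cols[:, j] = res.dose
            qualities[j] = res.quality.rsq_hat
            continue
        p = float(col.mean()) / 2.0
        maf = min(p, 1 - p) if 0 < p < 1 else 0.0
        if maf == 0.0:
            dose_cols[:, j] = col
            qualities[j] = 1.0
            continue
        target = _quality_curve(maf)
        if s.role == "block":
            c = np.sqrt(target)
            a = haplo[:, :, j].astype(float)  # truth alleles, both haplotypes
            repl = dose_rng.random((n, 2)) < p
            obs = np.where(u_shared < c, a, repl)
            d = 2.0 * (1.0 - c) * p + c * obs.sum(axis=1)
        else:
            d = degrade_to_dosage(col, target, seed=dose_rng.integers(2 ** 31))
        dose_cols[:, j] = np.clip(d, 0.0, 2.0)
        q = dosage_quality(dose_cols[:, j], snp_id=s.id).rsq_hat
        qualities[j] = min(q, 1.0) if np.isfinite(q) else 0.0
    dosages = DosageMatrix(sample_ids, dose_snps, dose_cols, qualities)

    cov_rng = np.random.default_rng(s_cov)
    import pandas as pd
    covs = pd.DataFrame(cov_rng.standard_normal((n, 4)),
                        columns=["PC1", "PC2", "PC3", "PC4"])
    pheno = PhenotypeTable(sample_ids, status, covs, [study_label] * n)

    params = dict(seed=seed, n_cases=n_cases, n_controls=n_controls,
                  or_causal=or_causal, prevalence=spec.prevalence,
                  alpha=alpha, panel_haplotypes=panel_haplotypes,
                  include_causal_on_array=include_causal_on_array,
                  impute_tags=tag_ids, study_label=study_label)
    return CohortBundle(truth=truth,
                        observed=ObservedData(observed_gm, dosages, pheno),
                        spec=spec, params=params)


def draw_conditional(spec: PanelSpec, cls, causal, rng) -> np.ndarray:
    """Materialize haplotypes given pre-drawn class and causal alleles."""
    n = len(cls)
    p_proxy = np.where(causal == 1, spec.proxy_carry_given_causal,
                       (spec.proxy_freq - spec.causal_freq * spec.proxy_carry_given_causal)
                       / (1.0 - spec.causal_freq))
    proxy = (rng.random(n) < p_proxy).astype(np.int8)
    core_table = _core_allele_table(spec)
    core = core_table[cls]
    bg = [s for s in spec.snps if s.role == "background" and s.id != spec.proxy_id]
    B = len(bg)
    rho = spec.background_rho
    z = np.empty((n, B))
    z[:, 0] = rng.standard_normal(n)
    noise = rng.standard_normal((n, B - 1))
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, B):
        z[:, j] = rho * z[:, j - 1] + scale * noise[:, j - 1]
    bg_alleles = (z < norm.ppf([s.maf for s in bg])).astype(np.int8)
    out = np.empty((n, len(spec.snps)), dtype=np.int8)
    core_iter = iter(range(core.shape[1]))
    bg_iter = iter(range(B))
    for j, s in enumerate(spec.snps):
        if s.role == "causal":
            out[:, j] = causal
        elif s.id == spec.proxy_id:
            out[:, j] = proxy
        elif s.role in ("tag", "block"):
            out[:, j] = core[:, next(core_iter)]
        else:
            out[:, j] = bg_alleles[:, next(bg_iter)]
    return out


def carrier_enriched_controls(spec: PanelSpec, n_total, fraction_carriers,
                              seed=None, or_causal=DEFAULT_OR,
                              max_batches=200) -> CohortBundle:
    """A control-only sample enriched in healthy causal-allele heterozygotes.

    ``fraction_carriers`` of the controls are conditioned to carry exactly
    one causal allele (mirroring a recruitment design that over-samples
    known mutation carriers); the rest are ordinary population controls.
    """
    if seed is None:
        raise ValidationError("carrier_enriched_controls requires an explicit seed")
    if not 0.0 <= fraction_carriers <= 1.0:
        raise ValidationError("fraction_carriers must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    s_draw, s_dose, s_panel, s_cov = ss.spawn(4)
    rng = np.random.default_rng(s_draw)

    n_carrier = int(round(n_total * fraction_carriers))
    n_plain = n_total - n_carrier
    alpha = _solve_alpha(spec.causal_freq, or_causal, spec.prevalence)
    beta = np.log(or_causal)
    freqs = np.array([c.frequency for c in spec.classes])
    carriage = np.array([c.causal_carriage for c in spec.classes])

    got_cls, got_causal, got_carrier = [], [], []
    need_c, need_p = n_carrier, n_plain
    batch = max(5000, int(30 * n_total))
    for _ in range(max_batches):
        if need_c <= 0 and need_p <= 0:
            break
        cls = rng.choice(len(freqs), size=(batch, 2), p=freqs)
        causal = (rng.random((batch, 2)) < carriage[cls]).astype(np.int8)
        gc = causal.sum(axis=1)
        control = rng.random(batch) >= expit(alpha + beta * gc)
        het = control & (gc == 1)
        plain = control
        take_c = np.where(het)[0][:need_c]
        take_p = np.where(plain & ~np.isin(np.arange(batch), take_c))[0][:need_p]
        for take, flag in ((take_c, 1), (take_p, 0)):
            if take.size:
                got_cls.append(cls[take])
                got_causal.append(causal[take])
                got_carrier.append(np.full(take.size, flag))
        need_c -= take_c.size
        need_p -= take_p.size
    if need_c > 0 or need_p > 0:
        raise ValidationError(f"control quotas unattainable within {max_batches} batches")
    cls = np.concatenate(got_cls)
    causal = np.concatenate(got_causal)
    carrier_flag = np.concatenate(got_carrier)
    n = len(carrier_flag)
    order = rng.permutation(n)
    cls, causal, carrier_flag = cls[order], causal[order], carrier_flag[order]

    hap_rng = np.random.default_rng(s_draw.spawn(1)[0])
    haplo = draw_conditional(spec, cls.reshape(-1), causal.reshape(-1),
                             hap_rng).reshape(n, 2, len(spec.snps))
    sample_ids = [f"C{i:05d}" for i in range(n)]
    truth_gm = _genotype_matrix(spec, haplo, sample_ids, lambda s: True)
    truth = TruthData(genotypes=truth_gm, phased=haplo,
                      causal_genotype=truth_gm.column(spec.causal_id).copy())
    observed_gm = _genotype_matrix(spec, haplo, sample_ids,
                                   lambda s: s.role not in ("block", "causal"))
    import pandas as pd
    covs = pd.DataFrame({"carrier": carrier_flag.astype(float)})
    pheno = PhenotypeTable(sample_ids, np.zeros(n, dtype=int), covs,
                           ["controls"] * n)
    dosages = DosageMatrix(sample_ids, [], np.empty((n, 0)), None)
    params = dict(seed=seed, n_total=n_total, fraction_carriers=fraction_carriers,
                  or_causal=or_causal)
    return CohortBundle(truth=truth,
                        observed=ObservedData(observed_gm, dosages, pheno),
                        spec=spec, params=params)
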