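"""End-to-end orchestration of the ghost-signal analysis narrative.

Runs, on simulated (or user-supplied) data, the sequence a careful imputed
GWAS follow-up would: per-study dosage association, fixed-effect
meta-analysis with a genome-wide threshold, LD structure of the hit region,
mutual conditional analyses among the hits, the exhaustive AIC haplotype
scan, haplotype odds ratios with and without adjustment, conditional
analysis of the top hit on the candidate culprit (imputed dose vs true
genotype), and imputation-quality diagnostics of the culprit.  The verdict
flag ``ghost_signal`` is set when the top association collapses under the
culprit's true genotype but survives its poorly imputed dose.

Every threshold is one named config key: ``genome_wide`` 7.4e-9,
``suggestive`` 1e-6, ``quality_min`` 0.3, ``conditional_null`` 0.10,
``persist_p`` 1e-3.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import association, haplotypes, imputation, ld, meta
from .errors import (
    CollinearityError,
    ConvergenceError,
    UnknownSnpError,
    ValidationError,
)
from .io_formats import PhenotypeTable
from .synthetic_data import (
    CohortBundle,
    default_ghost_spec,
    simulate_cohort,
)

GENOME_WIDE = 7.4e-9
SUGGESTIVE = 1e-6


@dataclass
class ScenarioConfig:
    """One simulated two-study scenario plus every analysis threshold."""

    preset: str = "ghost"            # ghost | null | positive_control
    seed: int = 1
    studies: tuple = (("gwas1", 419, 1228), ("gwas2", 1542, 1110))
    or_causal: float = 3.0
    covariates: tuple = ("PC1", "PC2", "PC3", "PC4")
    genome_wide: float = GENOME_WIDE
    suggestive: float = SUGGESTIVE
    quality_min: float = imputation.QUALITY_MIN
    conditional_null: float = 0.10
    persist_p: float = 1e-3
    max_size: int = 4
    scan_cap: int = 25
    with_ld: bool = True
    with_scan: bool = True
    with_haplotypes: bool = True
    with_conditionals: bool = True
    with_quality: bool = True

    def effective_or(self):
        return 1.0 if self.preset == "null" else self.or_causal


@dataclass
class GhostReport:
    config: ScenarioConfig
    study_assoc: dict                 # study label -> per-SNP DataFrame
    meta_table: pd.DataFrame
    hits: list
    top_hit: str | None
    gc_lambda: float | None
    ld_summary: dict
    mutual_conditional: pd.DataFrame | None
    scan: haplotypes.ScanResult | None
    haplotype_model: haplotypes.HaplotypeModel | None
    haplotype_adjusted: haplotypes.HaplotypeModel | None
    conditional_table: pd.DataFrame | None
    quality: dict
    verdict: dict
    manifest: list = field(default_factory=list)

    def to_dir(self, path):
        os.makedirs(path, exist_ok=True)
        for label, df in self.study_assoc.items():
            df.to_csv(os.path.join(path, f"assoc_{label}.tsv"), sep="\t", index=False)
        self.meta_table.to_csv(os.path.join(path, "meta.tsv"), sep="\t", index=False)
        if self.mutual_conditional is not None:
            self.mutual_conditional.to_csv(
                os.path.join(path, "mutual_conditional.tsv"), sep="\t", index=False)
        if self.conditional_table is not None:
            self.conditional_table.to_csv(
                os.path.join(path, "conditional.tsv"), sep="\t", index=False)
        if self.haplotype_model is not None:
            self.haplotype_model.to_frame().to_csv(
                os.path.join(path, "haplotypes.tsv"), sep="\t", index=False)
        if self.scan is not None:
            self.scan.equivalence.to_csv(
                os.path.join(path, "aic_equivalence.tsv"), sep="\t", index=False)
        payload = {
            "config": asdict(self.config),
            "hits": self.hits, "top_hit": self.top_hit,
            "gc_lambda": self.gc_lambda, "ld_summary": self.ld_summary,
            "quality": self.quality, "verdict": self.verdict,
            "manifest": self.manifest,
        }
        with open(os.path.join(path, "manifest.json"), "wt") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _study_bundles(config: ScenarioConfig):
    spec = default_ghost_spec()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.studies))
    bundles = {}
    for child, (label, n_cases, n_controls) in zip(children, config.studies):
        bundles[label] = simulate_cohort(
            spec, n_cases=n_cases, n_controls=n_controls,
            or_causal=config.effective_or(),
            seed=int(np.random.default_rng(child).integers(2 ** 31)),
            study_label=label,
            include_causal_on_array=(config.preset == "positive_control"),
        )
    return spec, bundles


def _assoc_table(bundle: CohortBundle, covariates) -> pd.DataFrame:
    dos = bundle.observed.dosages
    pheno = bundle.observed.phenotype
    rows = []
    for j, s in enumerate(dos.snps):
        dose = dos.dose[:, j]
        if np.ptp(dose) == 0:
            continue
        res = association.dose_logistic(dose, pheno, covariates=covariates, snp_id=s.id)
        p_hat = dose.mean() / 2.0
        rows.append({
            "snp": s.id, "pos": s.pos, "role": s.role,
            "maf": min(p_hat, 1 - p_hat),
            "logOR": res.log_or, "se": res.se, "p": res.p,
            "quality": dos.quality[j] if dos.quality is not None else np.nan,
        })
    return pd.DataFrame(rows)


def run_ghost_analysis(config: ScenarioConfig | None = None) -> GhostReport:
    """Execute the full analysis sequence on a simulated scenario."""
    config = config or ScenarioConfig()
    manifest = []

    def stage(name, **params):
        manifest.append({"stage": name, "params": params, "t0": time.time()})

    def done(**extra):
        manifest[-1]["runtime_s"] = round(time.time() - manifest[-1].pop("t0"), 3)
        manifest[-1].update(extra)

    spec, bundles = _study_bundles(config)
    labels = list(bundles)
    main = labels[-1]  # the larger study drives single-study stages
    culprit = spec.causal_id
    covariates = list(config.covariates)

    # (1) per-SNP dosage association per study
    stage("per_snp_association", covariates=covariates)
    study_assoc = {lab: _assoc_table(b, covariates) for lab, b in bundles.items()}
    done(n_snps={lab: len(df) for lab, df in study_assoc.items()})

    # (2) fixed-effect meta-analysis across studies
    stage("meta_analysis", genome_wide=config.genome_wide)
    merged = None
    for lab in labels:
        df = study_assoc[lab].rename(columns={
            "logOR": f"beta_{lab}", "se": f"se_{lab}", "p": f"p_{lab}",
            "quality": f"rsq_{lab}", "maf": f"maf_{lab}"})
        cols = ["snp", "pos", "role", f"maf_{lab}", f"beta_{lab}", f"se_{lab}",
                f"p_{lab}", f"rsq_{lab}"]
        merged = df[cols] if merged is None else merged.merge(
            df[cols], on=["snp", "pos", "role"], how="inner")
    metas = []
    for _, row in merged.iterrows():
        effects = [meta.StudyEffect(lab, row[f"beta_{lab}"], row[f"se_{lab}"])
                   for lab in labels]
        m = meta.fixed_effect_meta(effects)
        metas.append((m.beta_c, m.se_c, m.p, m.log10_p, m.q_p))
    merged[["beta_meta", "se_meta", "p_meta", "log10_p_meta", "q_p"]] = \
        pd.DataFrame(metas, index=merged.index)
    merged["pass_quality"] = np.all(
        [merged[f"rsq_{lab}"] >= config.quality_min for lab in labels], axis=0)
    eligible = merged[merged["pass_quality"]]
    hits = eligible[eligible["p_meta"] < config.genome_wide]["snp"].tolist()
    top_hit = (eligible.loc[eligible["p_meta"].idxmin(), "snp"]
               if len(eligible) else None)
    bg = merged[merged["role"] == "background"]
    gc_lambda = (meta.genomic_control(bg["p_meta"].to_numpy())
                 if len(bg) >= 100 else None)
    done(n_hits=len(hits), top_hit=top_hit, gc_lambda=gc_lambda)
    meta_table = merged

    main_bundle = bundles[main]
    obs = main_bundle.observed

    # (3) LD structure of the hit region (typed SNPs) + the imputed block
    ld_summary = {}
    if config.with_ld:
        stage("ld_region", region=spec.region)
        typed_ld = ld.ld_matrix(obs.genotypes, region=spec.region)
        block_ids = spec.ids("block")
        phased = main_bundle.truth.phased
        tsnp = {s.id: j for j, s in enumerate(main_bundle.truth.genotypes.snps)}
        hap_alleles = phased.reshape(-1, phased.shape[2])
        r2min = 1.0
        for a in range(len(block_ids)):
            for b in range(a + 1, len(block_ids)):
                x = hap_alleles[:, tsnp[block_ids[a]]].astype(float)
                y = hap_alleles[:, tsnp[block_ids[b]]].astype(float)
                r = np.corrcoef(x, y)[0, 1]
                r2min = min(r2min, r * r)
        ld_summary = {"typed_median_r2": typed_ld.median_r2,
                      "typed_p90_r2": typed_ld.p90_r2,
                      "block_min_r2": float(r2min)}
        done(**ld_summary)

    # (4) mutual conditional analyses among the block hits
    mutual = None
    if config.with_conditionals and top_hit is not None:
        stage("mutual_conditionals")
        dos = obs.dosages
        others = [h for h in hits if h != top_hit]
        rows = []
        for other in others:
            try:
                res = association.conditional_logistic(
                    dos.column(top_hit), dos.column(other), obs.phenotype,
                    covariates=covariates, snp_id=top_hit, adjust_ids=[other])
                p, note = res.p, ""
            except (CollinearityError, ConvergenceError):
                # the two doses are statistical duplicates of one block
                # genotype; the pair carries no separable information
                p, note = np.nan, "degenerate"
            rows.append({"target": top_hit, "adjusted_on": other, "p": p,
                         "note": note})
        mutual = pd.DataFrame(rows, columns=["target", "adjusted_on", "p", "note"])
        informative = mutual["p"].dropna()
        done(n=len(rows),
             all_vanish=bool((informative > config.conditional_null).all())
             if len(informative) else None)

    # (5) exhaustive AIC haplotype scan over typed region SNPs
    scan = None
    if config.with_scan:
        stage("aic_scan", max_size=config.max_size)
        scan = haplotypes.aic_scan(obs.genotypes, obs.phenotype,
                                   region=spec.region, max_size=config.max_size,
                                   covariates=covariates, scan_cap=config.scan_cap)
        done(n_models=scan.n_models, best=",".join(scan.best_snps))

    # (6) haplotype ORs of the winning model, crude and block-adjusted
    hap_model = hap_adjusted = None
    if config.with_haplotypes and scan is not None:
        stage("haplotype_effects")
        sub = obs.genotypes.subset(scan.best_snps)
        phase = haplotypes.em_haplotypes(sub)
        hap_model = haplotypes.haplotype_logistic(
            phase, obs.phenotype, covariates=covariates, snps=sub.snps)
        adjust_id = top_hit if top_hit is not None else spec.ids("block")[0]
        hap_adjusted = haplotypes.haplotype_conditional(
            phase, obs.phenotype, obs.dosages.column(adjust_id),
            covariates=covariates, snps=sub.snps, adjust_id=adjust_id)
        done(global_p=hap_model.global_p)

    # (7) conditional analysis of the top hit on the culprit
    conditional_table = None
    if config.with_conditionals and top_hit is not None:
        stage("culprit_conditionals", culprit=culprit)
        rows = []
        for lab, b in bundles.items():
            dos, pheno = b.observed.dosages, b.observed.phenotype
            target = dos.column(top_hit)
            crude = association.dose_logistic(target, pheno, covariates=covariates,
                                              snp_id=top_hit)
            dose_c = dos.column(culprit)
            truth_c = b.truth.causal_genotype.astype(float)
            mixed = np.where(pheno.status == 1, truth_c, dose_c)
            variants = {
                "crude": None, "adjusted_dose": dose_c,
                "adjusted_mixed": mixed, "adjusted_truth": truth_c,
            }
            for name, adj in variants.items():
                if name == "crude":
                    res = crude
                else:
                    try:
                        res = association.conditional_logistic(
                            target, adj, pheno, covariates=covariates,
                            snp_id=top_hit, adjust_ids=[f"{culprit}:{name}"])
                    except (CollinearityError, ConvergenceError):
                        # top hit is (or duplicates) the culprit itself:
                        # self-adjustment degenerates
                        rows.append({"study": lab, "analysis": name,
                                     "OR": np.nan, "ci_low": np.nan,
                                     "ci_high": np.nan, "p": np.nan})
                        continue
                rows.append({"study": lab, "analysis": name,
                             "OR": res.odds_ratio, "ci_low": res.ci()[0],
                             "ci_high": res.ci()[1], "p": res.p})
        conditional_table = pd.DataFrame(rows)
        done(n=len(rows))

    # (8) imputation quality and concordance of the culprit
    quality = {}
    if config.with_quality:
        stage("culprit_quality")
        for lab, b in bundles.items():
            dos = b.observed.dosages
            dose_c = dos.column(culprit)
            q = imputation.dosage_quality(dose_c, snp_id=culprit)
            conc = imputation.concordance(dose_c, b.truth.causal_genotype)
            quality[lab] = {"rsq_hat": q.rsq_hat, "maf_hat": q.maf_hat,
                            "spearman_rho": conc.spearman_rho}
        done(**{lab: q["rsq_hat"] for lab, q in quality.items()})

    # verdict
    verdict = {"locus_significant": bool(hits)}
    if conditional_table is not None and top_hit is not None:
        sub = conditional_table[conditional_table["study"] == main]
        get = lambda name: float(sub[sub["analysis"] == name]["p"].iloc[0])
        crude_p = float(meta_table.loc[meta_table["snp"] == top_hit, "p_meta"].iloc[0])
        verdict.update({
            "top_hit": top_hit,
            "top_hit_is_culprit": top_hit == culprit,
            "crude_meta_p": crude_p,
            "truth_adjusted_p": get("adjusted_truth"),
            "dose_adjusted_p": get("adjusted_dose"),
            "mixed_adjusted_p": get("adjusted_mixed"),
        })
        verdict["ghost_signal"] = bool(
            top_hit != culprit
            and crude_p < config.suggestive
            and verdict["truth_adjusted_p"] > config.conditional_null
            and verdict["dose_adjusted_p"] < config.persist_p
        )
    else:
        verdict["ghost_signal"] = False

    return GhostReport(
        config=config, study_assoc=study_assoc, meta_table=meta_table,
        hits=hits, top_hit=top_hit, gc_lambda=gc_lambda, ld_summary=ld_summary,
        mutual_conditional=mutual, scan=scan, haplotype_model=hap_model,
        haplotype_adjusted=hap_adjusted, conditional_table=conditional_table,
        quality=quality, verdict=verdict, manifest=manifest,
    )


def conditional_rediscovery(dosages, phenotype: PhenotypeTable, known_loci,
                            threshold=SUGGESTIVE, covariates=()) -> pd.DataFrame:
    """Re-test every SNP conditioning on a set of known associated SNPs.

    Returns the per-SNP conditional results with a ``survives`` flag at the
    given threshold.  An empty conditioning set reproduces the crude scan.
    """
    known = list(known_loci)
    ids = set(dosages.snp_ids)
    for k in known:
        if k not in ids:
            raise UnknownSnpError(k)
    adjust = np.column_stack([dosages.column(k) for k in known]) if known else None
    rows = []
    for j, s in enumerate(dosages.snps):
        dose = dosages.dose[:, j]
        if np.ptp(dose) == 0:
            continue
        if s.id in known:
            continue
        if adjust is None:
            res = association.dose_logistic(dose, phenotype,
                                            covariates=covariates, snp_id=s.id)
        else:
            res = association.conditional_logistic(
                dose, adjust, phenotype, covariates=covariates,
                snp_id=s.id, adjust_ids=known)
        rows.append({"snp": s.id, "p": res.p, "logOR": res.log_or, "se": res.se,
                     "survives": res.p < threshold})
    return pd.DataFrame(rows)
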