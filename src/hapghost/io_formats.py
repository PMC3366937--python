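"""Containers and readers/writers for the tabular formats used across hapghost.

Three in-memory containers are shared by every analysis module:

* :class:`GenotypeMatrix` -- unphased genotype calls coded 0/1/2 as copies of
  the counted (ALT) allele, with ``-1`` for missing.
* :class:`DosageMatrix` -- continuous imputed allele dosages in [0, 2] with an
  optional per-SNP imputation-quality track (MACH-style r-hat-squared).
* :class:`PhenotypeTable` -- binary case/control status plus real-valued
  covariates (typically principal components) and a study label used for
  meta-analysis grouping.

File dialects: VCF 4.x (GT only, diploid, biallelic) read through cyvcf2;
a MACH-dose-like header-less dosage TSV with an "info" sidecar; and a
phenotype TSV with header ``sample  status  <covariates...>  study``.
Coordinates are 1-based and region filters are closed intervals.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    UnsupportedPloidyError,
    ValidationError,
)

MISSING = -1  # genotype code for an unobserved call


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP.

    ``id`` is an rsID when one exists, otherwise a ``chrom:pos`` name.
    ``alt_allele`` is the allele that genotype/dosage values count.
    ``maf`` is the minor allele frequency in [0, 0.5] when known; it is
    computed from data when absent.  ``role`` is free-form annotation used by
    the cohort simulator ({block, tag, causal, background}).
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float | None = None
    role: str | None = None

    def __post_init__(self):
        if self.pos <= 0:
            raise ValidationError(f"SNP {self.id}: position must be positive, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"SNP {self.id}: ref and alt alleles are identical")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"SNP {self.id}: MAF {self.maf} outside [0, 0.5]")


def _check_alignment(samples, snps, values, what):
    n, m = values.shape
    if n != len(samples):
        raise ValidationError(f"{what}: {len(samples)} samples but {n} rows")
    if m != len(snps):
        raise ValidationError(f"{what}: {len(snps)} SNPs but {m} columns")
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{what}: duplicated sample identifiers")
    ids = [s.id for s in snps]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{what}: duplicated SNP identifiers")


class _SnpIndexed:
    """Shared sample/SNP bookkeeping for genotype and dosage matrices."""

    samples: list
    snps: list

    def _index(self):
        return {s.id: j for j, s in enumerate(self.snps)}

    @property
    def snp_ids(self):
        return [s.id for s in self.snps]

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def n_snps(self):
        return len(self.snps)

    def snp(self, snp_id) -> SnpRecord:
        from .errors import UnknownSnpError

        try:
            return self.snps[self._index()[snp_id]]
        except KeyError:
            raise UnknownSnpError(snp_id) from None

    def column(self, snp_id) -> np.ndarray:
        from .errors import UnknownSnpError

        try:
            j = self._index()[snp_id]
        except KeyError:
            raise UnknownSnpError(snp_id) from None
        return self._values()[:, j]

    def region_ids(self, chrom, start, end):
        """SNP ids with ``chrom`` and position in the closed interval [start, end]."""
        return [s.id for s in self.snps if s.chrom == str(chrom) and start <= s.pos <= end]


@dataclass
class GenotypeMatrix(_SnpIndexed):
    """Unphased genotype calls, ``calls[i, j]`` = ALT copies of sample i at SNP j."""

    samples: list
    snps: list
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        _check_alignment(self.samples, self.snps, self.calls, "GenotypeMatrix")
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            raise ValidationError("GenotypeMatrix: calls must be in {0,1,2} or missing")

    def _values(self):
        return self.calls

    def observed_maf(self, snp_id) -> float:
        """Frequency of the counted allele among non-missing calls, folded to [0, 0.5]."""
        col = self.column(snp_id)
        col = col[col != MISSING]
        if col.size == 0:
            raise ValidationError(f"SNP {snp_id}: all calls missing")
        p = float(col.mean()) / 2.0
        return min(p, 1.0 - p)

    def alt_freq(self, snp_id) -> float:
        col = self.column(snp_id)
        col = col[col != MISSING]
        if col.size == 0:
            raise ValidationError(f"SNP {snp_id}: all calls missing")
        return float(col.mean()) / 2.0

    def subset(self, snp_ids) -> "GenotypeMatrix":
        idx = self._index()
        cols = [idx[i] for i in snp_ids]
        return GenotypeMatrix(list(self.samples), [self.snps[j] for j in cols], self.calls[:, cols])

    def reorder(self, samples) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in samples]
        return GenotypeMatrix(list(samples), list(self.snps), self.calls[rows])


@dataclass
class DosageMatrix(_SnpIndexed):
    """Imputed expected ALT-allele counts in [0, 2], optional per-SNP quality r^2."""

    samples: list
    snps: list
    dose: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        _check_alignment(self.samples, self.snps, self.dose, "DosageMatrix")
        if self.dose.size and (np.nanmin(self.dose) < 0.0 or np.nanmax(self.dose) > 2.0):
            bad = np.argwhere((self.dose < 0) | (self.dose > 2))[0]
            raise ValidationError(
                f"DosageMatrix: dose outside [0, 2] at sample {self.samples[bad[0]]}, "
                f"SNP {self.snps[bad[1]].id}"
            )
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=np.float64)
            if self.quality.shape != (len(self.snps),):
                raise ValidationError("DosageMatrix: quality length must match SNP count")
            if self.quality.size and (self.quality.min() < 0 or self.quality.max() > 1):
                raise ValidationError("DosageMatrix: quality values must lie in [0, 1]")

    def _values(self):
        return self.dose

    def snp_quality(self, snp_id) -> float | None:
        if self.quality is None:
            return None
        return float(self.quality[self._index()[snp_id]])

    def subset(self, snp_ids) -> "DosageMatrix":
        idx = self._index()
        cols = [idx[i] for i in snp_ids]
        q = self.quality[cols] if self.quality is not None else None
        return DosageMatrix(list(self.samples), [self.snps[j] for j in cols], self.dose[:, cols], q)

    def reorder(self, samples) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in samples]
        return DosageMatrix(list(samples), list(self.snps), self.dose[rows], self.quality)


@dataclass
class PhenotypeTable:
    """Case/control status (1/0), covariates and a study label per sample."""

    samples: list
    status: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    study: list | None = None

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=np.int64)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("PhenotypeTable: duplicated sample identifiers")
        if self.status.shape != (len(self.samples),):
            raise ValidationError("PhenotypeTable: status length must match sample count")
        if not np.isin(self.status, [0, 1]).all():
            bad = self.samples[int(np.flatnonzero(~np.isin(self.status, [0, 1]))[0])]
            raise ValidationError(f"PhenotypeTable: status outside {{0,1}} for sample {bad}")
        if len(self.covariates):
            if len(self.covariates) != len(self.samples):
                raise ValidationError("PhenotypeTable: covariate rows must match sample count")
            if self.covariates.isna().any().any():
                bad = self.samples[int(np.where(self.covariates.isna().any(axis=1))[0][0])]
                raise ValidationError(f"PhenotypeTable: missing covariate value for sample {bad}")
        self.covariates = self.covariates.reset_index(drop=True)
        if self.study is None:
            self.study = ["study1"] * len(self.samples)
        if len(self.study) != len(self.samples):
            raise ValidationError("PhenotypeTable: study labels must match sample count")

    @property
    def n_cases(self):
        return int(self.status.sum())

    @property
    def n_controls(self):
        return int((self.status == 0).sum())

    def covariate_matrix(self, names=None) -> np.ndarray:
        names = list(self.covariates.columns) if names is None else list(names)
        if not names:
            return np.empty((len(self.samples), 0))
        missing = [n for n in names if n not in self.covariates.columns]
        if missing:
            raise ValidationError(f"PhenotypeTable: unknown covariates {missing}")
        return self.covariates[names].to_numpy(dtype=float)

    def reorder(self, samples) -> "PhenotypeTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in samples]
        cov = self.covariates.iloc[rows].reset_index(drop=True) if len(self.covariates) else self.covariates
        return PhenotypeTable(list(samples), self.status[rows], cov, [self.study[i] for i in rows])


def align(phenotype: PhenotypeTable, *matrices):
    """Restrict a phenotype table and any genotype/dosage matrices to their
    common samples, all in phenotype order.  The join is by sample id, so the
    result is independent of the input row orders."""
    common = set(phenotype.samples)
    for m in matrices:
        common &= set(m.samples)
    order = [s for s in phenotype.samples if s in common]
    return (phenotype.reorder(order), *[m.reorder(order) for m in matrices])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header_lines(path):
    n = 0
    with open(path, "rt") as fh:
        for line in fh:
            n += 1
            if line.startswith("#CHROM"):
                return n
            if not line.startswith("#"):
                break
    raise FormatError(f"{path}: no #CHROM header line found (line {n})")


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid, biallelic VCF 4.x (GT only) into a :class:`GenotypeMatrix`.

    Calls count copies of the ALT allele; ``./.`` maps to missing.  Phased
    separators are accepted but phase is discarded.  Multi-allelic sites and
    indels are rejected.
    """
    from cyvcf2 import VCF

    header_n = _vcf_header_lines(path)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # malformed header
        raise FormatError(f"{path}: cannot parse VCF header (lines 1-{header_n}): {exc}") from exc

    samples = list(vcf.samples)
    snps, rows = [], []
    for k, v in enumerate(vcf):
        line_no = header_n + 1 + k
        if len(v.ALT) != 1:
            raise FormatError(f"{path} line {line_no}: multi-allelic site {v.CHROM}:{v.POS}")
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise FormatError(f"{path} line {line_no}: non-SNP alleles {ref}/{alt}")
        calls = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise UnsupportedPloidyError(
                    f"{path} line {line_no}: sample {samples[i]} has ploidy {len(alleles)}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                calls[i] = MISSING
            else:
                calls[i] = alleles[0] + alleles[1]
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        snps.append(SnpRecord(id=vid, chrom=str(v.CHROM), pos=int(v.POS),
                              ref_allele=ref, alt_allele=alt))
        rows.append(calls)
    if not snps:
        return GenotypeMatrix(samples, [], np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, snps, np.stack(rows, axis=1))


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, phased_haplotypes=None):
    """Write a :class:`GenotypeMatrix` as a minimal VCF 4.2 text file.

    If ``phased_haplotypes`` (n_samples x 2 x n_snps allele array) is given,
    GT fields are emitted phased (``a|b``) instead of from the 0/1/2 calls.
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in dict.fromkeys(s.chrom for s in gm.snps):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(gm.samples) + "\n")
    for j in range(len(gm.snps)):
        s = gm.snps[j]
        fields = [s.chrom, str(s.pos), s.id, s.ref_allele, s.alt_allele, ".", "PASS", "."]
        if phased_haplotypes is not None:
            gts = [f"{int(a)}|{int(b)}" for a, b in phased_haplotypes[:, :, j]]
        else:
            gts = [_GT_CODE[int(c)] for c in gm.calls[:, j]]
        buf.write("\t".join(fields + ["GT"] + gts) + "\n")
    with open(path, "wt") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# dosage dialect
# ---------------------------------------------------------------------------

def read_dosage(dose_path, info_path) -> DosageMatrix:
    """Read a MACH-dose-like pair of files.

    ``dose_path``: header-less TSV, one row per sample: sample id then one
    dosage per SNP.  ``info_path``: TSV with header, columns SNP_ID, MAF, Rsq
    and optionally CHROM, POS.  Doses outside [0, 2] are a validation error,
    never silently clamped.
    """
    info = pd.read_csv(info_path, sep="\t")
    required = {"SNP_ID", "MAF", "Rsq"}
    if not required.issubset(info.columns):
        raise FormatError(f"{info_path}: expected columns {sorted(required)}, got {list(info.columns)}")
    snps = []
    for _, row in info.iterrows():
        sid = str(row["SNP_ID"])
        if "CHROM" in info.columns and "POS" in info.columns:
            chrom, pos = str(row["CHROM"]), int(row["POS"])
        elif ":" in sid:
            chrom, pos = sid.split(":", 1)[0], int(sid.split(":", 1)[1])
        else:
            raise FormatError(
                f"{info_path}: SNP {sid} has no CHROM/POS columns and no chrom:pos id"
            )
        maf = float(row["MAF"])
        snps.append(SnpRecord(id=sid, chrom=chrom, pos=pos,
                              ref_allele="A", alt_allele="B",
                              maf=maf if maf <= 0.5 else None))
    quality = info["Rsq"].to_numpy(dtype=float)

    samples, rows = [], []
    with open(dose_path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(snps) + 1:
                raise FormatError(
                    f"{dose_path} line {ln}: expected {len(snps) + 1} fields, got {len(parts)}"
                )
            samples.append(parts[0])
            try:
                vals = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{dose_path} line {ln}: non-numeric dose") from exc
            if vals.size and (vals.min() < 0.0 or vals.max() > 2.0):
                raise ValidationError(
                    f"{dose_path} line {ln}: dose outside [0, 2] for sample {parts[0]}"
                )
            rows.append(vals)
    dose = np.vstack(rows) if rows else np.empty((0, len(snps)))
    return DosageMatrix(samples, snps, dose, quality)


def write_dosage(dm: DosageMatrix, dose_path, info_path, decimals=6):
    with open(dose_path, "wt") as fh:
        for i, sample in enumerate(dm.samples):
            vals = "\t".join(f"{x:.{decimals}f}" for x in dm.dose[i])
            fh.write(f"{sample}\t{vals}\n" if dm.n_snps else f"{sample}\n")
    qual = dm.quality if dm.quality is not None else np.ones(dm.n_snps)
    with open(info_path, "wt") as fh:
        fh.write("SNP_ID\tMAF\tRsq\tCHROM\tPOS\n")
        for j, s in enumerate(dm.snps):
            maf = s.maf
            if maf is None:
                col = dm.dose[:, j]
                p = float(col.mean()) / 2.0 if col.size else 0.0
                maf = min(p, 1 - p)
            fh.write(f"{s.id}\t{maf:.6f}\t{qual[j]:.6f}\t{s.chrom}\t{s.pos}\n")


# ---------------------------------------------------------------------------
# phenotype dialect
# ---------------------------------------------------------------------------

def read_phenotype(path) -> PhenotypeTable:
    """Read a phenotype TSV: header ``sample  status  <covariates...>  study``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns or "status" not in df.columns:
        raise FormatError(f"{path}: header must contain 'sample' and 'status'")
    samples = df["sample"].tolist()
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicated sample id {dup}")
    status = df["status"].to_numpy()
    if not np.isin(status, [0, 1]).all():
        bad = samples[int(np.flatnonzero(~np.isin(status, [0, 1]))[0])]
        raise ValidationError(f"{path}: status outside {{0,1}} for sample {bad}")
    cov_cols = [c for c in df.columns if c not in ("sample", "status", "study")]
    covs = df[cov_cols].astype(float) if cov_cols else pd.DataFrame()
    if cov_cols and df[cov_cols].isna().any().any():
        bad = samples[int(np.where(df[cov_cols].isna().any(axis=1))[0][0])]
        raise ValidationError(f"{path}: missing covariate cell for sample {bad}")
    study = df["study"].astype(str).tolist() if "study" in df.columns else None
    return PhenotypeTable(samples, status.astype(int), covs, study)


def write_phenotype(pt: PhenotypeTable, path):
    df = pd.DataFrame({"sample": pt.samples, "status": pt.status})
    for c in pt.covariates.columns:
        df[c] = pt.covariates[c].to_numpy()
    df["study"] = pt.study
    df.to_csv(path, sep="\t", index=False)
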