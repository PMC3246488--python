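"""Genotype containers, file IO, and SNP-level quality control.

The central container is :class:`GenotypeMatrix`: a samples x SNPs additive
dosage matrix (copies of the counted allele, ``NaN`` = missing call) with
per-SNP metadata. Genotypes can be read from / written to plain VCF (GT
fields only, biallelic records) or a simple dosage-matrix TSV dialect.

QC follows the standard GWAS per-SNP filters: minor-allele frequency,
Hardy-Weinberg exact test, and call rate, all with strict-inequality
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "counted_allele", "other_allele"]


class GenotypeError(ValueError):
    """Malformed or empty genotype input."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix.

    Attributes
    ----------
    dosage : ndarray, shape (n_samples, n_snps)
        Copies of the counted allele in {0, 1, 2}; ``NaN`` marks a missing
        call. Missingness is never conflated with dosage 0.
    snps : DataFrame
        One row per SNP: snp_id, chrom, pos (1-based), counted_allele,
        other_allele.
    sample_ids : list of str
        Row labels, aligned with the cohort sample table.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise GenotypeError("dosage must be 2-D (samples x SNPs)")
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise GenotypeError("sample_ids length does not match dosage rows")
        if len(self.snps) != m:
            raise GenotypeError("snp metadata length does not match dosage columns")
        missing = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise GenotypeError(f"snp metadata lacks columns: {missing}")
        if self.snps["snp_id"].duplicated().any():
            raise GenotypeError("snp_ids must be unique")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise GenotypeError("dosage values must be 0, 1, 2 or missing")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP counts of (hom other, het, hom counted) among called genotypes."""
        out = np.empty((self.n_snps, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(self.dosage == g, axis=0)
        return out

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            snps=self.snps.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, keep_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep_ids]
        return GenotypeMatrix(self.dosage[idx], self.snps.copy(), list(keep_ids))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _hwe_cached(n_hom1: int, n_het: int, n_hom2: int) -> float:
    n = n_hom1 + n_het + n_hom2
    # rare-allele copy count; the het-count distribution conditional on
    # allele counts is enumerated with the stable ratio recurrence
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0:  # monomorphic: a single attainable configuration
        return 1.0
    het_states = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.empty(het_states.size, dtype=float)
    probs[0] = 1.0
    for k in range(1, het_states.size):
        h = het_states[k]  # move from h-2 hets to h hets
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # P(h) / P(h-2) = 4 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1))
        probs[k] = probs[k - 1] * 4.0 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1))
        if probs[k] > 1e250:  # rescale to avoid overflow on large n
            probs[: k + 1] /= probs[k]
    probs /= probs.sum()
    obs = probs[np.searchsorted(het_states, n_het)]
    p = probs[probs <= obs * (1.0 + 1e-10)].sum()
    return float(min(p, 1.0))


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Returns the probability, conditional on the observed allele counts, of a
    heterozygote count at least as improbable as the one observed. Symmetric
    under allele relabeling: ``P(a, b, c) == P(c, b, a)``.

    Parameters are genotype counts: homozygotes for one allele,
    heterozygotes, homozygotes for the other allele.
    """
    counts = (int(n_hom1), int(n_het), int(n_hom2))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("at least one observed genotype is required")
    return _hwe_cached(*counts)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-SNP QC statistics and pass/fail decisions.

    ``table`` has one row per input SNP with columns snp_id, maf, hwe_p,
    call_rate, pass, reasons (comma-joined failure reasons, empty if passed).
    """

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def snp_qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.02,
    hwe_p_min: float = 1e-4,
    call_rate_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply per-SNP QC filters with strict-inequality thresholds.

    A SNP is retained iff MAF > ``maf_min`` AND HWE exact P > ``hwe_p_min``
    AND call rate > ``call_rate_min``. MAF and the HWE test use non-missing
    calls only. The report lists every input SNP with all three statistics.
    """
    for name, t in (("maf_min", maf_min), ("hwe_p_min", hwe_p_min),
                    ("call_rate_min", call_rate_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if genotypes.n_snps == 0 or genotypes.n_samples == 0:
        raise GenotypeError("empty genotype matrix")

    maf = genotypes.maf()
    call_rate = genotypes.call_rate()
    counts = genotypes.genotype_counts()
    hwe_p = np.array([
        hwe_exact_test(*c) if c.sum() > 0 else np.nan for c in counts
    ])

    ok_maf = maf > maf_min
    ok_hwe = hwe_p > hwe_p_min
    ok_cr = call_rate > call_rate_min
    passed = ok_maf & ok_hwe & ok_cr

    reasons = []
    for i in range(genotypes.n_snps):
        r = []
        if not ok_maf[i]:
            r.append("maf")
        if not ok_hwe[i]:
            r.append("hwe")
        if not ok_cr[i]:
            r.append("call_rate")
        reasons.append(",".join(r))

    table = pd.DataFrame({
        "snp_id": genotypes.snps["snp_id"].to_numpy(),
        "maf": maf,
        "hwe_p": hwe_p,
        "call_rate": call_rate,
        "pass": passed,
        "reasons": reasons,
    })
    report = QCReport(table=table, thresholds={
        "maf_min": maf_min, "hwe_p_min": hwe_p_min,
        "call_rate_min": call_rate_min,
    })
    return genotypes.subset_snps(passed), report


# ---------------------------------------------------------------------------
# VCF IO (plain-text, GT only, biallelic)
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF (GT fields).

    Dosage counts copies of the ALT allele. Multiallelic records are skipped
    with a warning; missing genotypes are preserved as NaN.
    """
    import pysam

    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise GenotypeError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vf.header.samples)
    rows_meta: list[tuple] = []
    dosage_cols: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            log.warning("skipping non-biallelic record %s:%s", rec.chrom, rec.pos)
            continue
        col = np.empty(len(sample_ids), dtype=float)
        for i, s in enumerate(sample_ids):
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                col[i] = np.nan
            else:
                col[i] = float(sum(gt))
        rows_meta.append((rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom,
                          rec.pos, rec.alts[0], rec.ref))
        dosage_cols.append(col)
    vf.close()
    if not rows_meta:
        raise GenotypeError(f"no biallelic SNPs found in {path}")
    snps = pd.DataFrame(rows_meta, columns=SNP_META_COLUMNS)
    return GenotypeMatrix(np.column_stack(dosage_cols), snps, sample_ids)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal plain-text VCF (GT only); ALT is the counted allele."""
    chroms = list(dict.fromkeys(genotypes.snps["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgskit\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = np.lexsort((genotypes.snps["pos"].to_numpy(),
                            genotypes.snps["chrom"].astype(str).to_numpy()))
        for j in order:
            meta = genotypes.snps.iloc[j]
            gts = "\t".join(
                "./." if np.isnan(d) else gt_code[d]
                for d in genotypes.dosage[:, j]
            )
            fh.write(f"{meta.chrom}\t{meta.pos}\t{meta.snp_id}\t"
                     f"{meta.other_allele}\t{meta.counted_allele}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Matrix-TSV IO
# ---------------------------------------------------------------------------

def write_matrix_tsv(genotypes: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write dosages to ``<prefix>.dosage.tsv`` and metadata to ``<prefix>.snps.tsv``.

    Dosage dialect: header row of snp_ids, first column sample_id, cells in
    {0, 1, 2, NA}.
    """
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosage.tsv") if prefix.suffix == "" else prefix
    dosage_path = Path(str(prefix) + ".dosage.tsv")
    meta_path = Path(str(prefix) + ".snps.tsv")
    df = pd.DataFrame(genotypes.dosage,
                      columns=genotypes.snps["snp_id"].to_numpy())
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA",
              float_format="%.0f")
    genotypes.snps.to_csv(meta_path, sep="\t", index=False)
    return dosage_path, meta_path


def read_matrix_tsv(dosage_path, snp_meta_path=None) -> GenotypeMatrix:
    """Read the dosage-matrix TSV dialect written by :func:`write_matrix_tsv`.

    If ``snp_meta_path`` is omitted, looks for the ``.snps.tsv`` sidecar next
    to the dosage file; without one, placeholder metadata is synthesized
    (chromosome "1", positions by column order, alleles A/B).
    """
    dosage_path = Path(dosage_path)
    df = pd.read_csv(dosage_path, sep="\t", na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise GenotypeError(f"{dosage_path}: first column must be sample_id")
    sample_ids = df["sample_id"].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    if not snp_ids:
        raise GenotypeError(f"{dosage_path}: no SNP columns")
    dosage = df[snp_ids].to_numpy(dtype=float)

    if snp_meta_path is None:
        cand = Path(str(dosage_path).replace(".dosage.tsv", ".snps.tsv"))
        snp_meta_path = cand if cand != dosage_path and cand.exists() else None
    if snp_meta_path is not None:
        snps = pd.read_csv(snp_meta_path, sep="\t")
        snps = snps.set_index("snp_id").loc[snp_ids].reset_index()
    else:
        snps = pd.DataFrame({
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, len(snp_ids) + 1),
            "counted_allele": "A",
            "other_allele": "B",
        })
    return GenotypeMatrix(dosage, snps, sample_ids)


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from ``vcf`` or ``matrix-tsv`` (auto-detected by suffix)."""
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix == ".vcf" else "matrix-tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "matrix-tsv":
        return read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")
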