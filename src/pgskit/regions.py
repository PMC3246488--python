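"""Significant regions, known-locus recovery, and cross-study concordance.

Regions are grown seed-and-extend: a seed SNP passing a strict p-value
threshold is extended outward along the chromosome, absorbing consecutive
SNPs that pass a looser threshold and lie within a distance cap of the
current region edge; overlapping regions merge. Recovery counts how many
previously reported loci fall inside a top-ranked region or within a fixed
window of its index SNP. Concordance compares per-SNP effect sizes between
the cohort and an external panel with a two-sample heterogeneity z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class Region:
    """Contiguous significant interval (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    index_snp_id: str
    index_p: float
    index_pos: int
    snp_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def build_regions(assoc: pd.DataFrame, seed_p: float = 5e-4,
                  extend_p: float = 5e-3, max_gap: int = 25_000) -> list[Region]:
    """Seed-and-extend region construction from a sorted association scan.

    Each region grows outward from a seed SNP (p < seed_p), absorbing
    consecutive SNPs with p < extend_p whose distance from the current
    region edge is <= max_gap; a SNP failing either condition stops growth
    on that side. Overlapping or touching regions merge; every region keeps
    at least one seed and its minimum-p member as index SNP.
    """
    df = assoc.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    regions: list[Region] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        pval = grp["p"].to_numpy()
        ids = grp["snp_id"].to_numpy()
        seeds = np.flatnonzero(pval < seed_p)
        intervals: list[tuple[int, int]] = []  # (lo, hi) row-index span
        for s in seeds:
            lo = hi = s
            while lo - 1 >= 0 and pval[lo - 1] < extend_p \
                    and pos[lo] - pos[lo - 1] <= max_gap:
                lo -= 1
            while hi + 1 < len(pos) and pval[hi + 1] < extend_p \
                    and pos[hi + 1] - pos[hi] <= max_gap:
                hi += 1
            intervals.append((lo, hi))
        intervals.sort()
        merged: list[list[int]] = []
        for lo, hi in intervals:
            if merged and lo <= merged[-1][1]:  # overlap in sorted row space
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            member = slice(lo, hi + 1)
            best = lo + int(np.argmin(pval[member]))
            regions.append(Region(
                chrom=str(chrom), start=int(pos[lo]), end=int(pos[hi]),
                index_snp_id=str(ids[best]), index_p=float(pval[best]),
                index_pos=int(pos[best]), snp_ids=list(ids[member])))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def top_regions(regions: list[Region], k: int = 100) -> list[Region]:
    """Rank regions ascending by index-SNP p (genomic coordinate breaks
    ties) and keep the top k."""
    ranked = sorted(regions, key=lambda r: (r.index_p, _norm_chrom(r.chrom)
                                            .rjust(2, "0"), r.start))
    return ranked[:k]


@dataclass
class RecoveryReport:
    """Per-region matched catalog SNPs and distinct-locus totals.

    A region recovers a catalog locus if the catalog SNP lies within the
    region interval, or within ``window`` of the region's index SNP
    (inclusive boundaries); the two criteria are also reported separately.
    """

    table: pd.DataFrame
    n_recovered: int          # distinct loci, union of both criteria
    n_in_region: int
    n_near_index: int
    window: int


def recover_known_loci(regions: list[Region], catalog: pd.DataFrame,
                       window: int = 250_000) -> RecoveryReport:
    """Count known loci recovered by the given regions."""
    cat = catalog.copy()
    if cat["snp_id"].duplicated().any():
        raise ValueError("catalog snp_ids must be unique")
    raw_chroms = set(cat["chrom"].astype(str))
    cat["chrom"] = cat["chrom"].map(_norm_chrom)
    if raw_chroms != set(cat["chrom"]):
        log.warning("normalized 'chr' prefixes on catalog chromosome labels")

    rows = []
    in_region_hits: set[str] = set()
    near_index_hits: set[str] = set()
    for r in regions:
        chrom_match = cat[cat["chrom"] == _norm_chrom(r.chrom)]
        p = chrom_match["pos"].to_numpy()
        inside = chrom_match.loc[(p >= r.start) & (p <= r.end), "snp_id"]
        near = chrom_match.loc[np.abs(p - r.index_pos) <= window, "snp_id"]
        in_region_hits.update(inside)
        near_index_hits.update(near)
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "length": r.length, "index_snp_id": r.index_snp_id,
            "index_p": r.index_p,
            "catalog_in_region": ",".join(sorted(inside)),
            "catalog_near_index": ",".join(sorted(near)),
        })
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                        "index_snp_id", "index_p",
                                        "catalog_in_region",
                                        "catalog_near_index"])
    return RecoveryReport(
        table=table,
        n_recovered=len(in_region_hits | near_index_hits),
        n_in_region=len(in_region_hits),
        n_near_index=len(near_index_hits),
        window=window,
    )


def heterogeneity_test(beta_study: float, se_study: float,
                       beta_ref: float, se_ref: float) -> tuple[float, float]:
    """Two-sample effect-size heterogeneity z-test.

    z = (beta_study - beta_ref) / sqrt(se_study^2 + se_ref^2); the p-value
    is the two-sided standard-normal tail (reference SEs are treated as
    known, appropriate for large meta-analyses).
    """
    if se_study <= 0 or se_ref <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_study - beta_ref) / np.hypot(se_study, se_ref)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


@dataclass
class ConcordanceResult:
    """Panel-vs-cohort effect-size agreement summary.

    ``pearson_rho`` over all shared SNPs; ``n_sign_discordant`` counts SNPs
    whose effect estimates disagree in direction (a zero counts as
    concordant); ``rho_concordant_subset`` recomputes the correlation on
    the sign-concordant SNPs. Per-SNP heterogeneity rows are attached, with
    nominal (p < 0.05) and Bonferroni-adjusted significant counts.
    """

    per_snp: pd.DataFrame
    pearson_rho: float
    n_shared: int
    n_sign_discordant: int
    rho_concordant_subset: float
    n_het_nominal: int
    n_het_bonferroni: int


def panel_concordance(panel: pd.DataFrame,
                      cohort: pd.DataFrame) -> ConcordanceResult:
    """Compare a panel's reported effects with the cohort's re-estimates.

    SNPs are matched by snp_id; the panel beta is re-oriented to the
    cohort's counted allele (sign flip when the effect allele is the
    cohort's other allele).
    """
    cohort_idx = cohort.set_index("snp_id")
    rows = []
    for _, snp in panel.iterrows():
        sid = str(snp["snp_id"])
        if sid not in cohort_idx.index:
            continue
        c = cohort_idx.loc[sid]
        b_ref = float(snp["beta"])
        if str(snp["effect_allele"]) != str(c["counted_allele"]):
            if str(snp["other_allele"]) == str(c["counted_allele"]):
                b_ref = -b_ref
            else:
                continue
        z, p_het = heterogeneity_test(float(c["beta"]), float(c["se"]),
                                      b_ref, float(snp["se"])) \
            if float(snp.get("se", 0) or 0) > 0 and float(c["se"]) > 0 \
            else (np.nan, np.nan)
        rows.append({"snp_id": sid, "beta_study": float(c["beta"]),
                     "se_study": float(c["se"]), "beta_ref": b_ref,
                     "se_ref": float(snp.get("se", np.nan)),
                     "z": z, "p_het": p_het})
    per_snp = pd.DataFrame(rows)
    if len(per_snp) < 3:
        raise ValueError("fewer than 3 shared SNPs after alignment")

    bs = per_snp["beta_study"].to_numpy()
    br = per_snp["beta_ref"].to_numpy()
    rho = float(np.corrcoef(bs, br)[0, 1])
    discordant = bs * br < 0
    conc = ~discordant
    rho_conc = float(np.corrcoef(bs[conc], br[conc])[0, 1]) \
        if conc.sum() >= 3 and np.std(bs[conc]) > 0 and np.std(br[conc]) > 0 \
        else np.nan
    p_het = per_snp["p_het"].to_numpy()
    valid = ~np.isnan(p_het)
    n_nom = int(np.sum(p_het[valid] < 0.05))
    n_bonf = int(np.sum(p_het[valid] < 0.05 / max(valid.sum(), 1)))
    return ConcordanceResult(
        per_snp=per_snp, pearson_rho=rho, n_shared=len(per_snp),
        n_sign_discordant=int(discordant.sum()),
        rho_concordant_subset=rho_conc,
        n_het_nominal=n_nom, n_het_bonferroni=n_bonf)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end, "length": r.length,
        "index_snp_id": r.index_snp_id, "index_p": r.index_p,
        "index_pos": r.index_pos, "n_snps": len(r.snp_ids),
        "snp_ids": ",".join(r.snp_ids),
    } for r in regions])


def write_regions_tsv(regions: list[Region], path,
                      bed_half_open: bool = False) -> None:
    """Write regions; default 1-based inclusive, or 0-based half-open BED."""
    df = regions_to_frame(regions)
    if bed_half_open:
        df = df.copy()
        df["start"] = df["start"] - 1
    df.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    need = {"snp_id", "chrom", "pos"}
    if not need <= set(cat.columns):
        raise ValueError(f"locus catalog needs columns {sorted(need)}")
    return cat
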