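"""Effect-panel alignment and genetic-score construction.

An effect panel is an external study's table of trait-associated SNPs with
effect alleles and per-allele weights (betas or log odds ratios). Scores:

* unweighted — the individual's count of trait-increasing alleles;
* weighted  — sum of effect-allele dosages times reported betas;
* genotypic — sum of per-genotype-class weights, dropping the additive
  assumption.

Alignment reconciles the panel's effect allele with the cohort matrix's
counted allele, flipping dosage orientation (x -> 2 - x) or applying a
strand complement where needed; strand-ambiguous (A/T, C/G) SNPs are
dropped by default because a silent strand error corrupts the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

log = logging.getLogger(__name__)

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "eaf"]
GENOTYPE_WEIGHT_COLUMNS = ["w0", "w1", "w2"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlignmentError(ValueError):
    """No panel SNPs could be reconciled with the genotype matrix."""


@dataclass
class ScoreSet:
    """Per-sample genetic score values with provenance.

    ``kind`` is one of unweighted / weighted / genotypic; ``dropped``
    records panel SNPs excluded during alignment and why.
    """

    values: np.ndarray
    sample_ids: list[str]
    panel_name: str
    kind: str
    n_snps_used: int
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"]))

    @property
    def n_snps_dropped(self) -> int:
        return len(self.dropped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.values})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns
               and c not in ("se", "eaf")]
    if missing:
        raise ValueError(f"effect panel lacks columns: {missing}")
    return panel


def write_panel_tsv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False, na_rep="NA")


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


def align_panel(panel: pd.DataFrame, genotypes: GenotypeMatrix,
                ambiguous_policy: str = "drop") -> pd.DataFrame:
    """Match panel SNPs to matrix columns and resolve allele orientation.

    Matching prefers snp_id; unmatched SNPs fall back to chromosome+position
    provided the allele sets agree (possibly after strand complement).
    Returns the panel restricted to aligned SNPs with extra columns
    ``matrix_index`` (column in the dosage matrix) and ``orientation``
    (+1: panel effect allele is the matrix counted allele; -1: dosage must
    be flipped, x -> 2 - x). Rows dropped during alignment are available in
    ``result.attrs['dropped']``.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError("ambiguous_policy must be 'drop' or 'keep'")
    by_id = {s: j for j, s in enumerate(genotypes.snps["snp_id"])}
    by_pos = {(str(c), int(p)): j for j, (c, p) in
              enumerate(zip(genotypes.snps["chrom"], genotypes.snps["pos"]))}
    counted = genotypes.snps["counted_allele"].astype(str).str.upper().to_numpy()
    other = genotypes.snps["other_allele"].astype(str).str.upper().to_numpy()

    rows, dropped = [], []
    for _, snp in panel.iterrows():
        ea = str(snp["effect_allele"]).upper()
        oa = str(snp["other_allele"]).upper()
        j = by_id.get(str(snp["snp_id"]))
        if j is None:
            j = by_pos.get((str(snp.get("chrom")), int(snp.get("pos", -1))))
            if j is not None:
                # positional fallback demands an identical allele set
                if {ea, oa} != {counted[j], other[j]} and \
                   {_COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")} != \
                   {counted[j], other[j]}:
                    j = None
        if j is None:
            dropped.append((snp["snp_id"], "unmatched"))
            continue
        if _is_ambiguous(ea, oa) and ambiguous_policy == "drop":
            dropped.append((snp["snp_id"], "strand_ambiguous"))
            continue
        if (ea, oa) == (counted[j], other[j]):
            orient = 1
        elif (ea, oa) == (other[j], counted[j]):
            orient = -1
        else:
            cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
            if (cea, coa) == (counted[j], other[j]):
                orient = 1
            elif (cea, coa) == (other[j], counted[j]):
                orient = -1
            else:
                dropped.append((snp["snp_id"], "allele_mismatch"))
                continue
        row = snp.to_dict()
        row["matrix_index"] = j
        row["orientation"] = orient
        rows.append(row)

    if not rows:
        raise AlignmentError("no panel SNPs aligned to the genotype matrix")
    if dropped:
        log.warning("align_panel dropped %d panel SNPs", len(dropped))
    aligned = pd.DataFrame(rows).reset_index(drop=True)
    aligned.attrs["dropped"] = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    return aligned


def _effect_dosage(genotypes: GenotypeMatrix, aligned: pd.DataFrame,
                   impute_missing: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Oriented effect-allele dosage (samples x panel SNPs) and cohort
    effect-allele frequencies. Missing calls imputed as 2 x frequency."""
    idx = aligned["matrix_index"].to_numpy()
    x = genotypes.dosage[:, idx].copy()
    flip = aligned["orientation"].to_numpy() == -1
    x[:, flip] = 2.0 - x[:, flip]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(x, axis=0) / 2.0
    if impute_missing:
        nan_r, nan_c = np.nonzero(np.isnan(x))
        x[nan_r, nan_c] = 2.0 * freq[nan_c]
    return x, freq


def _dropped_of(aligned: pd.DataFrame) -> pd.DataFrame:
    return aligned.attrs.get("dropped",
                             pd.DataFrame(columns=["snp_id", "reason"]))


def unweighted_score(genotypes: GenotypeMatrix, aligned: pd.DataFrame,
                     panel_name: str = "panel") -> ScoreSet:
    """Count of trait-increasing alleles across panel SNPs.

    The increasing allele is the effect allele when beta > 0, the other
    allele otherwise; missing dosages are imputed as twice the cohort
    frequency of the increasing allele.
    """
    beta = aligned["beta"].to_numpy(dtype=float)
    if np.isnan(beta).any():
        raise ValueError("unweighted score needs a beta sign for every SNP")
    x, _ = _effect_dosage(genotypes, aligned)
    increasing = np.where(beta > 0, x, 2.0 - x)
    return ScoreSet(increasing.sum(axis=1), list(genotypes.sample_ids),
                    panel_name, "unweighted", len(aligned),
                    _dropped_of(aligned))


def weighted_score(genotypes: GenotypeMatrix, aligned: pd.DataFrame,
                   panel_name: str = "panel") -> ScoreSet:
    """Sum of effect-allele dosages weighted by the reported betas."""
    beta = aligned["beta"].to_numpy(dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("weighted score needs finite betas")
    if np.all(beta == 0):
        log.warning("all panel weights are zero; scores will be zero")
    x, _ = _effect_dosage(genotypes, aligned)
    return ScoreSet(x @ beta, list(genotypes.sample_ids),
                    panel_name, "weighted", len(aligned), _dropped_of(aligned))


def genotypic_score(genotypes: GenotypeMatrix, aligned: pd.DataFrame,
                    panel_name: str = "panel") -> ScoreSet:
    """Sum of per-genotype-class weights (w0, w1, w2), no additivity assumed.

    A missing genotype contributes the HWE-probability-weighted mean of the
    three class weights at the cohort effect-allele frequency.
    """
    for c in GENOTYPE_WEIGHT_COLUMNS:
        if c not in aligned.columns or aligned[c].isna().any():
            raise ValueError("genotypic score needs w0, w1, w2 for every SNP")
    w = aligned[GENOTYPE_WEIGHT_COLUMNS].to_numpy(dtype=float)  # (m, 3)
    x, freq = _effect_dosage(genotypes, aligned, impute_missing=False)
    p = freq
    hwe_mean = ((1 - p) ** 2 * w[:, 0] + 2 * p * (1 - p) * w[:, 1]
                + p ** 2 * w[:, 2])
    values = np.zeros(x.shape[0])
    for j in range(x.shape[1]):
        col = x[:, j]
        miss = np.isnan(col)
        contrib = np.where(miss, hwe_mean[j],
                           w[j, np.nan_to_num(col).astype(int)])
        values += contrib
    return ScoreSet(values, list(genotypes.sample_ids), panel_name,
                    "genotypic", len(aligned), _dropped_of(aligned))


def compute_score(genotypes: GenotypeMatrix, aligned: pd.DataFrame,
                  kind: str, panel_name: str = "panel") -> ScoreSet:
    fn = {"unweighted": unweighted_score, "weighted": weighted_score,
          "genotypic": genotypic_score}.get(kind)
    if fn is None:
        raise ValueError(f"unknown score kind: {kind}")
    return fn(genotypes, aligned, panel_name)
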