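"""Synthetic pedigree-structured cohort generator.

Emulates a height GWAS cohort of related and unrelated adults: nuclear
families plus singletons, genome-wide independent SNPs in Hardy-Weinberg
equilibrium at simulated allele frequencies (optionally with block LD),
and height built from sex, age, age x sex, per-SNP additive effects, a
pedigree-shared polygenic deviate, and independent environmental noise.

Defaults reproduce the study conditions the downstream analysis assumes:
1304 adults (565 males, 739 females), 533 unrelated singletons and 771
related individuals in 238 nuclear families.

Sex is encoded 0 = female, 1 = male throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

FEMALE, MALE = 0, 1

SAMPLE_COLUMNS = ["sample_id", "family_id", "father_id", "mother_id",
                  "sex", "age", "height"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Cohort simulation parameters.

    ``n_related`` is the total number of individuals inside families
    (2 founders + >= 1 offspring each); offspring are distributed as evenly
    as possible across families. ``n_male`` is the exact male total across
    the cohort (family fathers count toward it); ``None`` draws sexes
    Bernoulli(1/2). Allele frequencies are uniform on [maf_min, maf_max].
    ``ld_block_size`` > 1 switches founder haplotypes to an AR(1) latent
    Gaussian copula within consecutive blocks (correlation ``ld_rho``),
    giving intra-block LD while blocks stay independent.
    """

    n_families: int = 238
    n_related: int = 771
    n_unrelated: int = 533
    n_male: int | None = 565
    n_snps: int = 1000
    maf_min: float = 0.05
    maf_max: float = 0.50
    age_min: float = 18.0
    age_max: float = 90.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_families < 0 or self.n_unrelated < 0 or self.n_snps <= 0:
            raise ConfigError("counts must be non-negative (n_snps positive)")
        if self.n_families > 0 and self.n_related < 3 * self.n_families:
            raise ConfigError(
                "n_related must allow 2 parents + >=1 offspring per family")
        if not (0.0 < self.maf_min <= self.maf_max <= 0.5):
            raise ConfigError("need 0 < maf_min <= maf_max <= 0.5")
        if self.n_families == 0 and self.n_unrelated == 0:
            raise ConfigError("empty cohort")
        if not (self.age_min > 0 and self.age_max >= self.age_min):
            raise ConfigError("invalid age range")
        n_total = self.n_total
        if self.n_male is not None:
            n_parent_males = self.n_families
            if not n_parent_males <= self.n_male <= n_total - self.n_families:
                raise ConfigError("n_male incompatible with parent sexes")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not -0.99 <= self.ld_rho <= 0.99:
            raise ConfigError("ld_rho must be in [-0.99, 0.99]")

    @property
    def n_total(self) -> int:
        return (self.n_related if self.n_families > 0 else 0) + self.n_unrelated


@dataclass
class TruePanel:
    """Generative truth for the phenotype model.

    Per causal SNP: column index into the genotype matrix and the additive
    effect in cm per counted allele. Per cohort: sex means (cm), per-sex age
    slopes (cm/year, negative = decline with age), the age centering point
    (``None`` = sample mean age), polygenic background variance (cm^2,
    shared along the pedigree) and environmental residual SD (cm).
    """

    snp_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    true_beta: np.ndarray = field(default_factory=lambda: np.array([]))
    sex_mean: dict = field(default_factory=lambda: {FEMALE: 164.4, MALE: 177.7})
    age_slope: dict = field(default_factory=lambda: {FEMALE: -0.239, MALE: -0.195})
    age_ref: float | None = None
    residual_sd: float = 4.0
    polygenic_background_var: float = 25.0

    def validate(self) -> None:
        if len(self.snp_indices) != len(self.true_beta):
            raise ConfigError("snp_indices and true_beta lengths differ")
        if not np.all(np.isfinite(self.true_beta)):
            raise ConfigError("true_beta must be finite")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be positive")
        if self.polygenic_background_var < 0:
            raise ConfigError("variance components must be non-negative")


def simulate_pedigrees(config: SimConfig) -> pd.DataFrame:
    """Generate the sample table: nuclear families plus unrelated singletons.

    Families have two founder parents (father male, mother female) and at
    least one offspring; offspring counts are as even as possible across
    families. Ages are uniform on [age_min, age_max]; heights are left
    missing until :func:`simulate_phenotype` fills them. Deterministic given
    ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    rows: list[dict] = []

    n_offspring_total = max(config.n_related - 2 * config.n_families, 0) \
        if config.n_families > 0 else 0
    base, extra = (divmod(n_offspring_total, config.n_families)
                   if config.n_families > 0 else (0, 0))

    for f in range(config.n_families):
        fam = f"F{f + 1:04d}"
        father, mother = f"{fam}_p1", f"{fam}_p2"
        rows.append(dict(sample_id=father, family_id=fam, father_id=None,
                         mother_id=None, sex=MALE))
        rows.append(dict(sample_id=mother, family_id=fam, father_id=None,
                         mother_id=None, sex=FEMALE))
        k = base + (1 if f < extra else 0)
        for c in range(k):
            rows.append(dict(sample_id=f"{fam}_o{c + 1}", family_id=fam,
                             father_id=father, mother_id=mother, sex=None))
    for i in range(config.n_unrelated):
        rows.append(dict(sample_id=f"U{i + 1:04d}", family_id=None,
                         father_id=None, mother_id=None, sex=None))

    df = pd.DataFrame(rows)
    unset = df["sex"].isna().to_numpy()
    n_unset = int(unset.sum())
    if config.n_male is None:
        sexes = rng.integers(0, 2, size=n_unset)
    else:
        n_more_males = config.n_male - config.n_families
        sexes = np.concatenate([np.ones(n_more_males, dtype=int),
                                np.zeros(n_unset - n_more_males, dtype=int)])
        rng.shuffle(sexes)
    df.loc[unset, "sex"] = sexes
    df["sex"] = df["sex"].astype(int)
    df["age"] = rng.uniform(config.age_min, config.age_max, size=len(df))
    df["height"] = np.nan
    return df[SAMPLE_COLUMNS]


def _topological_order(samples: pd.DataFrame) -> list[int]:
    """Row order with every parent before its children; rejects cycles."""
    pos = {s: i for i, s in enumerate(samples["sample_id"])}
    children: dict[int, list[int]] = {i: [] for i in range(len(samples))}
    n_parents = np.zeros(len(samples), dtype=int)
    for i, (fa, mo) in enumerate(zip(samples["father_id"], samples["mother_id"])):
        for p in (fa, mo):
            if p is not None and not (isinstance(p, float) and np.isnan(p)):
                if p not in pos:
                    raise ConfigError(f"unknown parent id {p!r}")
                children[pos[p]].append(i)
                n_parents[i] += 1
    order, queue = [], [i for i in range(len(samples)) if n_parents[i] == 0]
    while queue:
        i = queue.pop()
        order.append(i)
        for c in children[i]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                queue.append(c)
    if len(order) != len(samples):
        raise ConfigError("pedigree contains a cycle")
    return order


def _founder_haplotypes(rng, n_hap: int, freqs: np.ndarray,
                        block_size: int, rho: float) -> np.ndarray:
    """Founder haplotypes: Bernoulli(p) alleles, AR(1) Gaussian copula per block."""
    m = freqs.size
    if block_size <= 1 or rho == 0.0:
        return (rng.random((n_hap, m)) < freqs).astype(np.int8)
    from scipy.stats import norm
    z = np.empty((n_hap, m))
    innov = rng.standard_normal((n_hap, m))
    sq = np.sqrt(1.0 - rho * rho)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        z[:, start] = innov[:, start]
        for j in range(start + 1, stop):
            z[:, j] = rho * z[:, j - 1] + sq * innov[:, j]
    return (z < norm.ppf(freqs)).astype(np.int8)


def drop_genotypes(samples: pd.DataFrame, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop genotypes down the pedigree.

    Founders draw haplotypes at Hardy-Weinberg equilibrium from each SNP's
    simulated allele frequency; non-founders receive one haplotype from each
    parent by fair Mendelian transmission (an independent coin per SNP when
    SNPs are independent, one coin per LD block otherwise). SNPs are laid
    out on chromosomes 1-22 at 50 kb spacing.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    m = config.n_snps
    freqs = rng.uniform(config.maf_min, config.maf_max, size=m)

    order = _topological_order(samples)
    n = len(samples)
    pos = {s: i for i, s in enumerate(samples["sample_id"])}
    founders = [i for i in order
                if samples["father_id"].iloc[i] is None
                or (isinstance(samples["father_id"].iloc[i], float)
                    and np.isnan(samples["father_id"].iloc[i]))]
    founder_set = set(founders)

    hap = np.zeros((n, 2, m), dtype=np.int8)
    fh = _founder_haplotypes(rng, 2 * len(founders), freqs,
                             config.ld_block_size, config.ld_rho)
    for k, i in enumerate(founders):
        hap[i, 0] = fh[2 * k]
        hap[i, 1] = fh[2 * k + 1]

    # transmission segments: whole blocks under LD, single SNPs otherwise
    seg = config.ld_block_size if config.ld_block_size > 1 else 1
    n_seg = -(-m // seg)
    seg_idx = np.repeat(np.arange(n_seg), seg)[:m]
    for i in order:
        if i in founder_set:
            continue
        fa = pos[samples["father_id"].iloc[i]]
        mo = pos[samples["mother_id"].iloc[i]]
        for h, parent in ((0, fa), (1, mo)):
            choice = rng.integers(0, 2, size=n_seg)[seg_idx]
            hap[i, h] = np.where(choice == 0, hap[parent, 0], hap[parent, 1])

    dosage = hap.sum(axis=1).astype(float)
    chrom_of = (np.arange(m) * 22) // m + 1
    pos_within = np.empty(m, dtype=int)
    for c in range(1, 23):
        mask = chrom_of == c
        pos_within[mask] = 1 + 50_000 * np.arange(mask.sum())
    snps = pd.DataFrame({
        "snp_id": [f"snp{j + 1:06d}" for j in range(m)],
        "chrom": chrom_of.astype(str),
        "pos": pos_within,
        "counted_allele": "A",
        "other_allele": "G",
    })
    return GenotypeMatrix(dosage, snps, samples["sample_id"].tolist())


def pedigree_relationship(samples: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix A = 2 x pedigree kinship (tabular method)."""
    n = len(samples)
    order = _topological_order(samples)
    pos = {s: i for i, s in enumerate(samples["sample_id"])}
    A = np.zeros((n, n))

    def parent_idx(i):
        out = []
        for col in ("father_id", "mother_id"):
            p = samples[col].iloc[i]
            if p is None or (isinstance(p, float) and np.isnan(p)):
                out.append(None)
            else:
                out.append(pos[p])
        return out

    done: list[int] = []
    for i in order:
        fa, mo = parent_idx(i)
        A[i, i] = 1.0 + (0.5 * A[fa, mo] if fa is not None and mo is not None else 0.0)
        for j in done:
            a = 0.0
            if fa is not None:
                a += 0.5 * A[j, fa]
            if mo is not None:
                a += 0.5 * A[j, mo]
            A[i, j] = A[j, i] = a
        done.append(i)
    return A


def simulate_phenotype(genotypes: GenotypeMatrix, samples: pd.DataFrame,
                       truth: TruePanel, rng_seed: int = 0) -> pd.DataFrame:
    """Fill heights: sex + age + causal SNPs + pedigree polygene + noise.

    height = sex_mean(sex) + age_slope(sex) * (age - age_ref)
             + sum_i beta_i * x_i + g_poly + e,
    where g_poly has covariance polygenic_background_var x A (A the
    numerator relationship matrix, sampled by Cholesky) and
    e ~ N(0, residual_sd^2). Deterministic given ``rng_seed``.
    """
    truth.validate()
    if len(truth.snp_indices) and truth.snp_indices.max() >= genotypes.n_snps:
        raise ConfigError("truth references SNP indices outside the genotype matrix")
    if list(samples["sample_id"]) != list(genotypes.sample_ids):
        raise ConfigError("samples and genotypes are not aligned")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2]))
    n = len(samples)
    sex = samples["sex"].to_numpy()
    age = samples["age"].to_numpy()
    age_ref = float(age.mean()) if truth.age_ref is None else truth.age_ref

    height = np.array([truth.sex_mean[s] for s in sex], dtype=float)
    height += np.array([truth.age_slope[s] for s in sex]) * (age - age_ref)
    if len(truth.snp_indices):
        g = genotypes.dosage[:, truth.snp_indices] @ truth.true_beta
        height += g - g.mean()  # centered so sex_mean stays the group mean
    if truth.polygenic_background_var > 0:
        A = pedigree_relationship(samples)
        L = np.linalg.cholesky(truth.polygenic_background_var * A
                               + 1e-10 * np.eye(n))
        height += L @ rng.standard_normal(n)
    height += truth.residual_sd * rng.standard_normal(n)

    out = samples.copy()
    out["height"] = height
    return out


def make_true_panel(genotypes: GenotypeMatrix, n_causal: int,
                    score_variance_share: float, rng_seed: int = 0,
                    beta_heterogeneity: float = 1.0,
                    **panel_kwargs) -> TruePanel:
    """Draw causal SNPs and scale betas to a target score-variance share.

    Betas are N(0, 1) draws (``beta_heterogeneity`` = 0 makes them all
    equal, fully homogeneous effects) rescaled so that under independence
    and HWE the additive score variance sum_i 2 p_i (1 - p_i) beta_i^2 is a
    fraction ``score_variance_share`` of the total phenotypic variance net
    of age and sex (score + polygenic background + environmental noise).
    """
    if not 0.0 < score_variance_share < 1.0:
        raise ConfigError("score_variance_share must be in (0, 1)")
    if n_causal > genotypes.n_snps:
        raise ConfigError("more causal SNPs requested than available")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 3]))
    idx = np.sort(rng.choice(genotypes.n_snps, size=n_causal, replace=False))
    raw = rng.standard_normal(n_causal) * beta_heterogeneity + 1.0
    panel = TruePanel(snp_indices=idx, true_beta=raw, **panel_kwargs)
    other_var = panel.polygenic_background_var + panel.residual_sd ** 2
    target = score_variance_share * other_var / (1.0 - score_variance_share)
    p = genotypes.allele_freq()[idx]
    current = float(np.sum(2.0 * p * (1.0 - p) * raw ** 2))
    panel.true_beta = raw * np.sqrt(target / current)
    return panel


def perturb_effect_panel(truth: TruePanel, genotypes: GenotypeMatrix,
                         est_se: float, sign_flip_fraction: float,
                         rng_seed: int = 0) -> pd.DataFrame:
    """Build a noisy external effect panel from the generative truth.

    Emulates cross-study transfer: reported beta = true beta + N(0, est_se^2),
    then a random fraction of entries has its sign forced opposite to the
    truth. Effect-allele frequencies come from the cohort genotypes; the SE
    column is ``est_se``. Returns an effect-panel DataFrame usable by the
    scoring module.
    """
    if est_se < 0:
        raise ConfigError("est_se must be non-negative")
    if not 0.0 <= sign_flip_fraction <= 1.0:
        raise ConfigError("sign_flip_fraction must be in [0, 1]")
    truth.validate()
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 4]))
    k = len(truth.snp_indices)
    beta = truth.true_beta + (est_se * rng.standard_normal(k) if est_se > 0
                              else 0.0)
    n_flip = int(round(sign_flip_fraction * k))
    if n_flip:
        flip = rng.choice(k, size=n_flip, replace=False)
        beta = beta.copy()
        beta[flip] = -np.abs(beta[flip]) * np.sign(truth.true_beta[flip])
    meta = genotypes.snps.iloc[truth.snp_indices]
    eaf = genotypes.allele_freq()[truth.snp_indices]
    return pd.DataFrame({
        "snp_id": meta["snp_id"].to_numpy(),
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "effect_allele": meta["counted_allele"].to_numpy(),
        "other_allele": meta["other_allele"].to_numpy(),
        "beta": beta,
        "se": est_se,
        "eaf": eaf,
    })


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"sample_id": str})
    for col in ("family_id", "father_id", "mother_id"):
        df[col] = df[col].where(df[col].notna(), None)
    df["sex"] = df["sex"].astype(int)
    return df[SAMPLE_COLUMNS]
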