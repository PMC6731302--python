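"""Synthetic GWAS cohorts with block LD structure.

The generator stands in for a real biobank: it draws haplotypes from a
copying Markov chain inside independent LD blocks (so that the dosage
correlation between SNPs j and k is exactly ``ld_decay**|j-k|`` within a
block and 0 across blocks), assigns annotation-additive per-SNP effect
variances Var(beta_j) = sum_c a_cj * tau_c, simulates phenotypes under the
additive model Y = X beta + e, and produces marginal-regression chi-square
summary statistics.

All randomness flows from ``SimulationConfig.seed``; named substreams keep
genotypes, effects, phenotype noise and control placements independent of
one another.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io

logger = logging.getLogger(__name__)

#: GWAS sample-size presets for simulation studies
N_PRESETS = (2_000, 20_000, 40_000)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``tau_vector`` gives per-annotation contributions to per-SNP effect
    variance (standardized-genotype scale); when it is None the flat
    polygenic mode is used instead: ``n_causal`` SNPs drawn at random, each
    with effect variance ``h2_g / n_causal``.
    """

    n_individuals: int = 2_000
    n_snps: int = 2_000
    n_blocks_ld: int = 40
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_g: float = 0.5
    n_causal: int | None = None
    tau_vector: np.ndarray | None = None
    seed: int = 0
    chrom: str = "1"
    spacing_bp: int = 1_000  # SNPs evenly spaced, positions 1-based

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        if not 0.0 <= self.h2_g <= 1.0:
            raise ValueError(f"h2_g must lie in [0, 1], got {self.h2_g}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be a non-empty interval in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError(f"ld_decay must lie in [0, 1), got {self.ld_decay}")
        if self.n_causal is not None and self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.n_blocks_ld <= 0 or self.n_blocks_ld > self.n_snps:
            raise ValueError("n_blocks_ld must be in [1, n_snps]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream derived from the config seed (stable across runs)."""
        tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


@dataclass
class Cohort:
    """Genotypes, variant table and (optionally) a phenotype."""

    genotypes: np.ndarray  # n_individuals x n_snps dosages in {0,1,2}
    variants: pd.DataFrame  # io.VARIANT_COLUMNS
    phenotype: np.ndarray | None = None
    genetic_values: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self) -> np.ndarray:
        """Genotype matrix standardized to mean 0, variance 1 per SNP."""
        G = self.genotypes.astype(np.float32)
        mu = G.mean(axis=0)
        sd = G.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic SNP in cohort; cannot standardize")
        return (G - mu) / sd


def _block_sizes(n_snps: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, n_snps // n_blocks, dtype=int)
    sizes[: n_snps % n_blocks] += 1
    return sizes


def simulate_genotypes(config: SimulationConfig) -> Cohort:
    """Draw diploid dosages with within-block LD.

    Haplotypes follow a copying chain: the first SNP of a block is
    Bernoulli(MAF); each subsequent allele copies its left neighbour with
    probability ``ld_decay`` and is otherwise redrawn fresh.  This keeps the
    marginal allele frequency exact and gives corr(j, k) = ld_decay**|j-k|
    within a block.  MAF is drawn once per block from ``maf_range``.

    Monomorphic columns (possible at small n) are redrawn as independent
    Bernoulli draws until polymorphic; the count is logged.
    """
    rng = config.rng("genotypes")
    n_hap = 2 * config.n_individuals
    m = config.n_snps
    H = np.empty((n_hap, m), dtype=np.int8)

    maf = np.empty(m)
    start = 0
    for size in _block_sizes(m, config.n_blocks_ld):
        p = rng.uniform(*config.maf_range)
        maf[start : start + size] = p
        copy = rng.random((n_hap, size)) < config.ld_decay
        fresh = (rng.random((n_hap, size)) < p).astype(np.int8)
        H[:, start] = fresh[:, 0]
        for j in range(1, size):
            col = start + j
            H[:, col] = np.where(copy[:, j], H[:, col - 1], fresh[:, j])
        start += size

    geno = (H[: config.n_individuals] + H[config.n_individuals :]).astype(np.int8)

    # reject monomorphic columns (rare except at tiny n / extreme MAF)
    redrawn = 0
    for j in np.flatnonzero(geno.std(axis=0) == 0):
        while geno[:, j].std() == 0:
            col = (rng.random(n_hap) < maf[j]).astype(np.int8)
            geno[:, j] = col[: config.n_individuals] + col[config.n_individuals :]
        redrawn += 1
    if redrawn:
        logger.info("redrew %d monomorphic SNP(s) as independent draws", redrawn)

    freq = geno.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "snp": [f"rs{j}" for j in range(m)],
            "chrom": config.chrom,
            "pos": 1 + config.spacing_bp * np.arange(m),
            "a1": "A",
            "a2": "G",
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    return Cohort(genotypes=geno, variants=variants)


def per_snp_variance(annot_values: np.ndarray, tau_vector: np.ndarray) -> np.ndarray:
    """Var(beta_j) = sum_c a_cj tau_c; rejects any negative implied variance."""
    tau = np.asarray(tau_vector, dtype=float)
    var = np.asarray(annot_values, dtype=float) @ tau
    bad = np.flatnonzero(var < 0)
    if bad.size:
        raise ValueError(
            f"tau_vector implies negative per-SNP variance at SNP index {bad[0]} "
            f"(value {var[bad[0]]:.3g})"
        )
    return var


def draw_effects(
    annot_values: np.ndarray | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-SNP effects beta on the standardized-genotype scale.

    Annotation mode (``config.tau_vector`` set): beta_j ~ N(0, sum_c a_cj tau_c)
    independently.  Flat polygenic mode: a random subset of ``n_causal`` SNPs
    gets beta ~ N(0, h2_g / n_causal), the rest are zero, so the effect
    variances sum to h2_g exactly.
    """
    rng = rng if rng is not None else config.rng("effects")
    m = config.n_snps
    if config.tau_vector is not None:
        if annot_values is None:
            raise ValueError("annotation values required when tau_vector is set")
        var = per_snp_variance(annot_values, config.tau_vector)
        return rng.standard_normal(m) * np.sqrt(var)
    n_c = config.n_causal if config.n_causal is not None else m
    beta = np.zeros(m)
    causal = rng.choice(m, size=n_c, replace=False)
    beta[causal] = rng.standard_normal(n_c) * np.sqrt(config.h2_g / n_c)
    return beta


def simulate_phenotype(
    cohort: Cohort,
    beta: np.ndarray,
    h2_g: float,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Y = X beta + e with X the standardized genotypes and
    e ~ N(0, 1 - h2_g) i.i.d.; returns the cohort with phenotype attached."""
    if not 0.0 <= h2_g <= 1.0:
        raise ValueError(f"h2_g must lie in [0, 1], got {h2_g}")
    rng = rng if rng is not None else np.random.default_rng(0)
    X = cohort.standardized()
    g = X @ np.asarray(beta, dtype=np.float32)
    e = rng.standard_normal(cohort.n_individuals) * np.sqrt(1.0 - h2_g)
    cohort.genetic_values = np.asarray(g, dtype=float)
    cohort.phenotype = np.asarray(g, dtype=float) + e
    logger.debug("realized genetic variance %.4f (target %.4f)", g.var(), h2_g)
    return cohort


def gwas_sumstats(cohort: Cohort) -> pd.DataFrame:
    """Marginal linear regression of the phenotype on each standardized SNP.

    Returns the sumstats table (SNP, A1, A2, N, Z, CHISQ) with
    chi2_j = z_j^2 where z_j = r_j * sqrt((N-2) / (1-r_j^2)) is the Wald
    statistic of simple linear regression.  Zero-variance SNPs are excluded
    with a logged count.
    """
    if cohort.phenotype is None:
        raise ValueError("cohort has no phenotype; call simulate_phenotype first")
    G = cohort.genotypes.astype(np.float32)
    sd = G.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d zero-variance SNP(s) from GWAS", n_dropped)
    n = cohort.n_individuals
    y = cohort.phenotype - cohort.phenotype.mean()
    ysd = y.std()
    Xc = G[:, keep] - G[:, keep].mean(axis=0)
    r = (Xc.T @ y) / (n * sd[keep] * ysd)
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt((n - 2) / (1.0 - r**2))
    out = cohort.variants.loc[keep, ["snp", "a1", "a2"]].copy()
    out.columns = ["SNP", "A1", "A2"]
    out["N"] = n
    out["Z"] = z.astype(float)
    out["CHISQ"] = out["Z"] ** 2
    return out.reset_index(drop=True)


def write_cohort(prefix, cohort: Cohort, sumstats: pd.DataFrame | None = None) -> None:
    """Write the cohort as PLINK .bed/.bim/.fam (+ sumstats TSV if given)."""
    io.write_plink(prefix, cohort.genotypes, cohort.variants)
    if sumstats is not None:
        io.write_sumstats(str(prefix) + ".sumstats", sumstats)
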