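"""Partitioned LD scores and regression-SNP filters.

The LD score of SNP j with respect to annotation c is
``l(j,c) = sum_k a_ck * r2_jk`` over reference SNPs k within a physical
window of j, with the squared correlation replaced by its small-sample
unbiased estimate ``r2_adj = r2 - (1 - r2) / (n_ref - 2)``; without the
adjustment, null calibration fails at reference panels of a few hundred
samples.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_MHC = ("6", 25_000_000, 34_000_000)
COMMON_MAF = 0.05
CHISQ_MAX = 80.0
CHISQ_N_FRACTION = 0.001


@dataclass
class LDScoreTable:
    """Per-SNP per-annotation LD scores at the scored (regression) SNPs."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    names: list[str]
    scores: np.ndarray  # (M_scored, C)
    w_ld: np.ndarray  # LD score w.r.t. the scored SNP set (weights)
    n_ref: int
    window_bp: int
    M: np.ndarray  # per-annotation totals over reference SNPs
    M_common: np.ndarray  # per-annotation totals over MAF >= 0.05 reference SNPs

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.names.index(name)]

    def subset(self, names: list[str]) -> "LDScoreTable":
        idx = [self.names.index(n) for n in names]
        return LDScoreTable(
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            names=list(names),
            scores=self.scores[:, idx],
            w_ld=self.w_ld,
            n_ref=self.n_ref,
            window_bp=self.window_bp,
            M=self.M[idx],
            M_common=self.M_common[idx],
        )


def adjusted_r2(r2: np.ndarray, n_ref: int) -> np.ndarray:
    """Small-sample unbiased estimate of the squared correlation."""
    return r2 - (1.0 - r2) / (n_ref - 2)


def ld_scores(
    ref_genotypes: np.ndarray,
    variants: pd.DataFrame,
    annot: AnnotationMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    score_mask: np.ndarray | None = None,
    ref_keep_mask: np.ndarray | None = None,
    chunk: int = 1024,
) -> LDScoreTable:
    """Compute partitioned LD scores.

    Scores are computed at the scored SNPs (``score_mask``, default all)
    but sum over every polymorphic reference SNP in the window.
    ``ref_keep_mask`` optionally drops reference SNPs (e.g., non-uniquely
    mappable ones) from the panel before scoring.  Monomorphic reference
    SNPs are excluded with a logged count.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    variants = variants.reset_index(drop=True)
    m_all = len(variants)
    if ref_genotypes.shape[1] != m_all or len(annot.snp_ids) != m_all:
        raise ValueError("genotypes, variants and annotations must cover the same SNPs")
    if score_mask is None:
        score_mask = np.ones(m_all, dtype=bool)
    keep = np.ones(m_all, dtype=bool) if ref_keep_mask is None else np.asarray(ref_keep_mask, bool).copy()

    G = ref_genotypes.astype(np.float64)
    sd = G.std(axis=0)
    n_mono = int((keep & (sd == 0)).sum())
    if n_mono:
        logger.info("excluded %d monomorphic reference SNP(s)", n_mono)
    keep &= sd > 0
    if not (score_mask & keep).any():
        raise ValueError("no scored SNP remains in the reference panel")

    n_ref = G.shape[0]
    A = annot.values  # (m_all, C)
    names = annot.names
    maf = variants["maf"].to_numpy()
    M = A[keep].sum(axis=0)
    M_common = A[keep & (maf >= COMMON_MAF)].sum(axis=0)

    out_rows = np.flatnonzero(score_mask & keep)
    scores = np.zeros((len(out_rows), len(names)))
    w_ld = np.zeros(len(out_rows))

    for chrom in variants["chrom"].unique():
        cmask = (variants["chrom"] == chrom).to_numpy() & keep
        cidx = np.flatnonzero(cmask)
        if cidx.size == 0:
            continue
        pos = variants["pos"].to_numpy()[cidx]
        order = np.argsort(pos, kind="stable")
        cidx, pos = cidx[order], pos[order]
        Z = G[:, cidx]
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        Ac = A[cidx]
        scored_local = np.flatnonzero(score_mask[cidx])
        in_score_set = score_mask[cidx].astype(np.float64)
        row_of = {int(g): r for r, g in enumerate(out_rows)}

        for lo in range(0, len(scored_local), chunk):
            block = scored_local[lo : lo + chunk]
            k0 = int(np.searchsorted(pos, pos[block[0]] - window_bp, side="left"))
            k1 = int(np.searchsorted(pos, pos[block[-1]] + window_bp, side="right"))
            r = (Z[:, block].T @ Z[:, k0:k1]) / n_ref
            r2 = adjusted_r2(np.asarray(r, dtype=np.float64) ** 2, n_ref)
            within = np.abs(pos[k0:k1][None, :] - pos[block][:, None]) <= window_bp
            r2 *= within
            sblock = r2 @ Ac[k0:k1]
            wblock = r2 @ in_score_set[k0:k1]
            for b, j in enumerate(block):
                rr = row_of[int(cidx[j])]
                scores[rr] = sblock[b]
                w_ld[rr] = wblock[b]

    return LDScoreTable(
        snp_ids=variants["snp"].to_numpy()[out_rows],
        chrom=variants["chrom"].to_numpy()[out_rows],
        pos=variants["pos"].to_numpy()[out_rows],
        names=list(names),
        scores=scores,
        w_ld=w_ld,
        n_ref=n_ref,
        window_bp=window_bp,
        M=np.asarray(M, dtype=float),
        M_common=np.asarray(M_common, dtype=float),
    )


def ld_scores_brute_force(
    ref_genotypes: np.ndarray,
    variants: pd.DataFrame,
    annot_values: np.ndarray,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> np.ndarray:
    """Naive O(M^2) double loop used as an independent oracle in tests."""
    G = ref_genotypes.astype(np.float64)
    n, m = G.shape
    Z = (G - G.mean(axis=0)) / G.std(axis=0)
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    out = np.zeros(m)
    for j in range(m):
        for k in range(m):
            if chrom[j] != chrom[k] or abs(int(pos[j]) - int(pos[k])) > window_bp:
                continue
            r = float(Z[:, j] @ Z[:, k]) / n
            out[j] += annot_values[k] * adjusted_r2(r * r, n)
    return out


def filter_snps(
    variants: pd.DataFrame,
    sumstats: pd.DataFrame,
    n: float | None = None,
    mhc: tuple[str, int, int] | None = DEFAULT_MHC,
    maf_threshold: float = COMMON_MAF,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Regression-SNP and heritability-SNP filters.

    Regression SNPs: summary-statistics SNPs with chi2 <= max(80, 0.001 N)
    and outside the MHC region.  Heritability SNPs: reference-panel SNPs
    with MAF >= 0.05.  Returns (filtered sumstats, heritability mask over
    ``variants``, counts dict).
    """
    ss = sumstats.copy()
    if n is None:
        n = float(ss["N"].median())
    threshold = max(CHISQ_MAX, CHISQ_N_FRACTION * n)
    keep = ss["CHISQ"].to_numpy() <= threshold
    n_chisq = int((~keep).sum())

    n_mhc = 0
    if mhc is not None:
        vpos = variants.set_index("snp")
        hit = ss["SNP"].map(
            lambda s: s in vpos.index
            and str(vpos.loc[s, "chrom"]) == str(mhc[0])
            and mhc[1] < vpos.loc[s, "pos"] <= mhc[2]
        ).to_numpy(dtype=bool)
        n_mhc = int((keep & hit).sum())
        keep &= ~hit

    if not keep.any():
        raise ValueError("no regression SNP remains after filtering")
    herit_mask = variants["maf"].to_numpy() >= maf_threshold
    if not herit_mask.any():
        raise ValueError(f"no heritability SNP with MAF >= {maf_threshold}")

    counts = {
        "chisq_threshold": threshold,
        "n_regression": int(keep.sum()),
        "n_excluded_chisq": n_chisq,
        "n_excluded_mhc": n_mhc,
        "n_heritability": int(herit_mask.sum()),
    }
    logger.info("SNP filters: %s", counts)
    return ss.loc[keep].reset_index(drop=True), herit_mask, counts


# ---------------------------------------------------------------------------
# ldscore TSV dialect


def write_ldscores(prefix, table: LDScoreTable) -> None:
    """CHR SNP BP + one column per annotation, gzip TSV, with per-annotation
    M and M_5_50 (common-SNP) count sidecar files."""
    df = pd.DataFrame({"CHR": table.chrom, "SNP": table.snp_ids, "BP": table.pos})
    for i, name in enumerate(table.names):
        df[f"{name}L2"] = table.scores[:, i]
    df["WL2"] = table.w_ld
    with open(f"{prefix}.l2.ldscore.gz", "wb") as fh:
        fh.write(gzip.compress(df.to_csv(sep="\t", index=False).encode(), mtime=0))
    np.savetxt(f"{prefix}.l2.M", table.M[None, :], fmt="%.6g", delimiter="\t")
    np.savetxt(f"{prefix}.l2.M_5_50", table.M_common[None, :], fmt="%.6g", delimiter="\t")


def read_ldscores(prefix, n_ref: int = 0, window_bp: int = DEFAULT_WINDOW_BP) -> LDScoreTable:
    with gzip.open(f"{prefix}.l2.ldscore.gz", "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    names = [c[:-2] for c in df.columns if c.endswith("L2") and c != "WL2"]
    scores = df[[f"{n}L2" for n in names]].to_numpy()
    w_ld = df["WL2"].to_numpy() if "WL2" in df.columns else scores[:, 0]
    M = np.loadtxt(f"{prefix}.l2.M", ndmin=1)
    M_common = np.loadtxt(f"{prefix}.l2.M_5_50", ndmin=1)
    return LDScoreTable(
        snp_ids=df["SNP"].to_numpy(),
        chrom=df["CHR"].to_numpy(),
        pos=df["BP"].to_numpy(),
        names=names,
        scores=scores,
        w_ld=w_ld,
        n_ref=n_ref,
        window_bp=window_bp,
        M=M,
        M_common=M_common,
    )
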