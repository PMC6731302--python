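"""Stratified regression of GWAS chi-square statistics on partitioned LD
scores.

The model: E[chi2_j] = N * sum_c l(j,c) tau_c + 1, where tau_c is the
contribution of annotation c to per-SNP heritability
(Var(beta_j) = sum_c a_cj tau_c).  The fit is weighted least squares with a
free intercept by default (constrainable to 1).  All uncertainty comes from
a genomic block jackknife: the regression SNPs are split into 200
contiguous blocks with equal SNP counts, the fit is repeated leaving one
block out, and every downstream quantity (tau*, %heritability, enrichment,
expected enrichment) is recomputed per leave-one-out fit.

Reported quantities per annotation c, over the heritability SNPs (MAF >=
0.05 in the reference panel):

* observed %h2(c)   = sum_{j in c} Var(beta_j) / h2_g
* observed enrichment = %h2(c) / %SNPs(c)
* tau*_c            = tau_c * sd(c) / (h2_g / M)
* expected %h2 / enrichment: per-SNP variances from a conditioning model
  fitted WITHOUT the focal annotation (its tau set to zero).

Negative %h2 and enrichment estimates are reported as-is, never truncated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import MIN_PCT_SNPS, AnnotationMatrix
from .ldscore import LDScoreTable

logger = logging.getLogger(__name__)

DEFAULT_N_BLOCKS = 200


class SizeGateError(ValueError):
    """Annotation too small for a reliable observed-enrichment estimate."""


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Boundaries of contiguous blocks with equal SNP counts."""
    n_blocks = min(n_blocks, n)
    return np.linspace(0, n, n_blocks + 1).round().astype(int)


def jackknife_se(full: float, loo: np.ndarray) -> float:
    """Delete-one block jackknife standard error."""
    loo = np.asarray(loo, dtype=float)
    b = len(loo)
    return float(np.sqrt((b - 1) / b * np.sum((loo - loo.mean()) ** 2)))


def _two_sided_p(value: float, se: float, null: float, df: int | None = None) -> float:
    if se == 0:
        return 1.0 if value == null else 0.0
    t = (value - null) / se
    if df is None:
        return float(2 * stats.norm.sf(abs(t)))
    return float(2 * stats.t.sf(abs(t), df))


@dataclass
class ModelFit:
    """A fitted stratified regression with its leave-one-block-out refits."""

    names: list[str]
    tau: np.ndarray
    intercept: float
    tau_loo: np.ndarray  # (n_blocks, C)
    intercept_loo: np.ndarray
    M: int  # number of heritability SNPs
    annot_sums: np.ndarray  # sum_j a_cj over heritability SNPs
    cross: np.ndarray  # A^T A over heritability SNPs
    sd: np.ndarray  # sd of a_cj over heritability SNPs
    A_herit: np.ndarray = field(repr=False)  # (M, C) annotation values
    n_blocks: int = DEFAULT_N_BLOCKS
    n_regression_snps: int = 0

    @property
    def h2_g(self) -> float:
        """Total SNP heritability: sum_j sum_c a_cj tau_c over heritability SNPs."""
        return float(self.annot_sums @ self.tau)

    @property
    def h2_loo(self) -> np.ndarray:
        return self.tau_loo @ self.annot_sums

    def index(self, name: str) -> int:
        return self.names.index(name)

    def pct_snps(self, name: str) -> float:
        """Mean annotation value over heritability SNPs (= |A|/M for binary)."""
        return float(self.annot_sums[self.index(name)] / self.M)


def _find_collinear_pair(X: np.ndarray, names: list[str]) -> tuple[str, str] | None:
    C = np.corrcoef(X.T)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(C[i, j]) > 1 - 1e-12:
                return names[i], names[j]
    return None


def fit(
    sumstats: pd.DataFrame,
    ld: LDScoreTable,
    annot: AnnotationMatrix,
    herit_mask: np.ndarray,
    names: list[str] | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    intercept: str = "free",
    weighted: bool = True,
) -> ModelFit:
    """Weighted least squares of chi2 on {N * l(j,c)}_c with jackknife refits.

    ``sumstats`` is matched to the LD score table by SNP id.  ``herit_mask``
    selects heritability SNPs over the full variant set of ``annot``.
    Weights (switchable off) are the product of an LD overcounting term
    1/max(1, l_w(j)) and a heteroskedasticity term 1/(2 (N l_tot(j) taubar
    + 1)^2) with taubar from a one-pass pre-fit, then one re-weighting
    iteration.
    """
    if names is None:
        names = list(ld.names)
    if intercept not in ("free", "fixed"):
        raise ValueError("intercept must be 'free' or 'fixed'")

    ss = sumstats.set_index("SNP")
    present = pd.Index(ld.snp_ids).isin(ss.index)
    if not present.any():
        raise ValueError("no overlap between sumstats and LD score SNPs")
    snp_order = np.asarray(ld.snp_ids)[present]
    chisq = ss.loc[snp_order, "CHISQ"].to_numpy(dtype=float)
    N = float(ss.loc[snp_order, "N"].median())

    idx = [ld.names.index(n) for n in names]
    L = ld.scores[present][:, idx]
    w_ld = ld.w_ld[present]
    m_reg, n_annot = L.shape
    if m_reg < 200 * n_annot:
        warnings.warn(
            f"{m_reg} regression SNPs for {n_annot} annotations "
            f"(fewer than 200 per annotation)",
            stacklevel=2,
        )

    X_annot = N * L
    if np.linalg.matrix_rank(np.column_stack([X_annot, np.ones(m_reg)])) < n_annot + 1:
        pair = _find_collinear_pair(X_annot, names)
        detail = f": annotations {pair[0]!r} and {pair[1]!r} are collinear" if pair else ""
        raise ValueError("rank-deficient design" + detail)

    free = intercept == "free"
    X = np.column_stack([X_annot, np.ones(m_reg)]) if free else X_annot
    y = chisq if free else chisq - 1.0

    # total LD score (all-ones annotation) drives the heteroskedasticity weight
    l_tot = L[:, names.index("base")] if "base" in names else np.maximum(w_ld, 1.0)

    def weights(taubar: float) -> np.ndarray:
        if not weighted:
            return np.ones(m_reg)
        het = 1.0 / (2.0 * (N * l_tot * max(taubar, 0.0) + 1.0) ** 2)
        over = 1.0 / np.maximum(w_ld, 1.0)
        w = het * over
        return w / w.mean()

    taubar = max(float(chisq.mean()) - 1.0, 0.0) / (N * float(l_tot.mean()))
    coef = _wls(X, y, weights(taubar))

    # one re-weighting iteration with taubar from the pre-fit
    A_h = annot.values[:, [annot.names.index(n) for n in names]][herit_mask]
    sums = A_h.sum(axis=0)
    taubar = max(float(sums @ coef[:n_annot]), 0.0) / max(len(A_h), 1)
    w = weights(taubar)

    bounds = _block_bounds(m_reg, n_blocks)
    n_blk = len(bounds) - 1
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y
    coef = np.linalg.solve(XtWX, XtWy)

    coef_loo = np.empty((n_blk, X.shape[1]))
    for b in range(n_blk):
        sl = slice(bounds[b], bounds[b + 1])
        XtWX_b = X[sl].T @ Xw[sl]
        XtWy_b = Xw[sl].T @ y[sl]
        try:
            coef_loo[b] = np.linalg.solve(XtWX - XtWX_b, XtWy - XtWy_b)
        except np.linalg.LinAlgError:
            # an annotation can vanish when its only SNPs sit in the dropped
            # block (possible below the size gate); minimal-norm solution
            coef_loo[b] = np.linalg.lstsq(XtWX - XtWX_b, XtWy - XtWy_b, rcond=None)[0]

    tau = coef[:n_annot]
    icpt = float(coef[n_annot]) if free else 1.0
    icpt_loo = coef_loo[:, n_annot] if free else np.ones(n_blk)

    return ModelFit(
        names=list(names),
        tau=tau,
        intercept=icpt,
        tau_loo=coef_loo[:, :n_annot],
        intercept_loo=icpt_loo,
        M=int(herit_mask.sum()),
        annot_sums=sums,
        cross=A_h.T @ A_h,
        sd=A_h.std(axis=0),
        A_herit=A_h,
        n_blocks=n_blk,
        n_regression_snps=m_reg,
    )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


# ---------------------------------------------------------------------------
# derived quantities


def tau_star(fit: ModelFit, name: str) -> dict:
    """Standardized effect size tau*_c = tau_c sd(c) / (h2_g / M) with
    jackknife SE and a two-sided normal p-value."""
    c = fit.index(name)
    sd_c = fit.sd[c]
    if sd_c == 0:
        warnings.warn(f"annotation {name!r} is constant over heritability SNPs; tau* = 0")
        return {"tau_star": 0.0, "se": 0.0, "p": 1.0}
    if fit.h2_g <= 0:
        raise ValueError(f"non-positive h2_g estimate ({fit.h2_g:.3g}); tau* undefined")

    def formula(tau_vec: np.ndarray) -> float:
        h2 = float(fit.annot_sums @ tau_vec)
        return float(tau_vec[c] * sd_c / (h2 / fit.M))

    value = formula(fit.tau)
    loo = np.array([formula(t) for t in fit.tau_loo])
    se = jackknife_se(value, loo)
    return {"tau_star": value, "se": se, "p": _two_sided_p(value, se, 0.0)}


def observed_enrichment(fit: ModelFit, name: str, force: bool = False) -> dict:
    """Observed %heritability and heritability enrichment with jackknife SEs.

    %h2(c) = sum_{j} a_jc Var(beta_j) / h2_g, enrichment = %h2(c) / %SNPs(c);
    the enrichment p-value tests enrichment != 1 by jackknife-t.  Annotations
    spanning < 0.4% of heritability SNPs are refused unless ``force`` (use
    expected_enrichment for those).
    """
    c = fit.index(name)
    pct = fit.pct_snps(name)
    if pct < MIN_PCT_SNPS and not force:
        raise SizeGateError(
            f"annotation {name!r} spans {100 * pct:.3f}% of common SNPs "
            f"(< {100 * MIN_PCT_SNPS}%); observed enrichment is unreliable — "
            "use expected_enrichment, or pass force=True"
        )

    def formula(tau_vec: np.ndarray) -> tuple[float, float]:
        h2_c = float(fit.cross[c] @ tau_vec)
        h2 = float(fit.annot_sums @ tau_vec)
        pct_h2 = h2_c / h2
        return pct_h2, pct_h2 / pct

    pct_h2, enr = formula(fit.tau)
    loo = np.array([formula(t) for t in fit.tau_loo])
    pct_h2_se = jackknife_se(pct_h2, loo[:, 0])
    enr_se = jackknife_se(enr, loo[:, 1])
    return {
        "pct_snps": pct,
        "pct_h2": pct_h2,
        "pct_h2_se": pct_h2_se,
        "enrichment": enr,
        "enrichment_se": enr_se,
        "enrichment_p": _two_sided_p(enr, enr_se, 1.0, df=fit.n_blocks - 1),
    }


def expected_enrichment(
    conditioning_fit: ModelFit, focal_values: np.ndarray, name: str = "focal"
) -> dict:
    """Enrichment expected for a focal annotation under a conditioning model
    fitted without it (i.e., assuming the focal annotation's tau is zero).

    ``focal_values`` are the focal annotation's values over the conditioning
    fit's heritability SNPs.  A focal annotation that is itself part of the
    conditioning model is rejected (its tau there is not zero, so the result
    would not be "expected"); a value-duplicate under a different name is
    allowed and reproduces that annotation's model-implied enrichment.
    """
    a_f = np.asarray(focal_values, dtype=float)
    if a_f.shape != (conditioning_fit.M,):
        raise ValueError(
            f"focal values must cover the {conditioning_fit.M} heritability SNPs"
        )
    if name in conditioning_fit.names:
        raise ValueError(
            f"focal annotation {name!r} is in the conditioning model; "
            "refit the conditioning model without it first"
        )
    u = conditioning_fit.A_herit.T @ a_f
    pct = float(a_f.mean())

    def formula(tau_vec: np.ndarray) -> tuple[float, float]:
        pct_h2 = float(u @ tau_vec) / float(conditioning_fit.annot_sums @ tau_vec)
        return pct_h2, pct_h2 / pct

    pct_h2, enr = formula(conditioning_fit.tau)
    loo = np.array([formula(t) for t in conditioning_fit.tau_loo])
    return {
        "pct_snps": pct,
        "expected_pct_h2": pct_h2,
        "expected_pct_h2_se": jackknife_se(pct_h2, loo[:, 0]),
        "expected_enrichment": enr,
        "expected_enrichment_se": jackknife_se(enr, loo[:, 1]),
    }


def partition(
    sumstats: pd.DataFrame,
    ld: LDScoreTable,
    annot: AnnotationMatrix,
    herit_mask: np.ndarray,
    focal: list[str],
    n_blocks: int = DEFAULT_N_BLOCKS,
    intercept: str = "free",
    weighted: bool = True,
    force: bool = False,
) -> pd.DataFrame:
    """Joint conditional analysis of one or more focal annotations.

    One regression contains the conditioning annotations plus every focal
    annotation and its flank companion (flanks guard against model
    misspecification at element boundaries); tau*, observed %h2/enrichment
    come from that joint fit.  Expected %h2/enrichment come from a second
    fit on the conditioning set alone (focal annotations and their flanks
    removed).  Returns one row per focal annotation.
    """
    for name in focal:
        if name not in annot:
            raise ValueError(f"focal annotation {name!r} not in the matrix")
    flank_of = {n: annot.meta(n)["flank_of"] for n in annot.names}
    flanks = {f for f in focal for n in annot.names if flank_of[n] == f}
    conditioning = [
        n for n in annot.names if n not in focal and flank_of[n] not in focal
    ]
    if not conditioning:
        raise ValueError(
            "no conditioning annotations remain after removing the focal set; "
            "include at least the all-SNPs 'base' annotation"
        )

    joint = fit(
        sumstats, ld, annot, herit_mask,
        names=annot.names, n_blocks=n_blocks, intercept=intercept, weighted=weighted,
    )
    cond = fit(
        sumstats, ld, annot, herit_mask,
        names=conditioning, n_blocks=n_blocks, intercept=intercept, weighted=weighted,
    )

    herit_values = {
        n: annot[n][np.asarray(herit_mask, bool)] for n in focal
    }
    rows = []
    for name in focal:
        obs = observed_enrichment(joint, name, force=force)
        try:
            ts = tau_star(joint, name)
        except ValueError as exc:  # e.g. non-positive h2 estimate on a null trait
            warnings.warn(f"tau* undefined for {name!r}: {exc}")
            ts = {"tau_star": np.nan, "se": np.nan, "p": np.nan}
        exp = expected_enrichment(cond, herit_values[name], name=name)
        rows.append(
            {
                "annotation": name,
                "pct_snps": obs["pct_snps"],
                "pct_h2": obs["pct_h2"],
                "pct_h2_se": obs["pct_h2_se"],
                "enrichment": obs["enrichment"],
                "enrichment_se": obs["enrichment_se"],
                "enrichment_p": obs["enrichment_p"],
                "tau": joint.tau[joint.index(name)],
                "tau_star": ts["tau_star"],
                "tau_star_se": ts["se"],
                "tau_star_p": ts["p"],
                "expected_pct_h2": exp["expected_pct_h2"],
                "expected_pct_h2_se": exp["expected_pct_h2_se"],
                "expected_enrichment": exp["expected_enrichment"],
                "expected_enrichment_se": exp["expected_enrichment_se"],
            }
        )
    logger.info(
        "joint fit: %d annotations (%d focal, %d flank, %d conditioning), h2=%.4f",
        len(annot.names), len(focal), len(flanks), len(conditioning), joint.h2_g,
    )
    return pd.DataFrame(rows)
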