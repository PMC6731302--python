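"""Excess overlap between annotations, cross-trait random-effects
meta-analysis, and trait-class contrasts.

Excess overlap of annotations A and B over M SNPs:
``Excess(A, B) = (|A∩B|/M) / ((|A|/M)(|B|/M))`` — 1 under independence,
M/|B| when A is a subset of B.  Standard errors come from a 200-block
jackknife over SNPs, using the same contiguous genomic blocks as the
heritability regression for comparability.

Meta-analysis pools per-trait enrichment or tau* estimates with
DerSimonian-Laird random effects; class contrasts compare the pooled means
of two disjoint trait classes with an unpaired z-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.meta_analysis import combine_effects

from .regression import _block_bounds, jackknife_se

logger = logging.getLogger(__name__)

TRAIT_CLASSES = ("blood", "autoimmune", "brain", "other")


@dataclass
class OverlapResult:
    annotation_a: str
    annotation_b: str
    excess: float
    se: float
    n_intersection: int
    n_a: int
    n_b: int
    n_snps: int


def excess_overlap(
    a: np.ndarray,
    b: np.ndarray,
    n_blocks: int = 200,
    names: tuple[str, str] = ("A", "B"),
) -> OverlapResult:
    """Excess overlap of two binary annotations with block-jackknife SE."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("annotations must cover the same SNPs")
    m = len(a)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("excess overlap is undefined for an empty annotation")

    def formula(na: float, nb: float, nab: float, mm: float) -> float:
        return (nab / mm) / ((na / mm) * (nb / mm))

    na, nb, nab = int(a.sum()), int(b.sum()), int((a & b).sum())
    value = formula(na, nb, nab, m)

    bounds = _block_bounds(m, n_blocks)
    loo = []
    for k in range(len(bounds) - 1):
        sl = slice(bounds[k], bounds[k + 1])
        na_b = na - int(a[sl].sum())
        nb_b = nb - int(b[sl].sum())
        nab_b = nab - int((a[sl] & b[sl]).sum())
        m_b = m - (bounds[k + 1] - bounds[k])
        if na_b == 0 or nb_b == 0 or m_b == 0:
            loo.append(value)  # degenerate block; contributes no variance
        else:
            loo.append(formula(na_b, nb_b, nab_b, m_b))
    se = jackknife_se(value, np.asarray(loo))
    return OverlapResult(names[0], names[1], value, se, nab, na, nb, m)


# ---------------------------------------------------------------------------
# meta-analysis across traits

TRAIT_RESULT_COLUMNS = ["trait", "trait_class", "N", "estimate", "se"]


def _validate_trait_results(results: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"trait result table missing columns: {missing}")
    bad = set(results["trait_class"]) - set(TRAIT_CLASSES)
    if bad:
        raise ValueError(f"unknown trait classes {sorted(bad)}; expected {TRAIT_CLASSES}")
    return results


def drop_duplicate_traits(results: pd.DataFrame) -> pd.DataFrame:
    """When one trait appears in several datasets, keep the largest-N one."""
    return (
        results.sort_values("N", ascending=False)
        .drop_duplicates(subset="trait", keep="first")
        .sort_index()
        .reset_index(drop=True)
    )


def meta_analyze(estimates: np.ndarray, ses: np.ndarray) -> dict:
    """DerSimonian-Laird random-effects pooling of per-trait estimates.

    Returns pooled mean, SE, between-trait variance tau2 and relative
    per-trait weights.  A single trait is returned unchanged with a warning.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and SEs must have the same length")
    if not np.isfinite(se).all() or (se <= 0).any():
        raise ValueError("every trait needs a finite positive SE")
    if len(est) == 1:
        warnings.warn("meta-analysis of a single trait returns it unchanged")
        return {"pooled": float(est[0]), "se": float(se[0]), "tau2": 0.0, "weights": np.ones(1)}
    with warnings.catch_warnings():
        # statsmodels emits divide-by-zero warnings when its (untruncated)
        # moment estimate of tau2 is negative; that branch is replaced below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = combine_effects(est, se**2, method_re="dl")
    if res.tau2 > 0:
        return {
            "pooled": float(res.mean_effect_re),
            "se": float(res.sd_eff_w_re),
            "tau2": float(res.tau2),
            "weights": np.asarray(res.weights_rel_re, dtype=float),
        }
    # the DL moment estimate is truncated at zero, where random effects
    # reduce to inverse-variance fixed-effects pooling
    w = 1.0 / se**2
    return {
        "pooled": float(w @ est / w.sum()),
        "se": float(np.sqrt(1.0 / w.sum())),
        "tau2": 0.0,
        "weights": w / w.sum(),
    }


def meta_analyze_traits(results: pd.DataFrame, dedupe: bool = True) -> dict:
    """Meta-analyze a trait result table (columns trait, trait_class, N,
    estimate, se) after optional duplicate-trait removal."""
    results = _validate_trait_results(results)
    if dedupe:
        results = drop_duplicate_traits(results)
    if len(results) < 2:
        warnings.warn("fewer than 2 traits; returning the single estimate")
    return meta_analyze(results["estimate"].to_numpy(), results["se"].to_numpy())


def class_contrast(
    results: pd.DataFrame,
    class_a: str | list[str],
    class_b: str | list[str],
    dedupe: bool = True,
) -> dict:
    """Difference between two trait classes' pooled means.

    Each class is meta-analyzed separately; the difference is tested with an
    unpaired two-sided z = (m_a - m_b) / sqrt(se_a^2 + se_b^2).  Overlapping
    class memberships are rejected.
    """
    results = _validate_trait_results(results)
    if dedupe:
        results = drop_duplicate_traits(results)
    ca = [class_a] if isinstance(class_a, str) else list(class_a)
    cb = [class_b] if isinstance(class_b, str) else list(class_b)
    in_a = results["trait_class"].isin(ca)
    in_b = results["trait_class"].isin(cb)
    traits_a = set(results.loc[in_a, "trait"])
    traits_b = set(results.loc[in_b, "trait"])
    # identical classes give a well-defined zero contrast; partial overlap is an error
    if traits_a & traits_b and traits_a != traits_b:
        raise ValueError("trait classes overlap; the contrast requires disjoint classes")
    if not in_a.any() or not in_b.any():
        raise ValueError("both classes must contain at least one trait")
    ma = meta_analyze(results.loc[in_a, "estimate"].to_numpy(), results.loc[in_a, "se"].to_numpy())
    mb = meta_analyze(results.loc[in_b, "estimate"].to_numpy(), results.loc[in_b, "se"].to_numpy())
    diff = ma["pooled"] - mb["pooled"]
    se = float(np.sqrt(ma["se"] ** 2 + mb["se"] ** 2))
    z = diff / se if se > 0 else np.inf * np.sign(diff) if diff else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0:
        p = 1.0
    return {
        "difference": diff,
        "se": se,
        "z": float(z) if np.isfinite(z) else z,
        "p": p,
        "mean_a": ma["pooled"],
        "se_a": ma["se"],
        "mean_b": mb["pooled"],
        "se_b": mb["se"],
    }


def multiple_testing(
    pvalues: np.ndarray, n_tests: int, alpha: float = 0.05, method: str = "bonferroni"
) -> np.ndarray:
    """Bonferroni significance calls against an explicit designed family.

    ``n_tests`` is the size of the full designed hypothesis family (which
    may exceed the number of p-values actually computed, e.g., 281 consensus
    9-mers x 27 one-mismatch neighbours = 7587).
    """
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests < len(p):
        raise ValueError(f"n_tests ({n_tests}) smaller than number of p-values ({len(p)})")
    return p < alpha / n_tests
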