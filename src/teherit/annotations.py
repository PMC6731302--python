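"""SNP-level annotation construction.

Builds the annotation matrices consumed by the stratified regression:
element-body annotations from genomic intervals, flanking-region
annotations, element-age quintiles (milliDiv divergence as the age proxy),
k-mer motif annotations from genome scans with mismatches, unions of
chromatin tracks, mappability restrictions, and size-matched random
controls.

Coordinate conventions (stated once, tested): intervals are BED-style
0-based half-open; SNP positions are 1-based; a SNP at position p lies in
[start, end) iff start < p <= end.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
FLANK_WIDTHS = (100, 200, 500, 1000)
DEFAULT_FLANK_BP = 500
#: annotations spanning less than this fraction of common SNPs get
#: expected-enrichment estimates only
MIN_PCT_SNPS = 0.004

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# interval primitives


def merge_intervals(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    """Union overlapping/adjacent intervals; {chrom: (k, 2) array}, sorted."""
    merged: dict[str, np.ndarray] = {}
    for chrom, grp in intervals.groupby("chrom"):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        arr = arr[np.argsort(arr[:, 0])]
        out = []
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[str(chrom)] = np.array(out, dtype=np.int64)
    return merged


def _positions_in_merged(pos: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """1-based positions inside any 0-based half-open merged interval."""
    if merged.size == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos, side="left")  # count of starts < pos
    inside = idx > 0
    inside[inside] = merged[idx[inside] - 1, 1] >= pos[inside]
    return inside


def _check_chromosomes(variants: pd.DataFrame, intervals: pd.DataFrame) -> None:
    unmatched = set(intervals["chrom"].astype(str)) - set(variants["chrom"].astype(str))
    if unmatched:
        raise ValueError(
            "interval chromosomes absent from the variant table: "
            + ", ".join(sorted(unmatched))
        )


def snps_in_intervals(variants: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Binary annotation: 1 iff the SNP lies in the union of the intervals."""
    variants = variants.reset_index(drop=True)
    values = np.zeros(len(variants), dtype=np.int8)
    if len(intervals) == 0:
        return values
    _check_chromosomes(variants, intervals)
    merged = merge_intervals(intervals)
    for chrom, grp in variants.groupby("chrom"):
        if str(chrom) in merged:
            mask = _positions_in_merged(grp["pos"].to_numpy(), merged[str(chrom)])
            values[grp.index.to_numpy()] = mask
    return values


def flank_intervals(intervals: pd.DataFrame, width: int) -> pd.DataFrame:
    """Flanking regions: within ``width`` bases of an element boundary but
    outside every element body.  Flanks running past the chromosome start are
    clipped at 0 (logged)."""
    if width <= 0:
        raise ValueError(f"flank width must be positive, got {width}")
    merged = merge_intervals(intervals)
    rows = []
    clipped = 0
    for chrom, arr in merged.items():
        for s, e in arr:
            left = max(0, s - width)
            clipped += left != s - width
            rows.append({"chrom": chrom, "start": left, "end": s})
            rows.append({"chrom": chrom, "start": e, "end": e + width})
    if clipped:
        logger.info("clipped %d flank(s) at chromosome start", clipped)
    flanks = pd.DataFrame(rows)
    # subtract element bodies (an adjacent element may intrude into a flank)
    out = []
    for chrom, grp in flanks.groupby("chrom"):
        bodies = merged[str(chrom)]
        for s, e in merge_intervals(grp)[str(chrom)]:
            cur = s
            for bs, be in bodies:
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    out.append({"chrom": chrom, "start": cur, "end": bs})
                cur = max(cur, be)
            if cur < e:
                out.append({"chrom": chrom, "start": cur, "end": e})
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def flank_annotation(
    variants: pd.DataFrame, intervals: pd.DataFrame, width: int = DEFAULT_FLANK_BP
) -> np.ndarray:
    """Binary annotation of the ``width``-bp flanking regions of the elements."""
    fl = flank_intervals(intervals, width)
    if len(fl) == 0:
        return np.zeros(len(variants), dtype=np.int8)
    return snps_in_intervals(variants, fl)


# ---------------------------------------------------------------------------
# element age


def snp_milli_div(
    variants: pd.DataFrame, intervals: pd.DataFrame, tie: str = "older"
) -> np.ndarray:
    """Per-SNP divergence score inherited from the covering element.

    SNPs covered by two elements with different milliDiv get the older
    (larger) value by default (``tie`` in {"older", "younger", "mean"});
    conflicts are counted and logged.  SNPs outside every dated element get
    NaN.
    """
    if intervals["milli_div"].isna().any():
        raise ValueError("every contributing interval needs a milli_div value")
    _check_chromosomes(variants, intervals)
    variants = variants.reset_index(drop=True)
    out = np.full(len(variants), np.nan)
    counts = np.zeros(len(variants), dtype=int)
    sums = np.zeros(len(variants))
    conflicts = np.zeros(len(variants), dtype=bool)
    for chrom, grp in variants.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        gidx = grp.index.to_numpy()
        sub = intervals[intervals["chrom"].astype(str) == str(chrom)]
        for _, iv in sub.iterrows():
            inside = (iv["start"] < pos) & (pos <= iv["end"])
            tgt = gidx[inside]
            md = float(iv["milli_div"])
            prev = out[tgt]
            new_conflict = (~np.isnan(prev)) & (prev != md)
            conflicts[tgt[new_conflict]] = True
            if tie == "older":
                out[tgt] = np.where(np.isnan(prev), md, np.maximum(prev, md))
            elif tie == "younger":
                out[tgt] = np.where(np.isnan(prev), md, np.minimum(prev, md))
            elif tie == "mean":
                counts[tgt] += 1
                sums[tgt] += md
                out[tgt] = sums[tgt] / counts[tgt]
            else:
                raise ValueError(f"unknown tie rule {tie!r}")
    n_conf = int(conflicts.sum())
    if n_conf:
        logger.info("%d SNP(s) covered by elements with conflicting milliDiv", n_conf)
    return out


def age_quintile_annotations(
    variants: pd.DataFrame,
    intervals: pd.DataFrame,
    by: str = "snp",
    tie: str = "older",
) -> tuple[list[np.ndarray], np.ndarray]:
    """Five disjoint binary annotations stratifying element SNPs by age.

    Quintile boundaries are the 20/40/60/80 percentiles of the per-SNP
    (default) or per-element (``by="element"``) milliDiv distribution.
    Quintile 1 is youngest (lowest divergence), 5 oldest.  The union of the
    five equals the set of SNPs in dated elements.
    """
    div = snp_milli_div(variants, intervals, tie=tie)
    dated = ~np.isnan(div)
    if not dated.any():
        raise ValueError("no SNP falls in a dated element")
    if by == "snp":
        pool = div[dated]
    elif by == "element":
        pool = intervals["milli_div"].to_numpy(dtype=float)
    else:
        raise ValueError(f"by must be 'snp' or 'element', got {by!r}")
    bounds = np.quantile(pool, [0.2, 0.4, 0.6, 0.8])
    q = np.searchsorted(bounds, div[dated], side="left")  # boundary ties -> lower
    annots = []
    for k in range(5):
        a = np.zeros(len(variants), dtype=np.int8)
        a[np.flatnonzero(dated)[q == k]] = 1
        annots.append(a)
    return annots, bounds


# ---------------------------------------------------------------------------
# k-mer motif annotations


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_neighbors(query: str, distance: int = 1) -> list[str]:
    """All words at Hamming distance exactly ``distance`` (=1) from the query,
    in lexicographic order; a k-mer has exactly 3k such neighbours."""
    if distance != 1:
        raise ValueError("only distance-1 neighbourhoods are supported")
    if set(query) - set(ALPHABET):
        raise ValueError(f"query must be over {ALPHABET}, got {query!r}")
    out = set()
    for i, base in enumerate(query):
        for alt in ALPHABET:
            if alt != base:
                out.add(query[:i] + alt + query[i + 1 :])
    return sorted(out)


def _window_mismatches(seq_codes: np.ndarray, query: str) -> np.ndarray:
    """Hamming distance of every length-k window to the query (vectorized).

    Non-ACGT characters never match any query base (universal mismatch).
    """
    k = len(query)
    n_win = len(seq_codes) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int32)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    mm = np.zeros(n_win, dtype=np.int32)
    for i in range(k):
        mm += seq_codes[i : i + n_win] != q[i]
    return mm


def kmer_scan(
    genome: dict[str, str], query: str, max_mismatch: int = 1
) -> pd.DataFrame:
    """Scan both strands of every sequence for windows within ``max_mismatch``
    Hamming distance of the query; returns 0-based half-open hit intervals."""
    if set(query) - set(ALPHABET):
        raise ValueError(f"query must be over {ALPHABET}, got {query!r}")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    k = len(query)
    rc = reverse_complement(query)
    rows = []
    for chrom, seq in genome.items():
        codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        hits_fwd = _window_mismatches(codes, query) <= max_mismatch
        hits_rev = _window_mismatches(codes, rc) <= max_mismatch
        for strand, hits in (("+", hits_fwd), ("-", hits_rev)):
            for start in np.flatnonzero(hits):
                rows.append(
                    {"chrom": chrom, "start": int(start), "end": int(start) + k, "strand": strand}
                )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def kmer_annotation(
    variants: pd.DataFrame,
    genome: dict[str, str],
    query: str,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Motif-footprint intervals and the binary SNP annotation over them."""
    hits = kmer_scan(genome, query, max_mismatch)
    if len(hits) == 0:
        return hits, np.zeros(len(variants), dtype=np.int8)
    shared = hits[hits["chrom"].astype(str).isin(set(variants["chrom"].astype(str)))]
    if len(shared) == 0:
        return hits, np.zeros(len(variants), dtype=np.int8)
    return hits, snps_in_intervals(variants, shared)


# ---------------------------------------------------------------------------
# chromatin, mappability, random controls


def chromatin_union(variants: pd.DataFrame, tracks: list[pd.DataFrame]) -> np.ndarray:
    """Binary annotation over the union of >= 1 interval tracks."""
    if not tracks:
        raise ValueError("at least one track is required")
    combined = pd.concat([t[["chrom", "start", "end"]] for t in tracks], ignore_index=True)
    return snps_in_intervals(variants, combined)


def mappability_restrict(
    values: np.ndarray, variants: pd.DataFrame, mappability: pd.DataFrame
) -> np.ndarray:
    """Keep only SNPs whose mappability score at the SNP position equals 1.

    ``mappability`` is a per-position track (chrom, start, end, value;
    0-based half-open).  Positions missing from the track are treated as
    non-uniquely mappable (counted and logged).  Produces the "-unique"
    companion of an annotation.
    """
    variants = variants.reset_index(drop=True)
    unique = np.zeros(len(variants), dtype=bool)
    covered = np.zeros(len(variants), dtype=bool)
    for chrom, grp in variants.groupby("chrom"):
        sub = mappability[mappability["chrom"].astype(str) == str(chrom)]
        if len(sub) == 0:
            continue
        pos = grp["pos"].to_numpy()
        gidx = grp.index.to_numpy()
        for _, row in sub.iterrows():
            inside = (row["start"] < pos) & (pos <= row["end"])
            covered[gidx[inside]] = True
            if row["value"] == 1:
                unique[gidx[inside]] = True
    n_missing = int((np.asarray(values, dtype=bool) & ~covered).sum())
    if n_missing:
        logger.info("%d annotated SNP(s) missing from the mappability track", n_missing)
    return (np.asarray(values, dtype=np.int8) * unique).astype(np.int8)


def random_control_intervals(
    variants: pd.DataFrame,
    template: pd.DataFrame,
    seed: int,
    chrom_sizes: dict[str, int] | None = None,
    max_pct_dev: float = 0.10,
    max_resample: int = 100,
) -> pd.DataFrame:
    """Random control regions with the template's interval-length multiset.

    Intervals are placed uniformly on the chromosomes covered by the
    template; placement is resampled (up to ``max_resample`` times) until the
    control annotation's %SNPs is within ``max_pct_dev`` relative of the
    template's, keeping the closest attempt otherwise.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(set(template["chrom"].astype(str)))
    if chrom_sizes is None:
        chrom_sizes = {}
        for c in chroms:
            vc = variants[variants["chrom"].astype(str) == c]
            hi = int(vc["pos"].max()) if len(vc) else int(template["end"].max())
            chrom_sizes[c] = max(hi, int(template[template["chrom"].astype(str) == c]["end"].max()))
    lengths = (template["end"] - template["start"]).to_numpy()
    longest = int(lengths.max())
    usable = [c for c in chroms if chrom_sizes[c] >= longest]
    if not usable:
        raise ValueError(
            f"no chromosome is long enough for the longest template interval ({longest} bp)"
        )
    target = snps_in_intervals(variants, template).mean()

    best, best_dev = None, np.inf
    for _ in range(max_resample):
        rows = []
        for length in lengths:
            ok = [c for c in usable if chrom_sizes[c] >= length]
            c = ok[rng.integers(len(ok))]
            s = int(rng.integers(0, chrom_sizes[c] - int(length) + 1))
            rows.append({"chrom": c, "start": s, "end": s + int(length)})
        cand = pd.DataFrame(rows)
        got = snps_in_intervals(variants, cand).mean()
        dev = abs(got - target) / target if target > 0 else 0.0
        if dev < best_dev:
            best, best_dev = cand, dev
        if dev <= max_pct_dev:
            return cand
    logger.warning(
        "control placement did not reach %.0f%% relative of template %%SNPs "
        "after %d tries (best %.1f%%)",
        100 * max_pct_dev, max_resample, 100 * best_dev,
    )
    return best


def random_control_annotation(
    variants: pd.DataFrame, template: pd.DataFrame, seed: int, **kwargs
) -> np.ndarray:
    """Binary annotation over size-matched random control regions."""
    return snps_in_intervals(
        variants, random_control_intervals(variants, template, seed, **kwargs)
    )


# ---------------------------------------------------------------------------
# annotation matrix container


@dataclass
class AnnotationMatrix:
    """SNPs x annotations values with per-annotation metadata.

    Binary annotations hold {0,1}; continuous annotations any real value.
    """

    snp_ids: np.ndarray
    _columns: dict[str, np.ndarray] = field(default_factory=dict)
    _meta: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def with_base(cls, variants: pd.DataFrame) -> "AnnotationMatrix":
        """Matrix pre-seeded with the all-SNPs 'base' annotation."""
        am = cls(snp_ids=variants["snp"].to_numpy())
        am.add("base", np.ones(len(variants)))
        return am

    @property
    def names(self) -> list[str]:
        return list(self._columns)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def values(self) -> np.ndarray:
        return np.column_stack([self._columns[n] for n in self.names])

    def __getitem__(self, name: str) -> np.ndarray:
        return self._columns[name]

    def __contains__(self, name: str) -> bool:
        return name in self._columns

    def add(
        self,
        name: str,
        values: np.ndarray,
        source: str = "",
        flank_of: str | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_snps,):
            raise ValueError(f"annotation {name!r}: expected {self.n_snps} values, got {values.shape}")
        if name in self._columns:
            raise ValueError(f"annotation {name!r} already present")
        if flank_of is not None and flank_of not in self._columns:
            raise ValueError(f"flank parent {flank_of!r} not in the matrix")
        self._columns[name] = values
        self._meta[name] = {"source": source, "flank_of": flank_of}

    def meta(self, name: str) -> dict:
        return dict(self._meta[name])

    def pct_snps(self, name: str, mask: np.ndarray | None = None) -> float:
        """Fraction of (masked) SNPs with a nonzero value."""
        v = self._columns[name] != 0
        if mask is not None:
            v = v[mask]
        return float(v.mean())

    def subset(self, names: list[str]) -> "AnnotationMatrix":
        out = AnnotationMatrix(snp_ids=self.snp_ids)
        for n in names:
            meta = self._meta[n]
            flank_of = meta["flank_of"] if meta["flank_of"] in names else None
            out.add(n, self._columns[n], source=meta["source"], flank_of=flank_of)
        return out

    # -- thin-annot TSV dialect -------------------------------------------
    def to_thin_annot(self, path) -> None:
        """One column per annotation, one row per SNP, gzip TSV.

        Written with a zeroed gzip timestamp so identical matrices produce
        byte-identical files.
        """
        df = pd.DataFrame({n: self._columns[n] for n in self.names})
        data = df.to_csv(sep="\t", index=False).encode()
        with open(path, "wb") as fh:
            fh.write(gzip.compress(data, mtime=0))

    @classmethod
    def from_thin_annot(cls, path, snp_ids: np.ndarray) -> "AnnotationMatrix":
        with gzip.open(path, "rt") as fh:
            df = pd.read_csv(fh, sep="\t")
        if len(df) != len(snp_ids):
            raise ValueError(f"{path}: {len(df)} rows but {len(snp_ids)} SNPs expected")
        am = cls(snp_ids=np.asarray(snp_ids))
        for name in df.columns:
            am.add(name, df[name].to_numpy())
        return am
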