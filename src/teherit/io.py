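"""File-format readers and writers.

Variant tables are plain :class:`pandas.DataFrame` objects with columns
``snp, chrom, pos, a1, a2, maf`` (``pos`` 1-based). Genomic intervals are
DataFrames with BED-style 0-based half-open ``chrom, start, end`` columns
plus optional ``name, class_name, family_name, milli_div, strand``.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf"]

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major .bed

# 2-bit PLINK codes -> dosage of allele A1 (01 = missing -> -1)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(prefix: str | Path, genotypes: np.ndarray, variants: pd.DataFrame) -> None:
    """Write diploid dosages (n_individuals x n_snps, values in {0,1,2}) as
    PLINK .bed/.bim/.fam, SNP-major."""
    prefix = Path(prefix)
    geno = np.asarray(genotypes)
    n, m = geno.shape
    if m != len(variants):
        raise ValueError(f"genotypes have {m} SNPs but variant table has {len(variants)}")

    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": variants["chrom"].values,
            "snp": variants["snp"].values,
            "cm": 0.0,
            "pos": variants["pos"].values,
            "a1": variants.get("a1", pd.Series(["A"] * m)).values,
            "a2": variants.get("a2", pd.Series(["G"] * m)).values,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    # pack 4 samples per byte, sample index increasing from the low bits
    codes = np.empty_like(geno, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[geno == dosage] = code
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        padded = np.zeros((m, 4 * n_bytes), dtype=np.uint8)
        padded[:, :n] = codes.T
        shifts = np.tile([0, 2, 4, 6], n_bytes)
        packed = np.zeros((m, n_bytes), dtype=np.uint8)
        for k in range(4):
            packed |= (padded[:, k::4] << shifts[k]).astype(np.uint8)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read PLINK .bed/.bim/.fam; returns (dosages, variant table).

    MAF in the returned table is the empirical frequency of the minor allele.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    codes = np.zeros((m, 4 * n_bytes), dtype=np.uint8)
    for k, shift in enumerate([0, 2, 4, 6]):
        codes[:, k::4] = (body >> shift) & 0b11
    geno = _CODE_TO_DOSAGE[codes[:, :n]].T.astype(np.int8)

    freq = geno.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "snp": bim["snp"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "a1": bim["a1"],
            "a2": bim["a2"],
            "maf": np.minimum(freq, 1 - freq),
        }
    )
    return geno, variants


def write_sumstats(path: str | Path, sumstats: pd.DataFrame) -> None:
    """Write the whitespace-delimited summary-statistics dialect
    (columns SNP A1 A2 N Z)."""
    cols = ["SNP", "A1", "A2", "N", "Z"]
    missing = [c for c in cols if c not in sumstats.columns]
    if missing:
        raise ValueError(f"sumstats table missing columns: {missing}")
    sumstats[cols].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a sumstats file; accepts Z or CHISQ, always returns both."""
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    if "CHISQ" not in df.columns:
        if "Z" not in df.columns:
            raise ValueError(f"{path}: need a Z or CHISQ column")
        df["CHISQ"] = df["Z"] ** 2
    return df


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a 3-6 column BED file into an interval DataFrame."""
    rows = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({len(fields)} fields)")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3] if len(fields) > 3 else ".",
                    "strand": fields[5] if len(fields) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def read_repeatmasker(path: str | Path) -> pd.DataFrame:
    """Parse a RepeatMasker .out file into an interval DataFrame.

    Column 2 (milliDiv, mutations per thousand bases relative to the element
    consensus) is kept as the element age proxy.  Coordinates in .out files
    are 1-based inclusive and are converted to 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or not fields[0].replace(".", "").isdigit():
                continue  # header / blank lines
            chrom, begin, end = fields[4], int(fields[5]), int(fields[6])
            name = fields[9]
            cls_fam = fields[10].split("/")
            rows.append(
                {
                    "chrom": chrom,
                    "start": begin - 1,
                    "end": end,
                    "name": name,
                    "class_name": cls_fam[0],
                    "family_name": cls_fam[1] if len(cls_fam) > 1 else cls_fam[0],
                    "milli_div": float(fields[1]),
                    "strand": "-" if fields[8] == "C" else "+",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "class_name", "family_name", "milli_div", "strand"],
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {sequence name: upper-case sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
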