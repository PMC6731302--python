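"""End-to-end orchestration: synthesize-or-load, annotate, score, partition.

A single YAML config drives a run; every stage writes its outputs under the
run directory together with a JSON manifest (inputs, filters, counts, seed,
version) so real-data runs are auditable.  In synthetic mode, the single
config seed drives named substreams per stage, and re-running an identical
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, ldscore, regression
from .annotations import AnnotationMatrix, flank_annotation, snps_in_intervals
from .simulate import Cohort, SimulationConfig, draw_effects, gwas_sumstats, simulate_genotypes, simulate_phenotype

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    mode: str
    seed: int | None
    out_dir: Path
    simulation: dict = field(default_factory=dict)
    annotations: list = field(default_factory=list)
    architecture: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        mode = raw.get("mode", "synthetic")
        if mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be 'synthetic' or 'real', got {mode!r}")
        seed = raw.get("seed")
        if mode == "synthetic" and seed is None:
            raise ValueError("seed is mandatory in synthetic mode")
        cfg = cls(
            mode=mode,
            seed=seed,
            out_dir=Path(raw.get("out_dir", "run")),
            simulation=raw.get("simulation", {}),
            annotations=raw.get("annotations", [{"type": "base"}]),
            architecture=raw.get("architecture", {}),
            regression=raw.get("regression", {}),
            inputs=raw.get("inputs", {}),
        )
        for recipe in cfg.annotations:
            if "path" in recipe:
                p = base / recipe["path"]
                if not p.exists():
                    raise FileNotFoundError(f"annotation input does not exist: {p}")
                recipe["path"] = str(p)
        for key, p in cfg.inputs.items():
            if not (base / p).exists():
                raise FileNotFoundError(f"input {key!r} does not exist: {base / p}")
        return cfg


def _manifest(path: Path, **payload) -> None:
    payload["version"] = __version__
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def build_annotations(cfg: RunConfig, cohort: Cohort) -> tuple[AnnotationMatrix, list[str]]:
    """Build the annotation matrix from the config's recipe list.

    Recipe types: ``base`` (all SNPs), ``bed`` (interval file; optional
    500 bp flank companion), ``random_snps`` (seeded random SNP subset of a
    given fraction, used in simulation studies).  Recipes with
    ``focal: true`` are reported by the partition stage.
    """
    variants = cohort.variants
    am = AnnotationMatrix(snp_ids=variants["snp"].to_numpy())
    focal: list[str] = []
    for i, recipe in enumerate(cfg.annotations):
        rtype = recipe.get("type")
        name = recipe.get("name", rtype if rtype != "base" else "base")
        if rtype == "base":
            am.add("base", np.ones(len(variants)), source="all SNPs")
        elif rtype == "bed":
            intervals = io.read_bed_intervals(recipe["path"])
            am.add(name, snps_in_intervals(variants, intervals), source=recipe["path"])
            if recipe.get("flank", False):
                width = int(recipe.get("flank_bp", 500))
                am.add(
                    f"{name}.flank{width}",
                    flank_annotation(variants, intervals, width),
                    flank_of=name,
                )
        elif rtype == "random_snps":
            rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed or 0), 1000 + i])
            )
            values = (rng.random(len(variants)) < float(recipe["pct"])).astype(float)
            am.add(name, values, source=f"random {recipe['pct']:.0%} of SNPs")
        else:
            raise ValueError(f"unknown annotation recipe type {rtype!r}")
        if recipe.get("focal", False):
            focal.append(name)
    return am, focal


def run(config: RunConfig | dict | str | Path) -> Path:
    """Execute a full run; returns the run directory.

    Stage failures halt with the stage name; partial outputs are preserved.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.mode == "synthetic":
            arch = config.architecture
            sim = SimulationConfig(
                seed=int(config.seed),
                h2_g=float(arch.get("h2_g", 0.5)),
                n_causal=arch.get("n_causal"),
                **config.simulation,
            )
            cohort = simulate_genotypes(sim)
        else:
            geno, variants = io.read_plink(config.inputs["plink_prefix"])
            cohort = Cohort(genotypes=geno, variants=variants)
            sim = None

        stage = "annotate"
        am, focal = build_annotations(config, cohort)
        am.to_thin_annot(out / "annotations.annot.gz")

        stage = "sumstats"
        if config.mode == "synthetic":
            tau = arch.get("tau")
            if tau is not None:
                sim.tau_vector = np.asarray(tau, dtype=float)
            beta = draw_effects(am.values if tau is not None else None, sim)
            simulate_phenotype(cohort, beta, sim.h2_g, rng=sim.rng("noise"))
            sumstats = gwas_sumstats(cohort)
            io.write_plink(out / "cohort", cohort.genotypes, cohort.variants)
            io.write_sumstats(out / "cohort.sumstats", sumstats)
        else:
            sumstats = io.read_sumstats(config.inputs["sumstats"])

        stage = "ldscore"
        reg_opts = config.regression
        ld = ldscore.ld_scores(
            cohort.genotypes,
            cohort.variants,
            am,
            window_bp=int(reg_opts.get("window_bp", ldscore.DEFAULT_WINDOW_BP)),
        )
        ldscore.write_ldscores(out / "scores", ld)

        stage = "filter"
        sumstats_f, herit_mask, counts = ldscore.filter_snps(cohort.variants, sumstats)

        stage = "partition"
        if not focal:
            focal = [n for n in am.names if n != "base"] or ["base"]
        results = regression.partition(
            sumstats_f,
            ld,
            am,
            herit_mask,
            focal=focal,
            n_blocks=int(reg_opts.get("n_blocks", regression.DEFAULT_N_BLOCKS)),
            intercept=reg_opts.get("intercept", "free"),
            weighted=bool(reg_opts.get("weighted", True)),
            force=bool(reg_opts.get("force", False)),
        )
        results.to_csv(out / "partition.results.tsv", sep="\t", index=False, float_format="%.10g")
        _manifest(
            out / "partition.manifest.json",
            mode=config.mode,
            seed=config.seed,
            filters=counts,
            focal=focal,
            annotations=am.names,
            n_snps=cohort.n_snps,
            n_individuals=cohort.n_individuals,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# test fixtures


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write the toy datasets used by the test suite, with checksums.

    * ``ld5``: 5-SNP / 50-individual PLINK panel for brute-force LD checks
    * ``overlap10.annot.gz``: 10-SNP annotation pair with |A|=4, |B|=5,
      |A∩B|=3 (excess overlap exactly 1.5)
    * ``kmer10k.fa``: random 10 kb FASTA for motif-scan oracles
    * ``noiseless``: LD scores + summary statistics satisfying
      chi2 = N * sum_c l(j,c) tau_c + 1 exactly, with the generating taus
      in a JSON sidecar
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    cfg = SimulationConfig(n_individuals=50, n_snps=5, n_blocks_ld=1, ld_decay=0.6, seed=seed)
    cohort = simulate_genotypes(cfg)
    io.write_plink(out / "ld5", cohort.genotypes, cohort.variants)

    a = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
    b = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0], dtype=float)
    am = AnnotationMatrix(snp_ids=np.array([f"rs{i}" for i in range(10)]))
    am.add("A", a)
    am.add("B", b)
    am.to_thin_annot(out / "overlap10.annot.gz")

    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    with open(out / "kmer10k.fa", "w") as fh:
        fh.write(">chrT\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    noiseless = make_noiseless_fixture(seed)
    ldscore.write_ldscores(out / "noiseless", noiseless["ld"])
    io.write_sumstats(out / "noiseless.sumstats", noiseless["sumstats"])
    with open(out / "noiseless.json", "w") as fh:
        json.dump(
            {"tau": list(noiseless["tau"]), "N": noiseless["N"]}, fh, indent=2
        )
        fh.write("\n")

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "fixtures.manifest.json")
    manifest = {p.name: _sha256(p) for p in files}
    _manifest(out / "fixtures.manifest.json", seed=seed, checksums=manifest)
    return manifest


def make_noiseless_fixture(
    seed: int = 0,
    m: int = 400,
    n_gwas: int = 10_000,
    tau: tuple[float, float] = (1e-4, 4e-4),
) -> dict:
    """An exact-algebra fixture: chi2_j = N * sum_c l(j,c) tau_c + 1.

    Two annotations: all-ones 'base' and a 25%-of-SNPs focal 'A'.  LD scores
    are synthetic positive values; any correct fit recovers tau exactly.
    """
    rng = np.random.default_rng(seed)
    variants_pos = 1 + 1000 * np.arange(m)
    values_a = (rng.random(m) < 0.25).astype(float)
    A = np.column_stack([np.ones(m), values_a])
    l_base = 1.0 + rng.gamma(2.0, 2.0, size=m)
    l_a = values_a + rng.gamma(1.0, 1.0, size=m) * 0.3
    L = np.column_stack([l_base, l_a])
    tau = np.asarray(tau, dtype=float)
    chisq = n_gwas * (L @ tau) + 1.0

    snp_ids = np.array([f"rs{j}" for j in range(m)])
    ld = ldscore.LDScoreTable(
        snp_ids=snp_ids,
        chrom=np.array(["1"] * m),
        pos=variants_pos,
        names=["base", "A"],
        scores=L,
        w_ld=l_base,
        n_ref=503,
        window_bp=ldscore.DEFAULT_WINDOW_BP,
        M=A.sum(axis=0),
        M_common=A.sum(axis=0),
    )
    sumstats = pd.DataFrame(
        {
            "SNP": snp_ids,
            "A1": "A",
            "A2": "G",
            "N": n_gwas,
            "Z": np.sqrt(chisq),
            "CHISQ": chisq,
        }
    )
    am = AnnotationMatrix(snp_ids=snp_ids)
    am.add("base", np.ones(m))
    am.add("A", values_a)
    return {
        "ld": ld,
        "sumstats": sumstats,
        "annot": am,
        "tau": tau,
        "N": n_gwas,
        "herit_mask": np.ones(m, dtype=bool),
    }
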