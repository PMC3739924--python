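"""Single-command orchestration of the five pipeline stages.

One YAML configuration file drives a run: (1) fixed-SNP inference (or
loading of two provided parental genomes), (2) grid simulation of reads
from both parental genomes, (3) residual-bias estimation, (4) allele
counting of the F1 replicates, (5) imbalance statistics.  Every output is a
plain-text standard format under one run directory with a JSON manifest;
identical config + seed reproduce identical outputs.  Stages whose outputs
already exist can be resumed from disk instead of recomputed.

Mapping is pluggable: each library can be given either as FASTQ (mapped
with the built-in aligner) or as a pre-aligned SAM from any external
mapper aligned against the combined diploid reference.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ase_quantification import (
    AlleleCountTable,
    bias_frame,
    count_features,
    estimate_bias,
    merge_tables,
)
from .diploid_builder import (
    ParentalGenomePair,
    load_provided_genomes,
    project_features,
    write_parental_fastas,
)
from .imbalance_stats import run_tests
from .io_formats import (
    read_fasta,
    read_fastq_pair,
    read_gtf,
    read_sam,
    read_table,
    read_vcf,
    write_table,
    write_vcf,
)
from .read_simulator import SimulationConfig, simulate_grid
from .snp_inference import SnpCallingParams, refine_iteratively
from .toy_aligner import AlignerParams, DiploidAligner, make_single_genome_mapper

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Aggregated configuration problems, one per line."""


_TOP_KEYS = {
    "mode",
    "reference",
    "annotation",
    "parent1",
    "parent2",
    "parent1_genome",
    "parent2_genome",
    "f1_libraries",
    "output_dir",
    "seed",
    "params",
}
_PARAM_KEYS = {
    "min_depth",
    "min_purity",
    "max_iters",
    "read_length",
    "insert_size",
    "grid_step",
    "seed_length",
    "max_mismatch",
    "insert_slack",
    "weak_bias_threshold",
    "min_total",
    "test_mode",
}


@dataclass
class LibrarySpec:
    """One sequencing library: either a FASTQ mate pair or a SAM file."""

    library_id: str
    fastq1: Path | None = None
    fastq2: Path | None = None
    sam: Path | None = None

    @property
    def is_sam(self) -> bool:
        return self.sam is not None


@dataclass
class PipelineConfig:
    mode: str  # from_parental_reads | from_parental_genomes
    annotation: Path
    output_dir: Path
    seed: int = 1
    reference: Path | None = None
    parent1: LibrarySpec | None = None
    parent2: LibrarySpec | None = None
    parent1_genome: Path | None = None
    parent2_genome: Path | None = None
    f1_libraries: list[LibrarySpec] = field(default_factory=list)
    snp_params: SnpCallingParams = field(default_factory=SnpCallingParams)
    max_iters: int = 2
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    aligner_params: AlignerParams = field(default_factory=AlignerParams)
    weak_bias_threshold: float = 5.0
    min_total: int = 10
    test_mode: str = "auto"  # auto | pooled | replicated

    def effective_test_mode(self) -> str:
        if self.test_mode != "auto":
            return self.test_mode
        return "replicated" if len(self.f1_libraries) >= 2 else "pooled"

    def effective_params(self) -> dict:
        """Every effective parameter value, for the run log."""
        return {
            "mode": self.mode,
            "seed": self.seed,
            "min_depth": self.snp_params.min_depth,
            "min_purity": self.snp_params.min_purity,
            "max_iters": self.max_iters,
            "read_length": self.sim_config.read_length,
            "insert_size": self.sim_config.insert_size,
            "grid_step": self.sim_config.grid_step,
            "seed_length": self.aligner_params.k,
            "max_mismatch": self.aligner_params.max_mismatch,
            "insert_slack": self.aligner_params.insert_slack,
            "weak_bias_threshold": self.weak_bias_threshold,
            "min_total": self.min_total,
            "test_mode": self.effective_test_mode(),
        }


def _suggest(key: str, valid: set[str]) -> str:
    close = difflib.get_close_matches(key, valid, n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def _parse_library(entry: dict, idx: int, errors: list[str], label: str) -> LibrarySpec:
    lib_id = str(entry.get("id", f"{label}{idx}"))
    spec = LibrarySpec(lib_id)
    if "sam" in entry:
        spec.sam = Path(entry["sam"])
    if "fastq1" in entry or "fastq2" in entry:
        if spec.sam is not None:
            errors.append(f"{label} {lib_id}: give either fastq1/fastq2 or sam, not both")
        if "fastq1" not in entry or "fastq2" not in entry:
            errors.append(f"{label} {lib_id}: both fastq1 and fastq2 are required")
        else:
            spec.fastq1 = Path(entry["fastq1"])
            spec.fastq2 = Path(entry["fastq2"])
    if spec.sam is None and spec.fastq1 is None:
        errors.append(f"{label} {lib_id}: no input given (fastq1/fastq2 or sam)")
    return spec


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML configuration file.

    All problems are aggregated into one :class:`ConfigError` report;
    unknown keys come with a nearest-match suggestion.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key {key!r}{_suggest(key, _TOP_KEYS)}")
    params = raw.get("params") or {}
    for key in params:
        if key not in _PARAM_KEYS:
            errors.append(f"unknown params key {key!r}{_suggest(key, _PARAM_KEYS)}")

    mode = raw.get("mode")
    if mode not in ("from_parental_reads", "from_parental_genomes"):
        errors.append(
            "mode must be 'from_parental_reads' or 'from_parental_genomes', "
            f"got {mode!r}"
        )
    has_parent_reads = "parent1" in raw or "parent2" in raw
    has_parent_genomes = "parent1_genome" in raw or "parent2_genome" in raw
    if has_parent_reads and has_parent_genomes:
        errors.append(
            "conflicting modes: both parental read libraries and parental "
            "genomes are configured; set exactly one"
        )

    if "annotation" not in raw:
        errors.append("missing required key 'annotation'")
    if "output_dir" not in raw:
        errors.append("missing required key 'output_dir'")
    if "f1_libraries" not in raw or not raw.get("f1_libraries"):
        errors.append("missing required key 'f1_libraries'")

    parent1 = parent2 = None
    p1_genome = p2_genome = None
    reference = None
    if mode == "from_parental_reads":
        if "reference" not in raw:
            errors.append("from_parental_reads mode requires 'reference'")
        else:
            reference = Path(raw["reference"])
        for name in ("parent1", "parent2"):
            if name not in raw:
                errors.append(f"from_parental_reads mode requires {name!r}")
        if "parent1" in raw:
            parent1 = _parse_library(raw["parent1"], 1, errors, "parent")
        if "parent2" in raw:
            parent2 = _parse_library(raw["parent2"], 2, errors, "parent")
    elif mode == "from_parental_genomes":
        for name in ("parent1_genome", "parent2_genome"):
            if name not in raw:
                errors.append(f"from_parental_genomes mode requires {name!r}")
        if "parent1_genome" in raw:
            p1_genome = Path(raw["parent1_genome"])
        if "parent2_genome" in raw:
            p2_genome = Path(raw["parent2_genome"])
        if "reference" in raw:
            reference = Path(raw["reference"])

    f1_libraries = [
        _parse_library(entry, i + 1, errors, "f1")
        for i, entry in enumerate(raw.get("f1_libraries") or [])
    ]
    lib_ids = [lib.library_id for lib in f1_libraries]
    if len(set(lib_ids)) != len(lib_ids):
        errors.append(f"duplicate f1 library ids: {lib_ids}")

    # referenced paths must exist at validation time
    def _check(p: Path | None, what: str) -> None:
        if p is not None and not Path(p).exists():
            errors.append(f"{what}: file not found: {p}")

    _check(reference, "reference")
    if "annotation" in raw:
        _check(Path(raw["annotation"]), "annotation")
    _check(p1_genome, "parent1_genome")
    _check(p2_genome, "parent2_genome")
    for lib in filter(None, [parent1, parent2, *f1_libraries]):
        _check(lib.fastq1, f"library {lib.library_id}")
        _check(lib.fastq2, f"library {lib.library_id}")
        _check(lib.sam, f"library {lib.library_id}")

    test_mode = params.get("test_mode", "auto")
    if test_mode not in ("auto", "pooled", "replicated"):
        errors.append(f"test_mode must be auto/pooled/replicated, got {test_mode!r}")

    if errors:
        raise ConfigError(
            f"{path}: {len(errors)} configuration problem(s):\n  - "
            + "\n  - ".join(errors)
        )

    return PipelineConfig(
        mode=mode,
        annotation=Path(raw["annotation"]),
        output_dir=Path(raw["output_dir"]),
        seed=int(raw.get("seed", 1)),
        reference=reference,
        parent1=parent1,
        parent2=parent2,
        parent1_genome=p1_genome,
        parent2_genome=p2_genome,
        f1_libraries=f1_libraries,
        snp_params=SnpCallingParams(
            min_depth=int(params.get("min_depth", 10)),
            min_purity=float(params.get("min_purity", 0.9)),
        ),
        max_iters=int(params.get("max_iters", 2)),
        sim_config=SimulationConfig(
            read_length=int(params.get("read_length", 100)),
            insert_size=int(params.get("insert_size", 78)),
            grid_step=int(params.get("grid_step", 1)),
        ),
        aligner_params=AlignerParams(
            k=int(params.get("seed_length", 20)),
            max_mismatch=int(params.get("max_mismatch", 5)),
            insert_size=int(params.get("insert_size", 78)),
            insert_slack=int(params.get("insert_slack", 20)),
        ),
        weak_bias_threshold=float(params.get("weak_bias_threshold", 5.0)),
        min_total=int(params.get("min_total", 10)),
        test_mode=test_mode,
    )


# ---------------------------------------------------------------------------
# Stage execution


def _load_library_pairs(lib: LibrarySpec):
    return read_fastq_pair(lib.fastq1, lib.fastq2)


def _library_alignments(lib: LibrarySpec, aligner: DiploidAligner):
    if lib.is_sam:
        return list(read_sam(lib.sam))
    return aligner.map_pairs(_load_library_pairs(lib))


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute all five stages; returns the output manifest.

    With ``resume=True``, stages whose output files already exist under the
    run directory are loaded from disk instead of recomputed, so deleting
    only a late stage's outputs reruns only that stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("asepipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    paths = {
        "snps": out / "fixed_snps.vcf",
        "genome_p1": out / "genome_p1.fa",
        "genome_p2": out / "genome_p2.fa",
        "sim_counts": out / "sim_counts.tsv",
        "bias": out / "bias.tsv",
        "counts": out / "counts.tsv",
        "results": out / "results.tsv",
        "uninformative": out / "uninformative_features.tsv",
        "manifest": out / "manifest.json",
    }
    logger.info("run started (version %s)", __version__)
    for key, value in cfg.effective_params().items():
        logger.info("parameter %s = %r", key, value)

    try:
        # --- stage 1: fixed SNPs and parental genomes
        stage1_done = resume and all(
            paths[k].exists() for k in ("snps", "genome_p1", "genome_p2")
        )
        if cfg.mode == "from_parental_genomes":
            logger.info("stage 1: loading provided parental genomes")
            pair = load_provided_genomes(cfg.parent1_genome, cfg.parent2_genome)
            snps = list(pair.snps)
        elif stage1_done:
            logger.info("stage 1: resuming from existing outputs")
            reference = read_fasta(cfg.reference)
            snps = read_vcf(paths["snps"])
            from .diploid_builder import build_parental_genomes

            pair = build_parental_genomes(reference, snps)
        else:
            logger.info("stage 1: inferring fixed SNPs from parental reads")
            reference = read_fasta(cfg.reference)
            mapper = make_single_genome_mapper(cfg.aligner_params)
            if cfg.parent1.is_sam or cfg.parent2.is_sam:
                # pre-aligned parents: no remapping possible, single round
                from .snp_inference import call_fixed_snps, pileup

                aln1 = (
                    list(read_sam(cfg.parent1.sam))
                    if cfg.parent1.is_sam
                    else mapper(_load_library_pairs(cfg.parent1), reference)
                )
                aln2 = (
                    list(read_sam(cfg.parent2.sam))
                    if cfg.parent2.is_sam
                    else mapper(_load_library_pairs(cfg.parent2), reference)
                )
                snps = call_fixed_snps(
                    pileup(aln1, reference), pileup(aln2, reference), cfg.snp_params
                )
                from .diploid_builder import build_parental_genomes

                pair = build_parental_genomes(reference, snps)
            else:
                reads_p1 = _load_library_pairs(cfg.parent1)
                reads_p2 = _load_library_pairs(cfg.parent2)
                snps, pair, converged = refine_iteratively(
                    reads_p1,
                    reads_p2,
                    reference,
                    mapper,
                    cfg.snp_params,
                    cfg.max_iters,
                )
                logger.info(
                    "stage 1: %d fixed SNPs (converged=%s)", len(snps), converged
                )
        if not stage1_done or cfg.mode == "from_parental_genomes":
            write_vcf(snps, pair.contig_lengths(), paths["snps"])
            write_parental_fastas(pair, paths["genome_p1"], paths["genome_p2"])

        # --- annotation, projection, shared aligner
        features = project_features(read_gtf(cfg.annotation), pair)
        uninformative = [f for f in features if not f.is_informative]
        write_table(
            pd.DataFrame(
                {
                    "feature_id": [f.feature_id for f in uninformative],
                    "level": [f.kind for f in uninformative],
                }
            ),
            paths["uninformative"],
        )
        logger.info(
            "annotation: %d features, %d uninformative (no fixed SNP)",
            len(features),
            len(uninformative),
        )
        aligner = DiploidAligner(pair, cfg.aligner_params)
        levels = {f.feature_id: f.kind for f in features}

        # --- stages 2+3: grid simulation, mapping, bias estimation
        if resume and paths["sim_counts"].exists():
            logger.info("stages 2-3: resuming from existing simulation counts")
            sim_table = AlleleCountTable(read_table(paths["sim_counts"]), levels)
        else:
            logger.info("stage 2: simulating read grid over polymorphic sites")
            grid = simulate_grid(pair, features, cfg.sim_config)
            logger.info("stage 2: %d simulated pairs", len(grid))
            logger.info("stage 3: mapping and counting simulated reads")
            sim_aln = aligner.map_pairs([g.pair for g in grid])
            sim_table = count_features(sim_aln, features, "sim")
            write_table(sim_table.data, paths["sim_counts"])
        bias = estimate_bias(sim_table, cfg.weak_bias_threshold)
        write_table(bias_frame(bias), paths["bias"])

        # --- stage 4: F1 allele counting
        if resume and paths["counts"].exists():
            logger.info("stage 4: resuming from existing counts")
            counts = AlleleCountTable(read_table(paths["counts"]), levels)
        else:
            tables = []
            for lib in cfg.f1_libraries:
                logger.info("stage 4: counting library %s", lib.library_id)
                aln = _library_alignments(lib, aligner)
                tables.append(count_features(aln, features, lib.library_id))
            counts = merge_tables(tables)
            write_table(counts.data, paths["counts"])

        # --- stage 5: statistics
        logger.info("stage 5: imbalance tests (%s mode)", cfg.effective_test_mode())
        results = run_tests(
            counts, bias, cfg.effective_test_mode(), cfg.min_total
        )
        write_table(results, paths["results"])

        manifest = {
            "version": __version__,
            "parameters": cfg.effective_params(),
            "outputs": {k: str(v) for k, v in paths.items() if k != "manifest"},
            "n_fixed_snps": len(snps),
            "n_features": len(features),
            "n_uninformative": len(uninformative),
            "f1_libraries": [lib.library_id for lib in cfg.f1_libraries],
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
        logger.info("run finished")
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
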