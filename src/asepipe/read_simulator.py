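"""Read simulation: the bias-estimation grid and synthetic test fixtures.

The grid simulator is part of the method, not a test helper.  For every
fixed SNP inside every feature it emits error-free paired-end fragments from
*both* parental genomes at identical template positions, so in the absence
of mapping bias each feature recovers an expression ratio of exactly one.
Mapping these simulated reads with the same mapper used for the real data
and counting them like real data measures the residual per-feature mapping
bias, which the statistical tests then use as their null expectation.

The fixture generator is the package's synthetic data source: a random
transcriptome with planted fixed SNPs, deterministic parental sequencing,
and F1 RNA-seq replicates with configurable allelic imbalance, sequencing
error and allele-1 read dropout (a mapping-bias-like distortion).  The
count-level simulator draws the same quantities directly as binomial counts
for calibration studies where read-level detail is not needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diploid_builder import (
    ParentalGenomePair,
    build_parental_genomes,
    project_features,
)
from .io_formats import (
    Feature,
    ReadPair,
    ReferenceSequence,
    write_fasta,
    write_fastq_pair,
    write_gtf,
    write_table,
)
from .snp_inference import FixedSnp
from .toy_aligner import reverse_complement

__all__ = [
    "SimulationConfig",
    "SimulatedReadPair",
    "simulate_grid",
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "write_fixture",
    "simulate_count_tables",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Grid-simulation geometry.

    ``read_length`` and ``insert_size`` default to the 2 x 100 bp, 78 bp
    insert layout of a typical paired-end RNA-seq library; the fragment
    length is ``2 * read_length + insert_size``.  ``grid_step`` is the
    spacing of fragment start offsets (1 = every offset).  Grid reads are
    error-free by construction so the bias estimate reflects mapping
    artifacts only.
    """

    read_length: int = 100
    insert_size: int = 78
    grid_step: int = 1
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1")
        if self.insert_size < 0:
            raise ValueError("insert_size must be >= 0")

    @property
    def fragment_length(self) -> int:
        return 2 * self.read_length + self.insert_size


@dataclass(frozen=True)
class SimulatedReadPair:
    """A grid read pair that knows where it came from."""

    pair: ReadPair
    truth_genome: str  # "p1" | "p2"
    truth_chrom: str
    truth_pos: int  # fragment start, spliced-transcript coordinate
    truth_feature_id: str


def _grid_starts(snp_offsets: list[int], tpl_len: int, cfg: SimulationConfig) -> list[int]:
    """Fragment starts on the grid whose fragment overlaps >= 1 SNP.

    The grid is anchored at absolute multiples of ``grid_step``; a start s
    is kept when the fragment [s, s + F) contains a SNP offset and lies
    within the template.
    """
    frag = cfg.fragment_length
    hi_bound = tpl_len - frag
    starts: set[int] = set()
    for t in snp_offsets:
        lo = max(0, t - frag + 1)
        hi = min(t, hi_bound)
        if hi < lo:
            continue
        first = ((lo + cfg.grid_step - 1) // cfg.grid_step) * cfg.grid_step
        starts.update(range(first, hi + 1, cfg.grid_step))
    return sorted(starts)


def simulate_grid(
    pair: ParentalGenomePair,
    features: list[Feature],
    cfg: SimulationConfig = SimulationConfig(),
) -> list[SimulatedReadPair]:
    """Generate the deterministic bias-estimation grid.

    Templates are spliced transcript sequences (exons concatenated), since
    that is what RNA-seq fragments are drawn from.  For every valid start,
    exactly two pairs are emitted — one per parental genome — so per-feature
    pair counts from the two genomes are equal by construction.  Features
    with no SNPs yield nothing; features whose transcript is shorter than
    the fragment are skipped.
    """
    lookup_p1 = pair.lookup_p1()
    lookup_p2 = pair.lookup_p2()
    out: list[SimulatedReadPair] = []
    L = cfg.read_length
    frag = cfg.fragment_length
    for feat in features:
        if not feat.is_informative:
            continue
        if feat.length < frag:
            continue
        tpl = {
            "p1": feat.spliced_sequence(lookup_p1),
            "p2": feat.spliced_sequence(lookup_p2),
        }
        offsets = [feat.genomic_to_spliced(snp.pos) for snp in feat.snps]
        for start in _grid_starts(offsets, feat.length, cfg):
            for genome in ("p1", "p2"):
                t = tpl[genome]
                r1 = t[start : start + L]
                r2 = reverse_complement(t[start + frag - L : start + frag])
                name = f"grid|{feat.feature_id}|{genome}|{start}"
                out.append(
                    SimulatedReadPair(
                        ReadPair(name, r1, r2),
                        truth_genome=genome,
                        truth_chrom=feat.chrom,
                        truth_pos=start,
                        truth_feature_id=feat.feature_id,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Stochastic fixture generation


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a synthetic ASE experiment.

    Defaults describe a small but realistic desk-scale design: 20 genes of
    ~1 kb expressed sequence carrying 5 fixed SNPs each, parental sequencing
    at 20x even coverage, and F1 libraries of 200 read pairs per gene per
    replicate.  ``imbalance_ratio`` r is the true parent1:parent2 expression
    ratio (allele-1 fraction r/(1+r)); ``dropout_p1`` silently removes that
    fraction of allele-1 F1 reads to mimic allele-specific mapping loss.
    """

    seed: int
    n_genes: int = 20
    n_snps_per_gene: int = 5
    depth: int = 200
    imbalance_ratio: float = 1.0
    error_rate: float = 0.0
    dropout_p1: float = 0.0
    n_replicates: int = 1
    read_length: int = 50
    insert_size: int = 20
    exons_per_gene: int = 1
    exon_length: int = 500
    intron_length: int = 100
    intergenic_length: int = 200
    parental_depth: int = 20
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_snps_per_gene > self.exons_per_gene * self.exon_length:
            raise ValueError("more SNPs requested than exonic positions available")
        if self.exons_per_gene * self.exon_length < 2 * self.read_length + self.insert_size:
            raise ValueError("transcript shorter than one fragment")

    @property
    def fragment_length(self) -> int:
        return 2 * self.read_length + self.insert_size


@dataclass
class Fixture:
    """Everything a pipeline run needs, plus the ground truth behind it."""

    spec: FixtureSpec
    reference: list[ReferenceSequence]
    genes: list[Feature]  # gene features with truth SNPs attached
    exons: list[Feature]
    snps: list[FixedSnp]
    pair: ParentalGenomePair
    parental_reads_p1: list[ReadPair]
    parental_reads_p2: list[ReadPair]
    f1_reads: dict[str, list[ReadPair]]  # replicate id -> pairs
    truth_pairs: pd.DataFrame  # one row per generated F1 pair
    truth_genes: pd.DataFrame  # one row per gene x replicate

    @property
    def features(self) -> list[Feature]:
        return self.genes + self.exons


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _tile_reads(
    template: str,
    name_prefix: str,
    read_length: int,
    insert_size: int,
    depth: int,
    rng: np.random.Generator,
    error_rate: float,
) -> list[ReadPair]:
    """Evenly tiled paired-end fragments giving ~``depth`` coverage."""
    frag = 2 * read_length + insert_size
    if len(template) < frag:
        return []
    step = max(1, round(2 * read_length / depth))
    pairs: list[ReadPair] = []
    for i, start in enumerate(range(0, len(template) - frag + 1, step)):
        r1 = template[start : start + read_length]
        r2 = reverse_complement(template[start + frag - read_length : start + frag])
        pairs.append(
            ReadPair(
                f"{name_prefix}|{i}",
                _mutate(r1, rng, error_rate),
                _mutate(r2, rng, error_rate),
            )
        )
    return pairs


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build a complete synthetic ASE experiment from a seed.

    The reference is a single chromosome of random sequence carrying
    ``n_genes`` gene models separated by intergenic spacers.  Fixed SNPs are
    planted at distinct exonic positions; parent 1 carries the reference
    allele, parent 2 a different allele.  Parental libraries are evenly
    tiled genomic fragments (DNA-seq style) so every SNP site is covered at
    ~``parental_depth``; F1 libraries draw ``depth`` fragments per gene and
    replicate from the spliced parental transcripts with the configured
    allele-1 fraction, then lose each allele-1 pair with probability
    ``dropout_p1``.  Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)

    # --- reference and gene models
    chunks: list[str] = []
    genes: list[Feature] = []
    exons: list[Feature] = []
    cursor = 0
    for g in range(spec.n_genes):
        cursor += spec.intergenic_length
        chunks.append(_random_bases(rng, spec.intergenic_length))
        intervals = []
        for e in range(spec.exons_per_gene):
            intervals.append((cursor, cursor + spec.exon_length))
            chunks.append(_random_bases(rng, spec.exon_length))
            cursor += spec.exon_length
            if e < spec.exons_per_gene - 1:
                chunks.append(_random_bases(rng, spec.intron_length))
                cursor += spec.intron_length
        gene_id = f"g{g + 1:03d}"
        genes.append(
            Feature(gene_id, gene_id, "gene", spec.chrom_name, tuple(intervals), "+")
        )
        for i, iv in enumerate(intervals, start=1):
            exons.append(
                Feature(f"{gene_id}.exon{i}", gene_id, "exon", spec.chrom_name, (iv,), "+")
            )
    chunks.append(_random_bases(rng, spec.intergenic_length))
    reference = [ReferenceSequence(spec.chrom_name, "".join(chunks))]
    ref_bases = reference[0].bases

    # --- plant fixed SNPs in exons
    snps: list[FixedSnp] = []
    for gene in genes:
        exonic = np.concatenate(
            [np.arange(s, e) for s, e in gene.intervals]
        )
        positions = np.sort(rng.choice(exonic, size=spec.n_snps_per_gene, replace=False))
        for pos in positions:
            ref_base = ref_bases[pos]
            alt = rng.choice(_BASES[_BASES != ord(ref_base)])
            snps.append(
                FixedSnp(
                    spec.chrom_name,
                    int(pos),
                    ref_base,
                    chr(alt),
                    depth_p1=spec.parental_depth,
                    depth_p2=spec.parental_depth,
                )
            )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    pair = build_parental_genomes(reference, snps)
    genes = project_features(genes, pair)
    exons = project_features(exons, pair)

    # --- parental genomic libraries (even tiling, near-uniform coverage)
    parental_reads_p1 = _tile_reads(
        pair.genome_p1[0].bases,
        "p1",
        spec.read_length,
        spec.insert_size,
        spec.parental_depth,
        rng,
        spec.error_rate,
    )
    parental_reads_p2 = _tile_reads(
        pair.genome_p2[0].bases,
        "p2",
        spec.read_length,
        spec.insert_size,
        spec.parental_depth,
        rng,
        spec.error_rate,
    )

    # --- F1 RNA-seq replicates
    lookup = {"p1": pair.lookup_p1(), "p2": pair.lookup_p2()}
    p1_fraction = spec.imbalance_ratio / (1.0 + spec.imbalance_ratio)
    frag = spec.fragment_length
    L = spec.read_length
    f1_reads: dict[str, list[ReadPair]] = {}
    pair_rows: list[dict] = []
    gene_rows: list[dict] = []
    for rep in range(1, spec.n_replicates + 1):
        rep_id = f"rep{rep}"
        reads: list[ReadPair] = []
        for gene in genes:
            n1 = int(rng.binomial(spec.depth, p1_fraction))
            n2 = spec.depth - n1
            kept1 = 0
            snp_offsets = {gene.genomic_to_spliced(s.pos) for s in gene.snps}
            for allele, n_pairs in (("p1", n1), ("p2", n2)):
                tpl = gene.spliced_sequence(lookup[allele])
                starts = rng.integers(0, len(tpl) - frag + 1, size=n_pairs)
                flips = rng.random(n_pairs) < 0.5
                dropped = (
                    rng.random(n_pairs) < spec.dropout_p1
                    if allele == "p1"
                    else np.zeros(n_pairs, dtype=bool)
                )
                for i, start in enumerate(starts):
                    start = int(start)
                    left = tpl[start : start + L]
                    right = reverse_complement(tpl[start + frag - L : start + frag])
                    r1, r2 = (left, right) if not flips[i] else (
                        reverse_complement(right),
                        reverse_complement(left),
                    )
                    name = f"f1|{gene.feature_id}|{allele}|{rep_id}|{i}"
                    covers = any(
                        start <= t < start + L or start + frag - L <= t < start + frag
                        for t in snp_offsets
                    )
                    pair_rows.append(
                        {
                            "name": name,
                            "gene_id": gene.feature_id,
                            "replicate": rep_id,
                            "allele": allele,
                            "start": start,
                            "covers_snp": covers,
                            "dropped": bool(dropped[i]),
                        }
                    )
                    if dropped[i]:
                        continue
                    if allele == "p1":
                        kept1 += 1
                    reads.append(
                        ReadPair(
                            name,
                            _mutate(r1, rng, spec.error_rate),
                            _mutate(r2, rng, spec.error_rate),
                        )
                    )
            gene_rows.append(
                {
                    "gene_id": gene.feature_id,
                    "replicate": rep_id,
                    "n_p1_generated": n1,
                    "n_p1_kept": kept1,
                    "n_p2": n2,
                    "imbalance_ratio": spec.imbalance_ratio,
                    "dropout_p1": spec.dropout_p1,
                }
            )
        f1_reads[rep_id] = reads

    return Fixture(
        spec=spec,
        reference=reference,
        genes=genes,
        exons=exons,
        snps=snps,
        pair=pair,
        parental_reads_p1=parental_reads_p1,
        parental_reads_p2=parental_reads_p2,
        f1_reads=f1_reads,
        truth_pairs=pd.DataFrame(pair_rows),
        truth_genes=pd.DataFrame(gene_rows),
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write a fixture to disk in standard formats; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["reference"] = outdir / "reference.fa"
    write_fasta(fixture.reference, paths["reference"])
    paths["annotation"] = outdir / "annotation.gtf"
    write_gtf(fixture.genes, paths["annotation"])
    for label, reads in (
        ("parent1", fixture.parental_reads_p1),
        ("parent2", fixture.parental_reads_p2),
    ):
        p1 = outdir / f"{label}_1.fastq"
        p2 = outdir / f"{label}_2.fastq"
        write_fastq_pair(reads, p1, p2)
        paths[f"{label}_reads"] = p1
        paths[f"{label}_reads_2"] = p2
    for rep_id, reads in fixture.f1_reads.items():
        p1 = outdir / f"f1_{rep_id}_1.fastq"
        p2 = outdir / f"f1_{rep_id}_2.fastq"
        write_fastq_pair(reads, p1, p2)
        paths[f"f1_{rep_id}"] = p1
        paths[f"f1_{rep_id}_2"] = p2
    paths["truth_pairs"] = outdir / "truth_pairs.tsv"
    write_table(fixture.truth_pairs, paths["truth_pairs"])
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    write_table(fixture.truth_genes, paths["truth_genes"])
    return paths


# ---------------------------------------------------------------------------
# Count-level simulation for statistical calibration


def simulate_count_tables(
    n_genes: int,
    depth: int,
    imbalance_ratio: float | np.ndarray,
    dropout_p1: float,
    n_replicates: int,
    grid_pairs_per_gene: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw F1 allele-count and grid-count tables directly as binomials.

    This reproduces, at the count level, what the read-level pipeline
    measures: per gene and replicate, allele-1 pairs are Binomial(depth,
    r/(1+r)) and then thinned by the allele-1 dropout; the simulation grid
    emits ``grid_pairs_per_gene`` pairs per genome, with the parent-1 side
    thinned by the same dropout (the grid runs through the same lossy
    mapper).  Returns ``(f1_counts, sim_counts)`` with columns
    (feature_id, replicate, count_p1, count_p2, count_ambiguous).
    """
    ratios = np.broadcast_to(np.asarray(imbalance_ratio, dtype=float), (n_genes,))
    p1_frac = ratios / (1.0 + ratios)
    rows = []
    for rep in range(1, n_replicates + 1):
        n1 = rng.binomial(depth, p1_frac)
        kept1 = rng.binomial(n1, 1.0 - dropout_p1)
        n2 = depth - n1
        for g in range(n_genes):
            rows.append(
                {
                    "feature_id": f"g{g + 1:04d}",
                    "replicate": f"rep{rep}",
                    "count_p1": int(kept1[g]),
                    "count_p2": int(n2[g]),
                    "count_ambiguous": 0,
                }
            )
    f1_counts = pd.DataFrame(rows)

    sim_p1 = rng.binomial(grid_pairs_per_gene, 1.0 - dropout_p1, size=n_genes)
    sim_rows = [
        {
            "feature_id": f"g{g + 1:04d}",
            "replicate": "sim",
            "count_p1": int(sim_p1[g]),
            "count_p2": grid_pairs_per_gene,
            "count_ambiguous": 0,
        }
        for g in range(n_genes)
    ]
    sim_counts = pd.DataFrame(sim_rows)
    return f1_counts, sim_counts
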