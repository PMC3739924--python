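"""Readers and writers for FASTA, GTF, SAM, VCF and the pipeline's tables.

All in-memory coordinates are 0-based half-open.  Conversions to the 1-based
conventions of GTF and VCF happen only at the file boundary, in this module.
Reference bases are uppercased on read and any character outside {A,C,G,T,N}
is collapsed to N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "ReferenceSequence",
    "Feature",
    "AlignmentRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_sam",
    "write_sam",
    "write_vcf",
    "read_vcf",
    "ReadPair",
    "write_fastq_pair",
    "read_fastq_pair",
    "write_table",
    "read_table",
]

_VALID_BASES = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """A file violated the expectations of its declared format."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence name must be non-empty")
        if len(self.bases) < 1:
            raise FormatError(f"sequence {self.name!r} is empty")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Feature:
    """A gene or exon: a set of intervals on one sequence.

    ``intervals`` are 0-based half-open, sorted and non-overlapping.  The
    expression-counting unit can be either an entire gene or a single exon;
    exon features carry the ``gene_id`` of their parent gene.  After SNP
    projection, ``snps`` holds the fixed SNPs falling inside the intervals,
    in positional order.
    """

    feature_id: str
    gene_id: str
    kind: str  # "gene" | "exon"
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    strand: str = "."
    snps: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "exon"):
            raise ValueError(f"feature kind must be gene or exon, got {self.kind!r}")
        prev_end = None
        for start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"feature {self.feature_id!r}: interval ({start},{end}) empty or inverted"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"feature {self.feature_id!r}: intervals overlap or are unsorted"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        """Total spliced length (sum of interval lengths)."""
        return sum(e - s for s, e in self.intervals)

    @property
    def is_informative(self) -> bool:
        """True when at least one fixed SNP falls inside the feature."""
        return len(self.snps) > 0

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)

    def genomic_to_spliced(self, pos: int) -> int:
        """Map a genomic position inside the feature to its spliced offset."""
        offset = 0
        for s, e in self.intervals:
            if s <= pos < e:
                return offset + (pos - s)
            offset += e - s
        raise ValueError(f"position {pos} not inside feature {self.feature_id!r}")

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Concatenate the exonic sequence from a name->bases mapping."""
        seq = genome[self.chrom]
        return "".join(seq[s:e] for s, e in self.intervals)

    def with_snps(self, snps: Sequence) -> "Feature":
        return replace(self, snps=tuple(snps))


# CIGAR operation sets, mirroring the SAM specification.
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise FormatError(f"malformed CIGAR string {cigar!r}")
    return ops


def cigar_query_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in _QUERY_OPS)


@dataclass
class AlignmentRecord:
    """One aligned (or unmapped) read, the interchange unit with any mapper."""

    query_name: str
    chrom: str | None
    pos: int  # 0-based leftmost reference position
    cigar: str
    sequence: str
    is_read1: bool = True
    mate_chrom: str | None = None
    mate_pos: int = -1
    mapped: bool = True
    mismatch_count: int | None = None
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.mapped:
            if self.pos < 0:
                raise ValueError(f"{self.query_name}: mapped read with pos < 0")
            qlen = cigar_query_length(self.cigar)
            if qlen != len(self.sequence):
                raise FormatError(
                    f"{self.query_name}: CIGAR {self.cigar!r} consumes {qlen} query "
                    f"bases but SEQ has {len(self.sequence)}"
                )

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_index, reference_position) for aligned bases.

        Insertions consume query only, deletions/skips reference only, and
        soft-clipped bases are skipped entirely.
        """
        q, r = 0, self.pos
        for op, n in parse_cigar(self.cigar):
            if op in ("M", "=", "X"):
                for i in range(n):
                    yield q + i, r + i
                q += n
                r += n
            elif op in ("I", "S"):
                q += n
            elif op in ("D", "N"):
                r += n

    def reference_span(self) -> tuple[int, int]:
        """0-based half-open reference interval covered by the alignment."""
        return self.pos, self.pos + sum(
            n for op, n in parse_cigar(self.cigar) if op in _REF_OPS
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a multi-record FASTA into validated reference sequences.

    Bodies are uppercased, line breaks joined, and any non-ACGTN character
    collapsed to N.  Duplicate record names and empty files are format errors.
    """
    records: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence name {rec.id!r} in {path}")
        seen.add(rec.id)
        bases = _NON_ACGTN.sub("N", str(rec.seq).upper())
        if not bases:
            raise FormatError(f"record {rec.id!r} in {path} has an empty body")
        records.append(ReferenceSequence(rec.id, bases))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Iterable[ReferenceSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.name}\n")
            for i in range(0, len(seq.bases), width):
                fh.write(seq.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_attributes(field9: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(field9))


def read_gtf(path: str | Path) -> list[Feature]:
    """Read gene models from GTF.

    Exon records are required; 1-based closed coordinates are converted to
    0-based half-open.  Returns one gene feature aggregating the exon
    intervals of each ``gene_id`` plus one feature per exon, genes first,
    ordered by (chrom, start).
    """
    exons_by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = parts[:9]
            if ftype != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            attributes = _gtf_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            if gene_id not in exons_by_gene:
                exons_by_gene[gene_id] = []
                gene_order.append(gene_id)
            # GTF is 1-based closed; internal convention is 0-based half-open.
            exons_by_gene[gene_id].append((chrom, strand, start1 - 1, end1))

    genes: list[Feature] = []
    exons: list[Feature] = []
    for gene_id in gene_order:
        recs = sorted(exons_by_gene[gene_id], key=lambda r: r[2])
        chroms = {r[0] for r in recs}
        if len(chroms) > 1:
            raise FormatError(f"{path}: gene {gene_id!r} has exons on multiple sequences")
        chrom = recs[0][0]
        strand = recs[0][1] if recs[0][1] in "+-" else "."
        intervals = tuple((s, e) for _, _, s, e in recs)
        genes.append(Feature(gene_id, gene_id, "gene", chrom, intervals, strand))
        for i, (_, _, s, e) in enumerate(recs, start=1):
            exons.append(
                Feature(f"{gene_id}.exon{i}", gene_id, "exon", chrom, ((s, e),), strand)
            )
    genes.sort(key=lambda f: (f.chrom, f.start, f.feature_id))
    return genes + exons


def write_gtf(features: Iterable[Feature], path: str | Path, source: str = "asepipe") -> None:
    """Write exon records (one line per interval) for the gene features given."""
    with open(path, "w") as fh:
        for feat in features:
            if feat.kind != "gene":
                continue
            for s, e in feat.intervals:
                attrs = f'gene_id "{feat.gene_id}"; transcript_id "{feat.gene_id}.t1";'
                fh.write(
                    "\t".join(
                        [
                            feat.chrom,
                            source,
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            feat.strand if feat.strand in "+-" else ".",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# SAM


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file (coordinate or name order).

    POS is converted to 0-based; the NM tag, when present, populates
    ``mismatch_count``.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            mapped = not rec.is_unmapped
            yield AlignmentRecord(
                query_name=rec.query_name,
                chrom=rec.reference_name if mapped else None,
                pos=rec.reference_start if mapped else -1,
                cigar=rec.cigarstring or "",
                sequence=rec.query_sequence or "",
                is_read1=not rec.is_read2,
                mate_chrom=rec.next_reference_name,
                mate_pos=rec.next_reference_start if rec.next_reference_start is not None else -1,
                mapped=mapped,
                mismatch_count=rec.get_tag("NM") if rec.has_tag("NM") else None,
                is_reverse=rec.is_reverse,
            )


def write_sam(
    records: Iterable[AlignmentRecord],
    contigs: dict[str, int],
    path: str | Path,
) -> None:
    """Write alignment records as SAM 1.x with an @SQ header per contig."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.query_name
            a.query_sequence = rec.sequence
            a.flag = (
                0x1
                | (0x40 if rec.is_read1 else 0x80)
                | (0x4 if not rec.mapped else 0)
                | (0x10 if rec.is_reverse else 0)
            )
            if rec.mapped:
                a.reference_id = out.header.get_tid(rec.chrom)
                a.reference_start = rec.pos
                a.cigarstring = rec.cigar
                a.mapping_quality = 60
                if rec.mismatch_count is not None:
                    a.set_tag("NM", int(rec.mismatch_count))
            if rec.mate_chrom is not None:
                a.next_reference_id = out.header.get_tid(rec.mate_chrom)
                a.next_reference_start = rec.mate_pos
            out.write(a)


# ---------------------------------------------------------------------------
# FASTQ


@dataclass(frozen=True)
class ReadPair:
    """An unaligned paired-end read: mate 1 and mate 2 as sequenced."""

    name: str
    seq1: str
    seq2: str


def write_fastq_pair(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path, phred: int = 40
) -> None:
    """Write mates to two FASTQ files with constant base qualities."""
    qual = chr(phred + 33)
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.name}/1\n{pair.seq1}\n+\n{qual * len(pair.seq1)}\n")
            f2.write(f"@{pair.name}/2\n{pair.seq2}\n+\n{qual * len(pair.seq2)}\n")


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Read two mate FASTQ files back into read pairs (names must agree)."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    pairs: list[ReadPair] = []
    for r1, r2 in zip(it1, it2, strict=True):
        name1 = r1.id.removesuffix("/1")
        name2 = r2.id.removesuffix("/2")
        if name1 != name2:
            raise FormatError(f"mate name mismatch: {r1.id!r} vs {r2.id!r}")
        pairs.append(ReadPair(name1, str(r1.seq).upper(), str(r2.seq).upper()))
    return pairs


# ---------------------------------------------------------------------------
# VCF


def write_vcf(snps: Sequence, contigs: dict[str, int], path: str | Path) -> None:
    """Write fixed SNPs as VCF 4.2.

    REF is the parent-1 allele and ALT the parent-2 allele; INFO carries both
    parents' supporting depths (DP1/DP2) and major-allele purities (PU1/PU2).
    Input must be sorted by (chrom, pos); positions beyond the declared
    contig length are rejected.
    """
    prev = None
    for snp in snps:
        key = (snp.chrom, snp.pos)
        if prev is not None and key < prev:
            raise ValueError("SNPs must be sorted by (chrom, pos) for VCF output")
        prev = key
        if snp.chrom not in contigs:
            raise ValueError(f"SNP on undeclared contig {snp.chrom!r}")
        if not 0 <= snp.pos < contigs[snp.chrom]:
            raise ValueError(
                f"SNP position {snp.pos} outside contig {snp.chrom!r} "
                f"(length {contigs[snp.chrom]})"
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=asepipe\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP1,Number=1,Type=Integer,Description="Parent 1 depth">\n')
        fh.write('##INFO=<ID=DP2,Number=1,Type=Integer,Description="Parent 2 depth">\n')
        fh.write('##INFO=<ID=PU1,Number=1,Type=Float,Description="Parent 1 major-allele purity">\n')
        fh.write('##INFO=<ID=PU2,Number=1,Type=Float,Description="Parent 2 major-allele purity">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snp in snps:
            info = (
                f"DP1={snp.depth_p1};DP2={snp.depth_p2};"
                f"PU1={snp.purity_p1:.4f};PU2={snp.purity_p2:.4f}"
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos + 1}\t.\t{snp.allele_p1}\t{snp.allele_p2}"
                f"\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> list:
    """Read fixed SNPs back from a VCF written by :func:`write_vcf`."""
    from .snp_inference import FixedSnp

    snps: list[FixedSnp] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            snps.append(
                FixedSnp(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    allele_p1=rec.ref,
                    allele_p2=rec.alts[0],
                    depth_p1=int(info.get("DP1", 0)),
                    depth_p2=int(info.get("DP2", 0)),
                    purity_p1=float(info.get("PU1", 1.0)),
                    purity_p2=float(info.get("PU2", 1.0)),
                )
            )
    return snps


# ---------------------------------------------------------------------------
# Tabular outputs


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a single header line."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
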