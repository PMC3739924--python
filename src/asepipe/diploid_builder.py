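"""Construction of the two parent-specific genomes from fixed SNPs.

Substituting each parent's allele into a copy of the reference yields a
polymorphism-aware diploid reference: reads from either haplotype then map
with equal fidelity, removing most of the reference-allele mapping bias.
Substitution only — both genomes keep the reference coordinate system, which
the counting and simulation machinery relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import Feature, ReferenceSequence, read_fasta, write_fasta
from .snp_inference import FixedSnp

__all__ = [
    "ParentalGenomePair",
    "build_parental_genomes",
    "load_provided_genomes",
    "project_feature",
    "project_features",
    "write_parental_fastas",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParentalGenomePair:
    """The two SNP-substituted genomes plus the SNP map linking them.

    Both genomes have identical sequence names and lengths; they differ at
    exactly the fixed-SNP positions and agree everywhere else.
    """

    genome_p1: tuple[ReferenceSequence, ...]
    genome_p2: tuple[ReferenceSequence, ...]
    snps: tuple[FixedSnp, ...]
    source: str = "inferred"  # "inferred" | "provided"

    def lookup_p1(self) -> dict[str, str]:
        return {seq.name: seq.bases for seq in self.genome_p1}

    def lookup_p2(self) -> dict[str, str]:
        return {seq.name: seq.bases for seq in self.genome_p2}

    def snp_map(self) -> dict[tuple[str, int], FixedSnp]:
        return {(s.chrom, s.pos): s for s in self.snps}

    def contig_lengths(self) -> dict[str, int]:
        return {seq.name: len(seq.bases) for seq in self.genome_p1}

    def swapped(self) -> "ParentalGenomePair":
        """The same pair with the parent labels exchanged."""
        return ParentalGenomePair(
            self.genome_p2,
            self.genome_p1,
            tuple(s.swapped() for s in self.snps),
            self.source,
        )


def build_parental_genomes(
    reference: Sequence[ReferenceSequence],
    snps: Sequence[FixedSnp],
) -> ParentalGenomePair:
    """Substitute fixed-SNP alleles into the reference, once per parent.

    The reference itself is untouched.  SNP positions must be unique and
    inside their contig.
    """
    by_chrom: dict[str, list[FixedSnp]] = {}
    seen: set[tuple[str, int]] = set()
    for snp in snps:
        key = (snp.chrom, snp.pos)
        if key in seen:
            raise ValueError(f"two SNPs at one position {snp.chrom}:{snp.pos}")
        seen.add(key)
        by_chrom.setdefault(snp.chrom, []).append(snp)

    names = {seq.name for seq in reference}
    for chrom in by_chrom:
        if chrom not in names:
            raise ValueError(f"SNP on sequence {chrom!r} absent from the reference")

    genome_p1: list[ReferenceSequence] = []
    genome_p2: list[ReferenceSequence] = []
    for seq in reference:
        b1 = bytearray(seq.bases, "ascii")
        b2 = bytearray(seq.bases, "ascii")
        for snp in by_chrom.get(seq.name, ()):
            if not 0 <= snp.pos < len(seq.bases):
                raise ValueError(
                    f"SNP position {snp.pos} outside contig {seq.name!r} "
                    f"(length {len(seq.bases)})"
                )
            b1[snp.pos] = ord(snp.allele_p1)
            b2[snp.pos] = ord(snp.allele_p2)
        genome_p1.append(ReferenceSequence(seq.name, b1.decode("ascii")))
        genome_p2.append(ReferenceSequence(seq.name, b2.decode("ascii")))
    ordered = tuple(sorted(snps, key=lambda s: (s.chrom, s.pos)))
    return ParentalGenomePair(tuple(genome_p1), tuple(genome_p2), ordered, "inferred")


def load_provided_genomes(path_p1, path_p2) -> ParentalGenomePair:
    """Load two ready-made parental genomes and derive the SNP map.

    The genomes must have matching sequence names and per-contig lengths
    (substitution-only differences); every mismatching position becomes a
    fixed SNP with purity 1 and depth 0 (not applicable).  Positions where
    either genome carries N are not diagnostic and are skipped.
    """
    g1 = read_fasta(path_p1)
    g2 = read_fasta(path_p2)
    names1 = [s.name for s in g1]
    names2 = [s.name for s in g2]
    if set(names1) != set(names2):
        only1 = sorted(set(names1) - set(names2))
        only2 = sorted(set(names2) - set(names1))
        raise ValueError(
            f"parental genomes disagree on contigs: only in p1 {only1}, only in p2 {only2}"
        )
    by_name2 = {s.name: s for s in g2}
    bad_lengths = [
        (s.name, len(s.bases), len(by_name2[s.name].bases))
        for s in g1
        if len(s.bases) != len(by_name2[s.name].bases)
    ]
    if bad_lengths:
        raise ValueError(
            "parental contigs differ in length (substitution-only genomes required): "
            + ", ".join(f"{n}: {l1} vs {l2}" for n, l1, l2 in bad_lengths)
        )
    snps: list[FixedSnp] = []
    for seq1 in g1:
        seq2 = by_name2[seq1.name]
        for pos, (a, b) in enumerate(zip(seq1.bases, seq2.bases)):
            if a != b and a != "N" and b != "N":
                snps.append(FixedSnp(seq1.name, pos, a, b))
    if not snps:
        logger.warning("provided parental genomes are identical: no fixed SNPs")
    g2_ordered = tuple(by_name2[s.name] for s in g1)
    return ParentalGenomePair(tuple(g1), g2_ordered, tuple(snps), "provided")


def project_feature(feature: Feature, pair: ParentalGenomePair) -> Feature:
    """Attach the ordered list of contained fixed SNPs to a feature.

    Features containing no SNP are uninformative: no F1 read overlapping
    them can be assigned to a parent, so they are excluded from counting and
    testing downstream and reported separately.
    """
    if feature.chrom not in {s.name for s in pair.genome_p1}:
        raise ValueError(
            f"feature {feature.feature_id!r} on unknown sequence {feature.chrom!r}"
        )
    contained = [
        snp
        for snp in pair.snps
        if snp.chrom == feature.chrom and feature.contains(snp.pos)
    ]
    return feature.with_snps(contained)


def project_features(features: Sequence[Feature], pair: ParentalGenomePair) -> list[Feature]:
    """Project a whole annotation; SNPs are binned per chromosome first."""
    by_chrom: dict[str, list[FixedSnp]] = {}
    for snp in pair.snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)
    out: list[Feature] = []
    names = {s.name for s in pair.genome_p1}
    for feat in features:
        if feat.chrom not in names:
            raise ValueError(
                f"feature {feat.feature_id!r} on unknown sequence {feat.chrom!r}"
            )
        contained = [s for s in by_chrom.get(feat.chrom, ()) if feat.contains(s.pos)]
        out.append(feat.with_snps(contained))
    return out


def write_parental_fastas(
    pair: ParentalGenomePair,
    path_p1,
    path_p2,
    tag_p1: str = "_p1",
    tag_p2: str = "_p2",
) -> None:
    """Write both genomes as FASTA with name-tagged contigs for external mappers."""
    write_fasta(
        [ReferenceSequence(s.name + tag_p1, s.bases) for s in pair.genome_p1], path_p1
    )
    write_fasta(
        [ReferenceSequence(s.name + tag_p2, s.bases) for s in pair.genome_p2], path_p2
    )
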