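"""Identification of fixed SNPs between two parental lines from aligned reads.

The two parents are assumed to be (near-)monomorphic inbred lines, so a
"fixed SNP" is a site where each parent shows one dominant allele, the two
dominant alleles differ, and both parents are covered well enough to trust
the call.  These are the only sites at which an F1 read can be assigned to a
parental haplotype, so they are the atoms of every downstream computation.

The reference can be improved iteratively: map parental reads, call fixed
SNPs, substitute them into the reference to obtain parent-specific genomes,
remap each parent against its own genome and call again, until the SNP set
stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

from .io_formats import AlignmentRecord, ReferenceSequence

__all__ = [
    "PileupColumn",
    "FixedSnp",
    "SnpCallingParams",
    "pileup",
    "call_fixed_snps",
    "refine_iteratively",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one covered reference site.

    Reads contributing a deletion or an N at the site are excluded, so
    ``depth`` always equals the sum of the four counts.
    """

    chrom: str
    pos: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def major_allele(self) -> tuple[str, float]:
        """The most frequent allele and its fraction of the counted depth."""
        allele = max(self.counts, key=lambda b: (self.counts[b], b))
        return allele, self.counts[allele] / self.depth


@dataclass(frozen=True, order=True)
class FixedSnp:
    """A site where the two parents carry different fixed alleles."""

    chrom: str
    pos: int  # 0-based
    allele_p1: str
    allele_p2: str
    depth_p1: int = 0
    depth_p2: int = 0
    purity_p1: float = 1.0
    purity_p2: float = 1.0

    def __post_init__(self) -> None:
        if self.allele_p1 == self.allele_p2:
            raise ValueError(
                f"{self.chrom}:{self.pos}: parental alleles must differ "
                f"(both {self.allele_p1!r})"
            )

    def swapped(self) -> "FixedSnp":
        """The same site with the parent labels exchanged."""
        return FixedSnp(
            self.chrom,
            self.pos,
            self.allele_p2,
            self.allele_p1,
            self.depth_p2,
            self.depth_p1,
            self.purity_p2,
            self.purity_p1,
        )


@dataclass(frozen=True)
class SnpCallingParams:
    """Thresholds for declaring a site fixed in both parents.

    ``min_depth`` is the per-parent counted depth required at the site and
    ``min_purity`` the minimum fraction of that parent's reads carrying the
    major allele.  The defaults (10 reads, 0.9) tolerate occasional
    sequencing errors while still demanding near-monomorphic parents.
    """

    min_depth: int = 10
    min_purity: float = 0.9


def pileup(
    alignments: Iterable[AlignmentRecord],
    genome: Sequence[ReferenceSequence],
) -> list[PileupColumn]:
    """Count read bases per covered reference site, CIGAR-aware.

    Insertions consume query only, deletions reference only, and soft clips
    neither side's counted bases.  Each read pair's bases are counted once:
    where mates of a pair overlap the same site, only the first mate's base
    is counted.  Bases other than A/C/G/T are excluded from the column.
    """
    known = {seq.name for seq in genome}
    counts: dict[tuple[str, int], dict[str, int]] = {}
    seen_by_pair: dict[str, set[tuple[str, int]]] = {}
    for rec in alignments:
        if not rec.mapped:
            continue
        if rec.chrom not in known:
            raise ValueError(f"alignment {rec.query_name!r} to unknown sequence {rec.chrom!r}")
        pair_sites = seen_by_pair.setdefault(rec.query_name, set())
        seq = rec.sequence
        for qidx, rpos in rec.aligned_pairs():
            base = seq[qidx]
            if base not in _BASES:
                continue
            site = (rec.chrom, rpos)
            if site in pair_sites:
                continue  # mate overlap: count the pair's base once
            pair_sites.add(site)
            col = counts.setdefault(site, {})
            col[base] = col.get(base, 0) + 1
    return [
        PileupColumn(chrom, pos, col)
        for (chrom, pos), col in sorted(counts.items())
    ]


def call_fixed_snps(
    pileup_p1: Iterable[PileupColumn],
    pileup_p2: Iterable[PileupColumn],
    params: SnpCallingParams = SnpCallingParams(),
) -> list[FixedSnp]:
    """Emit sites fixed for different alleles in the two parents.

    A site qualifies iff each parent has depth >= ``min_depth``, a major
    allele with purity >= ``min_purity``, and the two major alleles differ.
    Sites failing any criterion are silently skipped.  Output is sorted by
    (chrom, pos).
    """
    cols_p2 = {(c.chrom, c.pos): c for c in pileup_p2}
    snps: list[FixedSnp] = []
    for col1 in pileup_p1:
        col2 = cols_p2.get((col1.chrom, col1.pos))
        if col2 is None:
            continue
        if col1.depth < params.min_depth or col2.depth < params.min_depth:
            continue
        a1, purity1 = col1.major_allele()
        a2, purity2 = col2.major_allele()
        if purity1 < params.min_purity or purity2 < params.min_purity:
            continue
        if a1 == a2:
            continue
        snps.append(
            FixedSnp(
                chrom=col1.chrom,
                pos=col1.pos,
                allele_p1=a1,
                allele_p2=a2,
                depth_p1=col1.depth,
                depth_p2=col2.depth,
                purity_p1=purity1,
                purity_p2=purity2,
            )
        )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return snps


def refine_iteratively(
    reads_p1,
    reads_p2,
    genome: Sequence[ReferenceSequence],
    mapper: Callable,
    params: SnpCallingParams = SnpCallingParams(),
    max_iters: int = 2,
):
    """Iteratively refine the fixed-SNP set and the parental genomes.

    Round 1 maps both parents against the shared reference; every later
    round substitutes the current SNP set into the reference and remaps each
    parent against its own parent-specific genome, so reads near true SNPs
    are no longer penalised for mismatching the reference.  Iteration stops
    when the SNP set (as (chrom, pos, alleles) tuples) is unchanged from the
    previous round, or after ``max_iters`` mapping rounds.

    ``mapper`` is any callable ``mapper(read_pairs, genome) -> alignments``
    satisfying the aligner contract.  Returns ``(snps, pair, converged)``
    where ``pair`` is the final :class:`~asepipe.diploid_builder.ParentalGenomePair`.
    """
    from .diploid_builder import build_parental_genomes

    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")

    genome_p1: Sequence[ReferenceSequence] = genome
    genome_p2: Sequence[ReferenceSequence] = genome
    prev_key: set | None = None
    snps: list[FixedSnp] = []
    pair = None
    converged = False
    for iteration in range(1, max_iters + 1):
        try:
            aln_p1 = mapper(reads_p1, genome_p1)
            aln_p2 = mapper(reads_p2, genome_p2)
        except Exception as exc:
            raise RuntimeError(f"mapper failed in refinement iteration {iteration}") from exc
        snps = call_fixed_snps(
            pileup(aln_p1, genome_p1), pileup(aln_p2, genome_p2), params
        )
        key = {(s.chrom, s.pos, s.allele_p1, s.allele_p2) for s in snps}
        pair = build_parental_genomes(genome, snps)
        if prev_key is not None and key == prev_key:
            converged = True
            break
        prev_key = key
        genome_p1 = pair.genome_p1
        genome_p2 = pair.genome_p2
    return snps, pair, converged
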