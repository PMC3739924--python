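"""A minimal deterministic paired-end aligner for in-repo pipeline runs.

Production users bring alignments from a real splice-aware mapper as SAM;
this module exists so the whole pipeline is runnable and testable without
one, and it pins down the mapper contract any external tool must satisfy:
deterministic output, per-read mismatch counts, and alignment against the
combined diploid reference (both parent-specific genomes).

The algorithm is exact-k-mer seed and ungapped extend.  Because the two
parental genomes share one coordinate system, a candidate locus is scored on
both haplotypes and receives the better of the two scores; a read pair whose
best score is achieved at two *different* loci is discarded as a
multi-mapper, while equal scores at the *same* coordinate on both haplotypes
are perfectly normal (the pair simply spans no diagnostic site) and the pair
is kept.  That separation matters: mapping ambiguity is noise, allelic
ambiguity is data.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .diploid_builder import ParentalGenomePair
from .io_formats import AlignmentRecord, ReadPair, ReferenceSequence

__all__ = [
    "AlignerParams",
    "PairedEndAligner",
    "DiploidAligner",
    "LossyDiploidAligner",
    "build_index",
    "make_single_genome_mapper",
    "reverse_complement",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class AlignerParams:
    """Seed-and-extend parameters.

    ``insert_size`` is the nominal inner mate distance; pairs are accepted
    with an observed insert within ``insert_size ± insert_slack``.
    ``max_mismatch`` applies per read.
    """

    k: int = 20
    max_mismatch: int = 5
    insert_size: int = 78
    insert_slack: int = 20

    @property
    def insert_range(self) -> tuple[int, int]:
        return self.insert_size - self.insert_slack, self.insert_size + self.insert_slack


def build_index(
    genome: Sequence[ReferenceSequence], k: int
) -> dict[str, list[tuple[str, int]]]:
    """Exact k-mer -> [(chrom, pos)] map over all contigs."""
    if k < 8:
        raise ValueError(f"seed length k must be >= 8, got {k}")
    shortest = min(len(seq.bases) for seq in genome)
    if k > shortest:
        raise ValueError(f"seed length {k} exceeds shortest contig length {shortest}")
    index: dict[str, list[tuple[str, int]]] = {}
    for seq in genome:
        bases = seq.bases
        for pos in range(len(bases) - k + 1):
            index.setdefault(bases[pos : pos + k], []).append((seq.name, pos))
    return index


class _Haplotype:
    """One indexed genome copy the aligner can score reads against."""

    def __init__(self, label: str, genome: Sequence[ReferenceSequence], k: int):
        self.label = label
        self.arrays = {
            seq.name: np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
            for seq in genome
        }
        self.index = build_index(genome, k)

    def mismatches(self, chrom: str, start: int, read: np.ndarray) -> int | None:
        contig = self.arrays[chrom]
        if start < 0 or start + read.size > contig.size:
            return None
        return int(np.count_nonzero(contig[start : start + read.size] != read))


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class PairedEndAligner:
    """Deterministic seed-and-extend aligner over one or more haplotypes.

    All haplotypes must share sequence names and lengths (the diploid
    coordinate system); a locus is scored as the minimum mismatch total over
    haplotypes, each read capped at ``max_mismatch`` per haplotype.
    """

    def __init__(
        self,
        haplotypes: Sequence[tuple[str, Sequence[ReferenceSequence]]],
        params: AlignerParams = AlignerParams(),
    ):
        if not haplotypes:
            raise ValueError("at least one haplotype required")
        self.params = params
        self.haplotypes = [_Haplotype(label, g, params.k) for label, g in haplotypes]

    # -- candidate generation -----------------------------------------------

    def _seed_starts(self, read: str) -> dict[str, set[int]]:
        """Candidate read-start positions from exact seed hits, per chrom."""
        k = self.params.k
        offsets = list(range(0, len(read) - k + 1, k))
        last = len(read) - k
        if last not in offsets:
            offsets.append(last)
        starts: dict[str, set[int]] = {}
        for hap in self.haplotypes:
            for off in offsets:
                for chrom, pos in hap.index.get(read[off : off + k], ()):
                    starts.setdefault(chrom, set()).add(pos - off)
        return starts

    # -- pair alignment ------------------------------------------------------

    def align_pair_detail(self, pair: ReadPair):
        """Best placement of a pair, or None.

        Returns ``(records, preferred_label)`` where ``preferred_label`` is
        the haplotype with the strictly better score at the chosen locus, or
        None on a haplotype tie.  ``records`` is the (read1, read2) tuple of
        alignment records in the shared coordinate system.
        """
        if len(pair.seq1) < self.params.k or len(pair.seq2) < self.params.k:
            return None
        ins_lo, ins_hi = self.params.insert_range
        max_mm = self.params.max_mismatch
        orientations = (
            # (left sequence, right sequence, read1 is the left mate)
            ("fr", pair.seq1, reverse_complement(pair.seq2), True),
            ("rf", pair.seq2, reverse_complement(pair.seq1), False),
        )
        loci: dict[tuple, tuple[int, str | None, int, int]] = {}
        for orient, left, right, r1_left in orientations:
            left_arr, right_arr = _as_array(left), _as_array(right)
            cand_left = self._seed_starts(left)
            cand_right = self._seed_starts(right)
            for chrom, lefts in cand_left.items():
                rights = sorted(cand_right.get(chrom, ()))
                if not rights:
                    continue
                for start_l in sorted(lefts):
                    lo = start_l + len(left) + ins_lo
                    hi = start_l + len(left) + ins_hi
                    for idx in range(bisect_left(rights, lo), bisect_right(rights, hi)):
                        start_r = rights[idx]
                        key = (chrom, start_l, start_r, orient, r1_left)
                        if key in loci:
                            continue
                        best: tuple[int, str | None, int, int] | None = None
                        tied = False
                        for hap in self.haplotypes:
                            ml = hap.mismatches(chrom, start_l, left_arr)
                            mr = hap.mismatches(chrom, start_r, right_arr)
                            if ml is None or mr is None or ml > max_mm or mr > max_mm:
                                continue
                            score = ml + mr
                            if best is None or score < best[0]:
                                best = (score, hap.label, ml, mr)
                                tied = False
                            elif score == best[0]:
                                tied = True
                        if best is not None:
                            score, label, ml, mr = best
                            loci[key] = (score, None if tied else label, ml, mr)
        if not loci:
            return None
        best_score = min(v[0] for v in loci.values())
        winners = sorted(k for k, v in loci.items() if v[0] == best_score)
        if len(winners) > 1:
            return None  # equal best score at distinct loci: multi-mapper
        key = winners[0]
        chrom, start_l, start_r, orient, r1_left = key
        _, label, ml, mr = loci[key]
        left_seq = pair.seq1 if r1_left else pair.seq2
        right_seq = reverse_complement(pair.seq2 if r1_left else pair.seq1)
        left_rec = AlignmentRecord(
            query_name=pair.name,
            chrom=chrom,
            pos=start_l,
            cigar=f"{len(left_seq)}M",
            sequence=left_seq,
            is_read1=r1_left,
            mate_chrom=chrom,
            mate_pos=start_r,
            mapped=True,
            mismatch_count=ml,
            is_reverse=False,
        )
        right_rec = AlignmentRecord(
            query_name=pair.name,
            chrom=chrom,
            pos=start_r,
            cigar=f"{len(right_seq)}M",
            sequence=right_seq,
            is_read1=not r1_left,
            mate_chrom=chrom,
            mate_pos=start_l,
            mapped=True,
            mismatch_count=mr,
            is_reverse=True,
        )
        records = (left_rec, right_rec) if r1_left else (right_rec, left_rec)
        return records, label

    def align_pair(self, pair: ReadPair):
        """Best (read1, read2) alignment records for a pair, or None."""
        detail = self.align_pair_detail(pair)
        return None if detail is None else detail[0]

    def map_pairs(self, pairs: Iterable[ReadPair]) -> list[AlignmentRecord]:
        """Align many pairs; unmappable or ambiguous pairs are dropped."""
        out: list[AlignmentRecord] = []
        for pair in pairs:
            hit = self.align_pair(pair)
            if hit is not None:
                out.extend(hit)
        return out


class DiploidAligner(PairedEndAligner):
    """Aligner over the combined diploid reference of a parental genome pair."""

    def __init__(self, pair: ParentalGenomePair, params: AlignerParams = AlignerParams()):
        super().__init__(
            [("p1", pair.genome_p1), ("p2", pair.genome_p2)], params
        )


class LossyDiploidAligner(DiploidAligner):
    """Diploid aligner that loses a fraction of parent-1-diagnostic pairs.

    A pair is diagnostic for parent 1 when its best locus scores strictly
    better on the parent-1 haplotype; each such pair is dropped with
    probability ``dropout_p1``.  This injects a controlled allele-specific
    mapping loss, the failure mode that residual-bias estimation exists to
    measure: running the error-free simulation grid through this aligner
    recovers a per-feature expression ratio below one.
    """

    def __init__(
        self,
        pair: ParentalGenomePair,
        dropout_p1: float,
        seed: int,
        params: AlignerParams = AlignerParams(),
    ):
        super().__init__(pair, params)
        if not 0.0 <= dropout_p1 < 1.0:
            raise ValueError("dropout_p1 must be in [0, 1)")
        self.dropout_p1 = dropout_p1
        self._rng = np.random.default_rng(seed)

    def align_pair(self, pair: ReadPair):
        detail = self.align_pair_detail(pair)
        if detail is None:
            return None
        records, label = detail
        if label == "p1" and self._rng.random() < self.dropout_p1:
            return None
        return records


def make_single_genome_mapper(params: AlignerParams = AlignerParams()):
    """A ``mapper(read_pairs, genome) -> alignments`` closure over one genome.

    This is the callable shape :func:`asepipe.snp_inference.refine_iteratively`
    expects for mapping each parent's reads.
    """

    def mapper(
        read_pairs: Iterable[ReadPair], genome: Sequence[ReferenceSequence]
    ) -> list[AlignmentRecord]:
        aligner = PairedEndAligner([("ref", genome)], params)
        return aligner.map_pairs(read_pairs)

    return mapper
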