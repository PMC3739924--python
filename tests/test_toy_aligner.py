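import numpy as np
import pytest

from asepipe.diploid_builder import build_parental_genomes
from asepipe.io_formats import ReadPair, ReferenceSequence
from asepipe.snp_inference import FixedSnp
from asepipe.toy_aligner import (
    AlignerParams,
    DiploidAligner,
    LossyDiploidAligner,
    PairedEndAligner,
    build_index,
    make_single_genome_mapper,
    reverse_complement,
)

from conftest import FIXTURE_ALIGNER


class TestIndex:
    def test_kmer_positions(self):
        idx = build_index([ReferenceSequence("c", "ACGTACGT")], k=8)
        assert idx["ACGTACGT"] == [("c", 0)]
        # repeated k-mers collect all positions
        idx = build_index([ReferenceSequence("c", "ACGTACGTACGT")], k=8)
        assert idx["ACGTACGT"] == [("c", 0), ("c", 4)]

    def test_k_longer_than_contig_rejected(self):
        with pytest.raises(ValueError, match="exceeds shortest contig"):
            build_index([ReferenceSequence("c", "ACGTACGT")], k=9)

    def test_deterministic_across_builds(self):
        g = [ReferenceSequence("c", "ACGT" * 10)]
        assert build_index(g, 8) == build_index(g, 8)


def _simulate_pairs(genome_bases, rng, n, L, insert):
    frag = 2 * L + insert
    pairs, truth = [], []
    for i in range(n):
        start = int(rng.integers(0, len(genome_bases) - frag + 1))
        r1 = genome_bases[start : start + L]
        r2 = reverse_complement(genome_bases[start + frag - L : start + frag])
        pairs.append(ReadPair(f"r{i}", r1, r2))
        truth.append(start)
    return pairs, truth


class TestSingleGenomeAlignment:
    def test_error_free_pairs_recover_true_positions(self, fixture20):
        bases = fixture20.pair.genome_p1[0].bases
        rng = np.random.default_rng(0)
        pairs, truth = _simulate_pairs(bases, rng, 200, 50, 20)
        aligner = PairedEndAligner([("ref", fixture20.pair.genome_p1)], FIXTURE_ALIGNER)
        for pair, start in zip(pairs, truth):
            recs = aligner.align_pair(pair)
            assert recs is not None and recs[0].pos == start

    def test_mismatch_count_is_hamming_distance(self, fixture20):
        bases = fixture20.pair.genome_p1[0].bases
        rng = np.random.default_rng(1)
        pairs, truth = _simulate_pairs(bases, rng, 100, 50, 20)
        aligner = PairedEndAligner([("ref", fixture20.pair.genome_p1)], FIXTURE_ALIGNER)
        alphabet = "ACGT"
        for pair, start in zip(pairs, truth):
            # inject up to 2 substitutions into read 1
            seq = list(pair.seq1)
            for j in rng.integers(0, len(seq), size=2):
                seq[j] = alphabet[int(rng.integers(0, 4))]
            mutated = ReadPair(pair.name, "".join(seq), pair.seq2)
            recs = aligner.align_pair(mutated)
            if recs is None:
                continue
            rec1 = recs[0]
            window = bases[rec1.pos : rec1.pos + len(rec1.sequence)]
            ham = sum(a != b for a, b in zip(window, rec1.sequence))
            assert rec1.mismatch_count == ham

    def test_insert_outside_range_unmapped(self, fixture20):
        bases = fixture20.pair.genome_p1[0].bases
        L, far_insert = 50, 300  # range is 20 +/- 10
        start = 1000
        r1 = bases[start : start + L]
        r2 = reverse_complement(
            bases[start + L + far_insert : start + 2 * L + far_insert]
        )
        aligner = PairedEndAligner([("ref", fixture20.pair.genome_p1)], FIXTURE_ALIGNER)
        assert aligner.align_pair(ReadPair("r", r1, r2)) is None

    def test_repeat_locus_tie_discarded(self):
        # two identical 200 bp arms: any pair from one arm maps to both
        arm = "".join(
            np.random.default_rng(3).choice(list("ACGT"), 200)
        )
        genome = [ReferenceSequence("c", arm + "T" * 50 + arm)]
        params = AlignerParams(k=20, max_mismatch=2, insert_size=20, insert_slack=10)
        aligner = PairedEndAligner([("ref", genome)], params)
        r1 = arm[0:50]
        r2 = reverse_complement(arm[120:170])
        assert aligner.align_pair(ReadPair("r", r1, r2)) is None


class TestDiploidAlignment:
    def test_same_coordinate_on_both_genomes_is_kept(self, fixture20):
        # a pair from a SNP-free stretch scores equally on both haplotypes at
        # one coordinate: allelic ambiguity, not a mapping tie
        gene = fixture20.genes[0]
        bases = fixture20.pair.genome_p1[0].bases
        snp_positions = {s.pos for s in gene.snps}
        start = next(
            s
            for s in range(gene.start, gene.end - 120)
            if not any(p in snp_positions for p in range(s, s + 120))
        )
        r1 = bases[start : start + 50]
        r2 = reverse_complement(bases[start + 70 : start + 120])
        aligner = DiploidAligner(fixture20.pair, FIXTURE_ALIGNER)
        detail = aligner.align_pair_detail(ReadPair("r", r1, r2))
        assert detail is not None
        records, preferred = detail
        assert preferred is None  # haplotype tie, pair kept
        assert records[0].pos == start

    def test_snp_spanning_pair_prefers_true_haplotype(self, fixture20):
        gene = fixture20.genes[0]
        snp = gene.snps[0]
        bases2 = fixture20.pair.genome_p2[0].bases
        start = max(gene.start, snp.pos - 25)
        r1 = bases2[start : start + 50]
        r2 = reverse_complement(bases2[start + 70 : start + 120])
        aligner = DiploidAligner(fixture20.pair, FIXTURE_ALIGNER)
        records, preferred = aligner.align_pair_detail(ReadPair("r", r1, r2))
        assert preferred == "p2"
        assert records[0].mismatch_count == 0

    def test_lossy_aligner_drops_expected_fraction_of_p1_reads(self, fixture20):
        gene = fixture20.genes[1]
        snp = gene.snps[0]
        bases1 = fixture20.pair.genome_p1[0].bases
        start = max(gene.start, snp.pos - 25)
        r1 = bases1[start : start + 50]
        r2 = reverse_complement(bases1[start + 70 : start + 120])
        pairs = [ReadPair(f"r{i}", r1, r2) for i in range(400)]
        lossy = LossyDiploidAligner(fixture20.pair, 0.3, seed=9, params=FIXTURE_ALIGNER)
        kept = sum(lossy.align_pair(p) is not None for p in pairs)
        assert 400 * 0.7 - 3 * np.sqrt(400 * 0.21) <= kept <= 400 * 0.7 + 3 * np.sqrt(400 * 0.21)

    def test_determinism(self, fixture20):
        # two aligners over identical inputs give identical output
        rng = np.random.default_rng(5)
        pairs, _ = _simulate_pairs(fixture20.pair.genome_p1[0].bases, rng, 50, 50, 20)
        a1 = DiploidAligner(fixture20.pair, FIXTURE_ALIGNER)
        a2 = DiploidAligner(fixture20.pair, FIXTURE_ALIGNER)
        assert a1.map_pairs(pairs) == a2.map_pairs(pairs)


def test_single_genome_mapper_contract(fixture20):
    mapper = make_single_genome_mapper(FIXTURE_ALIGNER)
    alignments = mapper(fixture20.parental_reads_p1[:20], fixture20.reference)
    assert alignments and all(rec.mismatch_count is not None for rec in alignments)
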