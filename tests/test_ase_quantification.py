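from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from asepipe.ase_quantification import (
    AlleleCountTable,
    assign_pair,
    bias_frame,
    count_features,
    estimate_bias,
    merge_tables,
)
from asepipe.diploid_builder import build_parental_genomes, project_features
from asepipe.io_formats import AlignmentRecord, Feature, ReferenceSequence
from asepipe.snp_inference import FixedSnp
from asepipe.toy_aligner import DiploidAligner

from conftest import FIXTURE_ALIGNER


def _snp_lookup(snps):
    snp_map = {(s.chrom, s.pos): s for s in snps}
    positions = defaultdict(list)
    for c, p in snp_map:
        positions[c].append(p)
    for v in positions.values():
        v.sort()
    return positions, snp_map


SNPS = [FixedSnp("c", 5, "A", "G"), FixedSnp("c", 12, "C", "T")]


def _rec(pos, seq, name="r", read1=True):
    return AlignmentRecord(name, "c", pos, f"{len(seq)}M", seq, is_read1=read1)


class TestAssignPair:
    def test_single_snp_matching_parent1(self):
        positions, snp_map = _snp_lookup(SNPS)
        rec = _rec(3, "TTATT")  # covers pos 5 with "A" (parent-1 allele)
        label, covered = assign_pair([rec], positions, snp_map)
        assert label == "p1" and covered == [("c", 5)]

    def test_conflicting_snps_ambiguous(self):
        positions, snp_map = _snp_lookup(SNPS)
        # mate 1 shows the p1 allele at pos 5, mate 2 the p2 allele at pos 12
        seq = list("T" * 12)
        seq[5 - 3] = "A"
        rec1 = _rec(3, "".join(seq))
        seq2 = list("T" * 8)
        seq2[12 - 10] = "T"  # p2 allele at pos 12
        rec2 = _rec(10, "".join(seq2), read1=False)
        label, covered = assign_pair([rec1, rec2], positions, snp_map)
        assert label == "ambiguous" and ("c", 5) in covered and ("c", 12) in covered

    def test_two_concordant_snps_assign_parent2(self):
        positions, snp_map = _snp_lookup(SNPS)
        seq = list("A" * 14)
        seq[5] = "G"
        seq[12] = "T"
        rec = _rec(0, "".join(seq))
        label, covered = assign_pair([rec], positions, snp_map)
        assert label == "p2" and covered == [("c", 5), ("c", 12)]

    def test_no_covered_snp_is_ambiguous(self):
        positions, snp_map = _snp_lookup(SNPS)
        assert assign_pair([_rec(20, "AAAA")], positions, snp_map)[0] == "ambiguous"

    def test_non_parental_base_at_all_snps_is_ambiguous(self):
        positions, snp_map = _snp_lookup(SNPS)
        seq = list("A" * 14)
        seq[5] = "C"  # neither A nor G
        rec = _rec(0, "".join(seq))
        label, _ = assign_pair([rec], positions, snp_map)
        assert label == "ambiguous"


class TestCountFeatures:
    def _setup(self):
        bases = "".join(np.random.default_rng(0).choice(list("ACGT"), 100))
        ref = [ReferenceSequence("c", bases)]
        snps = [FixedSnp("c", 15, bases[15], "A" if bases[15] != "A" else "C"),
                FixedSnp("c", 55, bases[55], "G" if bases[55] != "G" else "T")]
        pair = build_parental_genomes(ref, snps)
        gene = Feature("g", "g", "gene", "c", ((0, 30), (40, 70)), "+")
        e1 = Feature("g.e1", "g", "exon", "c", ((0, 30),), "+")
        e2 = Feature("g.e2", "g", "exon", "c", ((40, 70),), "+")
        feats = project_features([gene, e1, e2], pair)
        return pair, feats

    def test_snp_in_second_exon_increments_gene_and_that_exon_only(self):
        pair, feats = self._setup()
        bases1 = pair.genome_p1[0].bases
        rec = _rec(50, bases1[50:60], name="x")  # covers SNP at 55, p1 allele
        table = count_features([rec], feats, "rep1")
        d = table.data.set_index("feature_id")
        assert d.loc["g", "count_p1"] == 1
        assert d.loc["g.e2", "count_p1"] == 1
        assert d.loc["g.e1", "count_p1"] == 0

    def test_pair_counted_once_per_feature_despite_two_snps(self):
        pair, feats = self._setup()
        bases2 = pair.genome_p2[0].bases
        rec1 = _rec(10, bases2[10:25], name="y")       # SNP 15, p2
        rec2 = _rec(50, bases2[50:60], name="y", read1=False)  # SNP 55, p2
        table = count_features([rec1, rec2], feats, "rep1")
        d = table.data.set_index("feature_id")
        assert d.loc["g", "count_p2"] == 1
        assert d.loc["g.e1", "count_p2"] == 1 and d.loc["g.e2", "count_p2"] == 1

    def test_overlapping_pair_without_snp_counts_ambiguous(self):
        pair, feats = self._setup()
        bases1 = pair.genome_p1[0].bases
        rec = _rec(41, bases1[41:51], name="z")  # inside exon 2, no SNP covered
        table = count_features([rec], feats, "rep1")
        d = table.data.set_index("feature_id")
        assert d.loc["g", "count_ambiguous"] == 1
        assert d.loc["g", "count_p1"] == 0

    def test_zero_alignments_gives_zero_table_with_universe(self):
        _, feats = self._setup()
        table = count_features([], feats, "rep1")
        assert set(table.data["feature_id"]) == {"g", "g.e1", "g.e2"}
        assert (table.data[["count_p1", "count_p2", "count_ambiguous"]] == 0).all().all()

    def test_replicate_collision_rejected(self):
        _, feats = self._setup()
        t1 = count_features([], feats, "rep1")
        with pytest.raises(ValueError, match="collision"):
            merge_tables([t1, t1])


class TestFixtureOracle:
    def test_assignment_agrees_with_truth_for_snp_covering_pairs(self, fixture20):
        """Error-free F1 pairs that cover >= 1 SNP must all be assigned to
        their true allele of origin."""
        aligner = DiploidAligner(fixture20.pair, FIXTURE_ALIGNER)
        positions, snp_map = _snp_lookup(fixture20.snps)
        truth = fixture20.truth_pairs.set_index("name")
        reads = fixture20.f1_reads["rep1"][:600]
        checked = 0
        for pair in reads:
            recs = aligner.align_pair(pair)
            if recs is None:
                continue
            label, _ = assign_pair(recs, positions, snp_map)
            row = truth.loc[pair.name]
            if row.covers_snp:
                assert label == row.allele
                checked += 1
            else:
                assert label == "ambiguous"
        assert checked > 100

    def test_label_symmetry_under_parent_swap(self, fixture20):
        aligner = DiploidAligner(fixture20.pair, FIXTURE_ALIGNER)
        aln = aligner.map_pairs(fixture20.f1_reads["rep1"][:300])
        feats = fixture20.features
        fwd = count_features(aln, feats, "rep1").data.set_index("feature_id")
        swapped_pair = fixture20.pair.swapped()
        feats_sw = project_features(
            [f.with_snps(()) for f in feats], swapped_pair
        )
        rev = count_features(aln, feats_sw, "rep1").data.set_index("feature_id")
        assert (fwd["count_p1"] == rev["count_p2"]).all()
        assert (fwd["count_p2"] == rev["count_p1"]).all()
        assert (fwd["count_ambiguous"] == rev["count_ambiguous"]).all()

    def test_conservation_of_assigned_pairs(self, fixture20):
        aligner = DiploidAligner(fixture20.pair, FIXTURE_ALIGNER)
        aln = aligner.map_pairs(fixture20.f1_reads["rep1"])
        table = count_features(aln, fixture20.features, "rep1")
        gene_rows = table.for_level("gene").data
        n_pairs = len({r.query_name for r in aln})
        # every mapped pair lands in exactly one single-exon gene here
        total = (
            gene_rows["count_p1"] + gene_rows["count_p2"] + gene_rows["count_ambiguous"]
        ).sum()
        assert total == n_pairs


class TestEstimateBias:
    def _table(self, rows):
        df = pd.DataFrame(
            [
                {
                    "feature_id": fid,
                    "replicate": "sim",
                    "count_p1": p1,
                    "count_p2": p2,
                    "count_ambiguous": 0,
                }
                for fid, p1, p2 in rows
            ]
        )
        return AlleleCountTable(df, {fid: "gene" for fid, _, _ in rows})

    def test_unbiased_feature_not_flagged(self):
        (b,) = estimate_bias(self._table([("g", 100, 100)]))
        assert b.ratio == 1.0 and not b.flagged and not b.untestable

    def test_threshold_boundary_not_flagged(self):
        (b,) = estimate_bias(self._table([("g", 105, 100)]))
        assert b.bias_pct == pytest.approx(5.0) and not b.flagged

    def test_above_threshold_flagged(self):
        (b,) = estimate_bias(self._table([("g", 110, 100)]))
        assert b.flagged

    def test_zero_denominator_untestable(self):
        (b,) = estimate_bias(self._table([("g", 50, 0)]))
        assert b.untestable

    def test_bias_frame_columns(self):
        df = bias_frame(estimate_bias(self._table([("g", 100, 100)])))
        assert list(df.columns) == [
            "feature_id", "sim_p1", "sim_p2", "ratio", "bias_pct", "flagged", "untestable",
        ]
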