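"""Allele assignment of aligned F1 read pairs and per-feature counting.

A read pair can only be attributed to a parental haplotype through the
fixed SNPs it covers.  The assignment rule is strict: every diagnostic
allele observed by the pair must agree with the same parent, otherwise the
pair is ambiguous — no majority voting.  A pair is counted at most once per
feature regardless of how many SNPs it spans.

The same counting machinery, applied to the mapped simulation grid, yields
the per-feature residual mapping bias: the ratio of simulated parent-1 to
parent-2 pair counts, which should be exactly one for an unbiased mapper.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AlignmentRecord, Feature
from .snp_inference import FixedSnp

__all__ = [
    "AlleleCountTable",
    "BiasFactor",
    "assign_pair",
    "count_features",
    "merge_tables",
    "estimate_bias",
    "bias_frame",
]

_COLUMNS = ["feature_id", "replicate", "count_p1", "count_p2", "count_ambiguous"]


@dataclass
class AlleleCountTable:
    """Per-feature, per-replicate allele-assigned pair counts.

    ``data`` has one row per (feature_id, replicate) with integer columns
    count_p1 / count_p2 / count_ambiguous; ``levels`` maps each feature_id
    of the declared universe to its level ("gene" or "exon"), so an empty
    library still yields a complete, zero-filled table.
    """

    data: pd.DataFrame
    levels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")

    def replicate_ids(self) -> list[str]:
        return sorted(self.data["replicate"].unique())

    def pooled(self) -> pd.DataFrame:
        """Counts summed over replicates, one row per feature."""
        pooled = (
            self.data.groupby("feature_id", sort=True)[
                ["count_p1", "count_p2", "count_ambiguous"]
            ]
            .sum()
            .reset_index()
        )
        return pooled

    def for_level(self, level: str) -> "AlleleCountTable":
        keep = {f for f, lv in self.levels.items() if lv == level}
        return AlleleCountTable(
            self.data[self.data["feature_id"].isin(keep)].reset_index(drop=True),
            {f: lv for f, lv in self.levels.items() if lv == level},
        )


def merge_tables(tables: Sequence[AlleleCountTable]) -> AlleleCountTable:
    """Concatenate per-replicate tables; replicate id collisions are errors."""
    seen: set[str] = set()
    levels: dict[str, str] = {}
    for t in tables:
        reps = set(t.replicate_ids())
        clash = seen & reps
        if clash:
            raise ValueError(f"replicate id collision: {sorted(clash)}")
        seen |= reps
        levels.update(t.levels)
    return AlleleCountTable(
        pd.concat([t.data for t in tables], ignore_index=True), levels
    )


# ---------------------------------------------------------------------------
# Assignment


def _covered_snp_bases(
    rec: AlignmentRecord,
    snp_positions: dict[str, list[int]],
    snp_map: dict[tuple[str, int], FixedSnp],
) -> dict[tuple[str, int], set[str]]:
    """Bases the read shows at each fixed-SNP position it aligns across."""
    out: dict[tuple[str, int], set[str]] = {}
    positions = snp_positions.get(rec.chrom)
    if not positions:
        return out
    span_start, span_end = rec.reference_span()
    i = bisect_left(positions, span_start)
    hits = []
    while i < len(positions) and positions[i] < span_end:
        hits.append(positions[i])
        i += 1
    if not hits:
        return out
    simple = rec.cigar == f"{len(rec.sequence)}M"
    if simple:
        for pos in hits:
            out.setdefault((rec.chrom, pos), set()).add(rec.sequence[pos - rec.pos])
    else:
        wanted = set(hits)
        for qidx, rpos in rec.aligned_pairs():
            if rpos in wanted:
                out.setdefault((rec.chrom, rpos), set()).add(rec.sequence[qidx])
    return out


def assign_pair(
    records: Sequence[AlignmentRecord],
    snp_positions: dict[str, list[int]],
    snp_map: dict[tuple[str, int], FixedSnp],
) -> tuple[str, list[tuple[str, int]]]:
    """Assign a mapped pair to "p1", "p2" or "ambiguous".

    Collects the alleles the pair's bases show at every covered fixed SNP.
    All observed diagnostic alleles from parent 1 -> "p1"; all from parent 2
    -> "p2"; no SNP covered, conflicting parents, a conflicting observation
    at one SNP, or only non-parental bases -> "ambiguous".  Returns the
    label and the covered SNP sites.
    """
    observed: dict[tuple[str, int], set[str]] = {}
    for rec in records:
        if not rec.mapped:
            continue
        for site, bases in _covered_snp_bases(rec, snp_positions, snp_map).items():
            observed.setdefault(site, set()).update(bases)
    if not observed:
        return "ambiguous", []
    votes: set[str] = set()
    for site, bases in observed.items():
        snp = snp_map[site]
        saw_p1 = snp.allele_p1 in bases
        saw_p2 = snp.allele_p2 in bases
        if saw_p1 and saw_p2:
            return "ambiguous", sorted(observed)
        if saw_p1:
            votes.add("p1")
        elif saw_p2:
            votes.add("p2")
    covered = sorted(observed)
    if votes == {"p1"}:
        return "p1", covered
    if votes == {"p2"}:
        return "p2", covered
    return "ambiguous", covered


# ---------------------------------------------------------------------------
# Counting


def _group_pairs(alignments: Iterable[AlignmentRecord]):
    by_name: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        by_name[rec.query_name].append(rec)
    return by_name


def count_features(
    alignments: Iterable[AlignmentRecord],
    features: Sequence[Feature],
    replicate_id: str,
) -> AlleleCountTable:
    """Count allele-assigned pairs per feature for one replicate library.

    ``features`` must be SNP-projected.  A pair assigned to a parent adds 1
    to every feature whose intervals contain a diagnostic SNP it covered
    (gene and exon rows are produced in the same pass); a pair overlapping a
    feature without covering any of its SNPs adds 1 to that feature's
    ambiguous column.  Uninformative features (zero SNPs) keep zero assigned
    counts by construction and are excluded from testing downstream.
    """
    snp_map: dict[tuple[str, int], FixedSnp] = {}
    snp_features: dict[tuple[str, int], list[str]] = defaultdict(list)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for feat in features:
        for snp in feat.snps:
            snp_map[(snp.chrom, snp.pos)] = snp
            snp_features[(snp.chrom, snp.pos)].append(feat.feature_id)
        for s, e in feat.intervals:
            trees[feat.chrom].addi(s, e, feat.feature_id)
    snp_positions: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in snp_map:
        snp_positions[chrom].append(pos)
    for positions in snp_positions.values():
        positions.sort()

    counts: dict[str, list[int]] = {
        feat.feature_id: [0, 0, 0] for feat in features
    }
    col = {"p1": 0, "p2": 1, "ambiguous": 2}
    for name, records in _group_pairs(alignments).items():
        mapped = [r for r in records if r.mapped]
        if not mapped:
            continue
        label, covered = assign_pair(mapped, snp_positions, snp_map)
        if label in ("p1", "p2"):
            targets = set()
            for site in covered:
                targets.update(snp_features[site])
            for fid in targets:
                counts[fid][col[label]] += 1
        else:
            touched: set[str] = set()
            for rec in mapped:
                s, e = rec.reference_span()
                for iv in trees.get(rec.chrom, IntervalTree()).overlap(s, e):
                    touched.add(iv.data)
            for fid in touched:
                counts[fid][2] += 1

    rows = [
        {
            "feature_id": fid,
            "replicate": replicate_id,
            "count_p1": c[0],
            "count_p2": c[1],
            "count_ambiguous": c[2],
        }
        for fid, c in sorted(counts.items())
    ]
    levels = {feat.feature_id: feat.kind for feat in features}
    return AlleleCountTable(pd.DataFrame(rows, columns=_COLUMNS), levels)


# ---------------------------------------------------------------------------
# Residual mapping bias


@dataclass(frozen=True)
class BiasFactor:
    """Per-feature residual mapping bias measured on the simulation grid.

    ``ratio`` (sim parent-1 pairs / sim parent-2 pairs) is the null
    expectation the imbalance tests are shifted by; with a perfect mapper it
    is exactly 1.  ``bias_pct`` is the presentation metric 100*|ratio - 1|;
    features exceeding ``weak_bias_threshold`` percent are flagged, and
    features with no simulated parent-2 pairs are untestable.
    """

    feature_id: str
    sim_count_p1: int
    sim_count_p2: int
    ratio: float
    bias_pct: float
    flagged: bool
    untestable: bool


def estimate_bias(
    sim_counts: AlleleCountTable,
    weak_bias_threshold: float = 5.0,
) -> list[BiasFactor]:
    """Turn grid-simulation counts into per-feature bias factors.

    The default 5% threshold separates weak from strong residual bias.
    """
    pooled = sim_counts.pooled()
    factors: list[BiasFactor] = []
    for row in pooled.itertuples(index=False):
        p1, p2 = int(row.count_p1), int(row.count_p2)
        if p2 == 0:
            factors.append(
                BiasFactor(row.feature_id, p1, p2, float("nan"), float("nan"), False, True)
            )
            continue
        ratio = p1 / p2
        # equal to 100*|ratio - 1| but exact on integer counts
        bias_pct = 100.0 * abs(p1 - p2) / p2
        factors.append(
            BiasFactor(
                row.feature_id,
                p1,
                p2,
                ratio,
                bias_pct,
                bias_pct > weak_bias_threshold,
                False,
            )
        )
    return factors


def bias_frame(factors: Sequence[BiasFactor]) -> pd.DataFrame:
    """Bias factors as a table (feature_id, sim_p1, sim_p2, ratio, flagged)."""
    return pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "sim_p1": f.sim_count_p1,
                "sim_p2": f.sim_count_p2,
                "ratio": f.ratio,
                "bias_pct": f.bias_pct,
                "flagged": f.flagged,
                "untestable": f.untestable,
            }
            for f in factors
        ]
    )
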