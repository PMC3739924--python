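"""Statistical tests for allelic imbalance on bias-corrected allele counts.

Without replication, each feature's pooled parent-1/parent-2 counts are
tested with a likelihood-ratio goodness-of-fit (G) test against a null
proportion shifted by the feature's residual mapping-bias ratio b:
p0 = b/(1+b), G = 2*sum(O*ln(O/E)), chi-square with 1 df.  Because the two
allele counts come from the same library, library size cancels inside the
ratio, so the G-test inherently accounts for it.

With replicates, the per-replicate log2 allele ratios (0.5 pseudocount,
TMM/library-size-adjusted counts, bias subtracted on the log scale) are fit
with an intercept-only linear model; the F statistic on 1 and m-1 degrees
of freedom is the squared one-sample t for a zero mean ratio.  TMM scaling
(trimmed mean of M-values) removes between-library composition effects
before the replicate-level comparison.

Gene-level and exon-level p-values are corrected for multiple testing
separately with the Benjamini-Hochberg step-up, since mixing nested
hypotheses in one family would distort the false discovery rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ase_quantification import AlleleCountTable, BiasFactor, bias_frame

__all__ = [
    "NormalizationFactors",
    "tmm_factors",
    "g_test",
    "anova_test",
    "fdr_correct",
    "run_tests",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-replicate TMM factors and library sizes.

    Factors are strictly positive and rescaled so their geometric mean is 1
    (the usual TMM convention); library size is the total of assigned pairs.
    """

    factors: dict[str, float]
    library_sizes: dict[str, float]

    def effective_size(self, replicate: str) -> float:
        return self.library_sizes[replicate] * self.factors[replicate]


def _choose_reference(matrix: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Reference library: upper quartile of scaled counts closest to the mean."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f75 = np.array(
            [np.quantile(matrix[:, j] / lib_sizes[j], 0.75) for j in range(matrix.shape[1])]
        )
    if np.median(f75) < 1e-20:
        return int(np.argmax(matrix.sum(axis=0)))
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference library.

    Implements the weighted trimmed mean of M-values: genes with zero
    counts in either library are excluded, the top and bottom
    ``logratio_trim`` of M-values and ``sum_trim`` of A-values are trimmed,
    and the remaining M-values are averaged with inverse asymptotic
    binomial-variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2) or np.sum(w[keep2]) <= 0:
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2.0**f)


def tmm_factors(
    count_matrix: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors for a feature x replicate table.

    ``count_matrix`` holds per-feature totals (both alleles summed) with one
    column per replicate.  With fewer than two libraries there is nothing to
    normalize: all factors are 1 and a warning is logged.
    """
    reps = list(count_matrix.columns)
    matrix = count_matrix.to_numpy(dtype=float)
    lib_sizes = matrix.sum(axis=0)
    if len(reps) < 2:
        logger.warning("TMM normalization needs >= 2 libraries; using factors of 1")
        return NormalizationFactors(
            {r: 1.0 for r in reps}, dict(zip(reps, lib_sizes))
        )
    ref_idx = _choose_reference(matrix, lib_sizes)
    raw = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair(
                matrix[:, j],
                matrix[:, ref_idx],
                lib_sizes[j],
                lib_sizes[ref_idx],
                logratio_trim,
                sum_trim,
            )
            for j in range(len(reps))
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(dict(zip(reps, factors)), dict(zip(reps, lib_sizes)))


def g_test(count_p1: int, count_p2: int, bias_ratio: float) -> tuple[float, float]:
    """Bias-corrected G-test of the two allele counts of one feature.

    The null proportion of parent-1 pairs is p0 = b/(1+b) where b is the
    residual-bias ratio, so a feature whose observed ratio equals its bias
    ratio scores G = 0.  G is chi-square with 1 df under the null.
    """
    if not (bias_ratio > 0) or not math.isfinite(bias_ratio):
        raise ValueError(f"bias_ratio must be finite and > 0, got {bias_ratio}")
    n = count_p1 + count_p2
    if n < 1:
        raise ValueError("need at least one assigned pair")
    p0 = bias_ratio / (1.0 + bias_ratio)
    expected = (n * p0, n * (1.0 - p0))
    g = 0.0
    for obs, exp in zip((count_p1, count_p2), expected):
        if obs > 0:
            g += obs * math.log(obs / exp)
    g *= 2.0
    g = max(g, 0.0)
    return g, float(stats.chi2.sf(g, df=1))


def anova_test(
    counts_p1: Sequence[int],
    counts_p2: Sequence[int],
    bias_ratio: float,
    factors: NormalizationFactors | None = None,
    replicate_ids: Sequence[str] | None = None,
) -> tuple[float, float, bool]:
    """Replicate-level test: intercept-only model on log2 allele ratios.

    The response per replicate is log2((c1 + 0.5)/(c2 + 0.5)) on TMM- and
    library-size-adjusted counts, minus log2(bias_ratio).  F = m * ybar^2 /
    s^2 on (1, m-1) df — the squared one-sample t.  Returns (F, p,
    degenerate): zero variance across replicates makes the statistic
    ill-defined, so the limiting p (1 for a zero mean, 0 otherwise) is
    reported with the degenerate flag set.
    """
    if not (bias_ratio > 0) or not math.isfinite(bias_ratio):
        raise ValueError(f"bias_ratio must be finite and > 0, got {bias_ratio}")
    c1 = np.asarray(counts_p1, dtype=float)
    c2 = np.asarray(counts_p2, dtype=float)
    m = c1.size
    if m < 2:
        raise ValueError("ANOVA requires >= 2 replicates; use the pooled G-test")
    if np.any(c1 + c2 < 1):
        raise ValueError("every replicate needs at least one assigned pair")
    if factors is not None:
        if replicate_ids is None:
            raise ValueError("replicate_ids required when factors are given")
        scale = np.array([factors.effective_size(r) for r in replicate_ids])
        scale = scale / np.exp(np.mean(np.log(scale)))
        c1 = c1 / scale
        c2 = c2 / scale
    y = np.log2((c1 + 0.5) / (c2 + 0.5)) - np.log2(bias_ratio)
    ybar = float(np.mean(y))
    s2 = float(np.var(y, ddof=1))
    if np.ptp(y) == 0.0:  # identical responses: variance is zero by design
        s2 = 0.0
    if s2 == 0.0:
        if ybar == 0.0:
            return float("nan"), 1.0, True
        return float("inf"), 0.0, True
    f_stat = m * ybar**2 / s2
    return float(f_stat), float(stats.f.sf(f_stat, 1, m - 1)), False


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def run_tests(
    counts: AlleleCountTable,
    bias: Sequence[BiasFactor],
    mode: str = "pooled",
    min_total: int = 10,
) -> pd.DataFrame:
    """Test every feature for allelic imbalance; one result row per feature.

    Pooled mode sums counts over replicates and applies the G-test;
    replicated mode additionally runs the per-replicate ANOVA on TMM- and
    library-size-adjusted ratios, and the q-value column then derives from
    the ANOVA p-values (the G-test columns remain for reference).  Features
    whose bias is missing/untestable, uninformative features, and features
    with zero assigned pairs are reported as untestable and excluded from
    the FDR families; gene and exon families are corrected separately.
    Features with fewer than ``min_total`` pooled pairs are tested but
    flagged low-coverage.  Results are sorted by q-value within level.
    """
    if mode not in ("pooled", "replicated"):
        raise ValueError(f"mode must be pooled or replicated, got {mode!r}")
    reps = counts.replicate_ids()
    if mode == "replicated" and len(reps) < 2:
        raise ValueError(
            "replicated mode needs >= 2 replicate libraries; use mode='pooled'"
        )
    bias_by_feature = {b.feature_id: b for b in bias}

    frames: list[pd.DataFrame] = []
    for level in ("gene", "exon"):
        table = counts.for_level(level)
        if table.data.empty:
            continue
        pooled = table.pooled()
        factors = None
        per_rep = None
        if mode == "replicated":
            per_rep = table.data.pivot_table(
                index="feature_id", columns="replicate", aggfunc="sum"
            )
            totals = (
                per_rep["count_p1"].fillna(0) + per_rep["count_p2"].fillna(0)
            )
            factors = tmm_factors(totals)
        rows: list[dict] = []
        for row in pooled.itertuples(index=False):
            fid = row.feature_id
            n = int(row.count_p1 + row.count_p2)
            b = bias_by_feature.get(fid)
            rec: dict = {
                "feature_id": fid,
                "level": level,
                "n_replicates": len(reps),
                "count_p1": int(row.count_p1),
                "count_p2": int(row.count_p2),
                "count_ambiguous": int(row.count_ambiguous),
                "bias_ratio": np.nan,
                "corrected_ratio": np.nan,
                "g_statistic": np.nan,
                "g_pvalue": np.nan,
                "anova_f": np.nan,
                "anova_pvalue": np.nan,
                "anova_degenerate": False,
                "testable": False,
                "low_coverage": n < min_total,
            }
            if b is None or b.untestable or not (b.ratio > 0) or n < 1:
                rows.append(rec)
                continue
            rec["bias_ratio"] = b.ratio
            if row.count_p2 > 0:
                rec["corrected_ratio"] = (row.count_p1 / row.count_p2) / b.ratio
            else:
                rec["corrected_ratio"] = np.inf
            g, p_g = g_test(int(row.count_p1), int(row.count_p2), b.ratio)
            rec["g_statistic"], rec["g_pvalue"] = g, p_g
            rec["testable"] = True
            if mode == "replicated":
                c1 = per_rep["count_p1"].loc[fid].fillna(0).to_numpy()
                c2 = per_rep["count_p2"].loc[fid].fillna(0).to_numpy()
                rep_ids = list(per_rep["count_p1"].columns)
                if np.all(c1 + c2 >= 1):
                    f_stat, p_a, degen = anova_test(c1, c2, b.ratio, factors, rep_ids)
                    rec["anova_f"] = f_stat
                    rec["anova_pvalue"] = p_a
                    rec["anova_degenerate"] = degen
            rows.append(rec)
        frame = pd.DataFrame(rows)
        primary = "anova_pvalue" if mode == "replicated" else "g_pvalue"
        frame["q_value"] = np.nan
        frame["g_qvalue"] = np.nan
        testable_g = frame["testable"] & frame["g_pvalue"].notna()
        if testable_g.any():
            frame.loc[testable_g, "g_qvalue"] = fdr_correct(
                frame.loc[testable_g, "g_pvalue"]
            )
        testable_primary = frame["testable"] & frame[primary].notna()
        if testable_primary.any():
            frame.loc[testable_primary, "q_value"] = fdr_correct(
                frame.loc[testable_primary, primary]
            )
        frame = frame.sort_values(
            ["q_value", "feature_id"], na_position="last"
        ).reset_index(drop=True)
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
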