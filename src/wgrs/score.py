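"""Weighted genetic risk score computation, exclusion, categorisation.

The score for one individual is

    wGRS = (N / n) * sum_i W_i * X_i

where the sum runs over the individual's genotyped SNPs, ``W_i = ln(OR_i)``
is the per-allele weight, ``X_i`` in {0, 1, 2} the effect-allele count,
``n`` the number of genotyped SNPs and ``N`` the panel size.  The ``N / n``
factor rescales partially genotyped individuals onto the full-panel scale so
scores remain comparable under missing genotypes.

Individuals genotyped at fewer than ``min_genotyped`` SNPs (default 2) are
excluded before any analysis: a score resting on a single SNP carries no
information about the rest of the panel and breaks the missing-at-random
assumption behind the rescaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io_formats import GenotypeMatrix, WeightPanel

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreResult",
    "CategoryAssignment",
    "DistributionReport",
    "compute_wgrs",
    "score_matrix",
    "filter_low_genotyping",
    "category_thresholds",
    "assign_category",
    "categorize_scores",
    "score_distribution_report",
]


@dataclass(frozen=True)
class ScoreResult:
    sample_id: str
    raw_sum: float
    n_genotyped: int
    scaled_score: float


@dataclass(frozen=True)
class CategoryAssignment:
    sample_id: str
    category: int  # 1..4
    thresholds: tuple[float, float, float]  # (mean - sd, mean, mean + sd)


@dataclass(frozen=True)
class DistributionReport:
    """Two-group comparison of score distributions.

    Levene's test (mean-centred) checks equality of variances; the two-sample
    t-test is pooled-variance when Levene p >= 0.05 and Welch otherwise.
    ``qq_points`` are (theoretical, sample) quantile pairs of the combined
    sample against a normal with matching mean and sd, ready for plotting.
    """

    mean: float
    sd: float
    min: float
    max: float
    mean_a: float
    mean_b: float
    levene_stat: float
    levene_p: float
    t_stat: float
    t_p: float
    equal_var: bool
    qq_points: tuple[tuple[float, float], ...]

    def qq_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.qq_points, columns=["theoretical", "sample"])


def compute_wgrs(sample_counts: pd.Series, panel: WeightPanel, sample_id: str = "") -> ScoreResult:
    """Score one individual from per-SNP effect-allele counts (NaN = missing)."""
    counts = pd.Series(sample_counts, dtype=float).reindex(panel.snp_ids)
    observed = counts.notna()
    n = int(observed.sum())
    if n == 0:
        raise ConfigError(f"sample {sample_id!r}: zero genotyped SNPs, score undefined")
    weights = pd.Series(panel.weights, index=panel.snp_ids)
    raw = float((weights[observed] * counts[observed]).sum())
    scaled = raw / n * panel.panel_size
    return ScoreResult(sample_id=sample_id, raw_sum=raw, n_genotyped=n, scaled_score=scaled)


def score_matrix(matrix: GenotypeMatrix, panel: WeightPanel) -> pd.DataFrame:
    """Vectorised scoring of a whole cohort.

    Returns a frame indexed by sample id with columns ``raw_sum``,
    ``n_genotyped`` and ``scaled_score``.  Samples with zero genotyped SNPs
    raise; run :func:`filter_low_genotyping` first.
    """
    counts = matrix.counts[panel.snp_ids].to_numpy(dtype=float)
    w = panel.weights
    observed = ~np.isnan(counts)
    n = observed.sum(axis=1)
    if (n == 0).any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(n == 0)]
        raise ConfigError(f"samples with zero genotyped SNPs: {bad[:5]}")
    raw = np.nansum(counts * w, axis=1)
    scaled = raw / n * panel.panel_size
    return pd.DataFrame(
        {"raw_sum": raw, "n_genotyped": n.astype(int), "scaled_score": scaled},
        index=matrix.counts.index,
    )


def filter_low_genotyping(
    matrix: GenotypeMatrix, min_genotyped: int = 2
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples genotyped at fewer than ``min_genotyped`` SNPs."""
    if min_genotyped < 1:
        raise ConfigError("min_genotyped must be >= 1")
    n = matrix.n_genotyped()
    excluded = list(n.index[n < min_genotyped])
    logger.info(
        "excluded %d of %d samples genotyped at < %d SNPs",
        len(excluded), len(n), min_genotyped,
    )
    retained = GenotypeMatrix(matrix.counts.drop(index=excluded))
    return retained, excluded


def category_thresholds(reference_scores: Sequence[float]) -> tuple[float, float, float]:
    """(mean - sd, mean, mean + sd) of a reference population, sd with n-1."""
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size < 2:
        raise ConfigError("need at least 2 reference scores for thresholds")
    m = float(ref.mean())
    s = float(ref.std(ddof=1))
    if s == 0.0:
        raise ConfigError("reference scores have zero standard deviation")
    return (m - s, m, m + s)


def assign_category(score: float, thresholds: tuple[float, float, float]) -> int:
    """Map a score to category 1-4 with left-closed upper intervals.

    Intervals are (-inf, m-s), [m-s, m), [m, m+s), [m+s, inf): a score
    exactly on a threshold falls in the upper interval (the mean itself is
    category 3).
    """
    lo, mid, hi = thresholds
    if not (lo < mid < hi):
        raise ConfigError(f"thresholds must be strictly increasing, got {thresholds}")
    if score < lo:
        return 1
    if score < mid:
        return 2
    if score < hi:
        return 3
    return 4


def categorize_scores(
    scores: Sequence[ScoreResult] | pd.Series,
    reference_scores: Sequence[float],
) -> list[CategoryAssignment]:
    """Assign the four mean +/- SD categories against a reference population."""
    thr = category_thresholds(reference_scores)
    if isinstance(scores, pd.Series):
        items = [(str(sid), float(v)) for sid, v in scores.items()]
    else:
        items = [(s.sample_id, s.scaled_score) for s in scores]
    return [
        CategoryAssignment(sample_id=sid, category=assign_category(v, thr), thresholds=thr)
        for sid, v in items
    ]


def score_distribution_report(
    group_a: Sequence[float], group_b: Sequence[float]
) -> DistributionReport:
    """Compare two score distributions (e.g. cases vs controls).

    Q-Q points use the Hazen plotting positions (i - 0.5)/n of the combined
    sample against the normal with the combined mean and sd.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs at least 2 observations")
    lev_stat, lev_p = stats.levene(a, b, center="mean")
    equal_var = bool(lev_p >= 0.05)
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=equal_var)
    combined = np.sort(np.concatenate([a, b]))
    m, s = combined.mean(), combined.std(ddof=1)
    probs = (np.arange(1, combined.size + 1) - 0.5) / combined.size
    theo = stats.norm.ppf(probs, loc=m, scale=s)
    qq = tuple(zip(theo.tolist(), combined.tolist()))
    return DistributionReport(
        mean=float(m),
        sd=float(s),
        min=float(combined[0]),
        max=float(combined[-1]),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        levene_stat=float(lev_stat),
        levene_p=float(lev_p),
        t_stat=float(t_stat),
        t_p=float(t_p),
        equal_var=equal_var,
        qq_points=qq,
    )
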