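"""Mutation-rate normalization, fold changes and contingency tests.

The normalized number of mutations per haploid genome and generation is

    n = ((total_genome / accessible_genome) × accepted_mutations) / generations

i.e. the accepted count is scaled up by the inaccessible fraction of the
genome and divided by the number of treated generations; the per-site rate
is n / total_genome.  Group comparisons use Fisher's exact test on pooled
mutated-versus-accessible-site counts, and methylation contrasts use the
chi-square test with Yates continuity correction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class RateSummary:
    """Normalized mutation burden of one genome or group."""

    label: str
    accepted: int
    accessible_sites: int
    total_genome: int
    generations: int
    n_per_genome: float  # normalized mutations / haploid genome / generation
    per_site_rate: float


def normalize_count(
    total_genome: float, accessible: float, accepted: int, generations: int
) -> float:
    """Normalized mutations per haploid genome per generation (exact)."""
    if accessible <= 0:
        raise ValueError("accessible site count must be positive")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if accessible > total_genome:
        raise ValueError("accessible sites exceed total genome size")
    return (total_genome / accessible) * accepted / generations


def per_site_rate(n: float, genome_size: float) -> float:
    """Per-site per-generation mutation rate, n / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return n / genome_size


def fold_change(a: float, b: float) -> float:
    """Raw rate ratio a/b (display rounding is separate; see display_fold)."""
    if b == 0:
        raise ZeroDivisionError("fold change undefined for zero denominator")
    return a / b


def display_fold(ratio: float) -> float:
    """Fold change at reporting precision: one decimal, half-even."""
    return round(ratio, 1)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to significant digits (used for per-site rates, percentages)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def rate_summary(
    label: str,
    accepted: int,
    accessible_sites: int,
    total_genome: int,
    generations: int = 1,
) -> RateSummary:
    n = normalize_count(total_genome, accessible_sites, accepted, generations)
    return RateSummary(
        label=label,
        accepted=accepted,
        accessible_sites=accessible_sites,
        total_genome=total_genome,
        generations=generations,
        n_per_genome=n,
        per_site_rate=per_site_rate(n, total_genome),
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": s.label,
                "accepted": s.accepted,
                "accessible_sites": s.accessible_sites,
                "total_genome": s.total_genome,
                "generations": s.generations,
                "n_per_genome": s.n_per_genome,
                "per_site_rate": s.per_site_rate,
            }
            for s in summaries
        ]
    )


def fisher_exact(table) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2×2 count table.

    Two-sided p sums hypergeometric probabilities no larger than the
    observed table's.  An empty margin gives p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("empty margin in Fisher table; p = 1", stacklevel=2)
        odds = np.nan
        return odds, 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def chi_square_yates(table) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and p (1 d.f.) for a 2×2 table.

    statistic = Σ (max(|O−E|−0.5, 0))² / E; the correction is capped so it
    never overshoots past the expected value.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    expected = np.outer(rows, cols) / t.sum()
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def compare_groups(
    mutations_a: int,
    accessible_a: int,
    mutations_b: int,
    accessible_b: int,
) -> dict:
    """Fisher contrast of two groups' mutated vs non-mutated accessible sites.

    Table layout: [[mut_A, accessible_A − mut_A], [mut_B, accessible_B −
    mut_B]] on pooled group counts.  The published analysis does not print
    its table construction, so p-values from this contrast are indicative
    rather than exact reproductions.
    """
    table = [
        [mutations_a, accessible_a - mutations_a],
        [mutations_b, accessible_b - mutations_b],
    ]
    odds, p = fisher_exact(table)
    return {"table": table, "odds_ratio": odds, "p_value": p}
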