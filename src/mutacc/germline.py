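"""Developmental timing of mutations and reciprocal-cross analysis.

In a selfing species, a heterozygous mutation present in the meristem
before male and female cell lineages separate segregates 1:2:1 in the
progeny, so among progeny that carry it the expected het:hom ratio is 2:1.
Mutations arising *after* the lineage split reach the progeny through a
single gamete and are always heterozygous.  A mixture with post-split
fraction q therefore shows

    R = (2 + q) / (1 − q)   and inversely   q̂ = (R − 2) / (R + 1),

so an observed het:hom ratio well above 2 indicates predominantly
post-split (late-germline) mutagenesis.  Reciprocal crosses attribute each
inherited mutation to the irradiated mother or father; a homozygous F1
mutation is impossible under outcrossing and flags self-pollination.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rates import fisher_exact

log = logging.getLogger(__name__)

#: Expected het:hom ratio among carriers when every mutation precedes the
#: male/female lineage split (from 1:2:1 Mendelian segregation).
SELFING_RATIO = 2.0


def expected_selfing_ratio() -> float:
    """Analytic pre-split het:hom carrier ratio (2.0)."""
    return SELFING_RATIO


@dataclass
class TimingSummary:
    """Heterozygous/homozygous composition of one group."""

    label: str
    het: float
    hom: float
    ratio: float
    ratio_infinite: bool
    post_split_fraction: float
    below_expectation: bool  # R < 2: q̂ reported as 0 with this flag set
    fisher_vs: dict = field(default_factory=dict)


def het_hom_ratio(het: float, hom: float) -> tuple[float, bool]:
    """Het:hom ratio on normalized per-haploid-genome counts.

    Returns ``(ratio, infinite_flag)``; with zero homozygous mutations the
    ratio is flagged infinite.
    """
    if hom == 0:
        return math.inf, True
    return het / hom, False


def post_split_fraction(ratio: float) -> float:
    """Estimated fraction of mutations arising after the lineage split.

    Inverts R = (2+q)/(1−q); clipped to [0, 1].  R below 2 (sampling noise
    or selection) maps to 0.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if math.isinf(ratio):
        return 1.0
    q = (ratio - 2.0) / (ratio + 1.0)
    return min(max(q, 0.0), 1.0)


def timing_summary(label: str, het: float, hom: float) -> TimingSummary:
    ratio, inf_flag = het_hom_ratio(het, hom)
    q = post_split_fraction(ratio)
    return TimingSummary(
        label=label,
        het=het,
        hom=hom,
        ratio=ratio,
        ratio_infinite=inf_flag,
        post_split_fraction=q,
        below_expectation=(not inf_flag and ratio < SELFING_RATIO),
    )


def compare_timing(groups: list[TimingSummary]) -> list[TimingSummary]:
    """Pairwise Fisher tests of het/hom counts between groups (in place)."""
    for g in groups:
        for other in groups:
            if other is g:
                continue
            _, p = fisher_exact(
                [
                    [int(round(g.het)), int(round(g.hom))],
                    [int(round(other.het)), int(round(other.hom))],
                ]
            )
            g.fisher_vs[other.label] = p
    return groups


def selfing_ratio_from_table(progeny: pd.DataFrame) -> tuple[float, int, int]:
    """Carrier het:hom ratio from a selfing zygosity table.

    ``progeny`` is the long table from ``simulate_selfing`` (zygosity ∈
    {absent, het, hom}); absent rows are non-carriers and drop out.
    """
    carriers = progeny[progeny["zygosity"] != "absent"]
    het = int((carriers["zygosity"] == "het").sum())
    hom = int((carriers["zygosity"] == "hom").sum())
    ratio, _ = het_hom_ratio(het, hom)
    return ratio, het, hom


def bootstrap_post_split_ci(
    per_genome: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bootstrap CI for q̂ over genomes (an extra beyond the published analysis).

    ``per_genome`` needs columns het and hom (per-genome counts); genomes
    are resampled with replacement.
    """
    rng = np.random.default_rng(seed)
    het = per_genome["het"].to_numpy(dtype=float)
    hom = per_genome["hom"].to_numpy(dtype=float)
    qs = []
    for _ in range(n_boot):
        idx = rng.integers(0, het.size, size=het.size)
        h, m = het[idx].sum(), hom[idx].sum()
        ratio, _ = het_hom_ratio(h, m)
        qs.append(post_split_fraction(ratio))
    lo, hi = np.quantile(qs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class CrossAnalysis:
    """Parent-of-origin accounting of reciprocally-crossed F1 genomes."""

    per_genome: pd.DataFrame  # genome_id, irradiated_parent, count, hom_count
    mean_maternal: float
    sd_maternal: float
    mean_paternal: float
    sd_paternal: float
    t_statistic: float
    p_value: float
    selfing_flagged: list[str]


def cross_analysis(f1_records: pd.DataFrame, design: pd.DataFrame) -> CrossAnalysis:
    """Attribute F1 mutation counts to the irradiated parent.

    ``f1_records`` needs columns genome_id and zygosity; ``design`` maps
    genome_id to ``irradiated_parent`` ('mother' or 'father').  Any
    homozygous F1 mutation flags that genome as self-pollinated.  Group
    means are compared with Welch's t-test.
    """
    if "irradiated_parent" not in design.columns or "genome_id" not in design.columns:
        raise ValueError("design needs genome_id and irradiated_parent columns")
    bad = set(design["irradiated_parent"]) - {"mother", "father"}
    if bad:
        raise ValueError(f"unknown irradiated_parent labels: {sorted(bad)}")
    missing = set(f1_records["genome_id"]) - set(design["genome_id"])
    if missing:
        raise ValueError(f"genomes missing from cross design: {sorted(missing)}")

    counts = (
        f1_records.groupby("genome_id")
        .agg(
            count=("zygosity", "size"),
            hom_count=("zygosity", lambda z: int((z == "hom").sum())),
        )
        .reset_index()
    )
    per_genome = design.merge(counts, on="genome_id", how="left").fillna(
        {"count": 0, "hom_count": 0}
    )
    per_genome[["count", "hom_count"]] = per_genome[["count", "hom_count"]].astype(int)
    flagged = per_genome.loc[per_genome["hom_count"] > 0, "genome_id"].tolist()
    if flagged:
        log.warning("homozygous F1 mutations flag self-pollination: %s", flagged)

    mat = per_genome.loc[per_genome["irradiated_parent"] == "mother", "count"]
    pat = per_genome.loc[per_genome["irradiated_parent"] == "father", "count"]
    if len(mat) > 1 and len(pat) > 1:
        t, p = stats.ttest_ind(mat, pat, equal_var=False)
    else:
        t, p = np.nan, np.nan
    return CrossAnalysis(
        per_genome=per_genome,
        mean_maternal=float(mat.mean()) if len(mat) else np.nan,
        sd_maternal=float(mat.std(ddof=1)) if len(mat) > 1 else np.nan,
        mean_paternal=float(pat.mean()) if len(pat) else np.nan,
        sd_paternal=float(pat.std(ddof=1)) if len(pat) > 1 else np.nan,
        t_statistic=float(t),
        p_value=float(p),
        selfing_flagged=flagged,
    )
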