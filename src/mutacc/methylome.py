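"""Methylation calling from replicate profiles and mutation–methylation association.

A cytosine (either strand; plant contexts CG, CHG, CHH with H ∈ {A,T,C})
is called *methylated* when its methylation fraction reaches ≥10% in at
least two biological replicates, counting only replicates with ≥10 reads
at the position; with fewer than two such replicates the position is not
analysed.  These inclusive thresholds are deliberately lenient and give
higher methylation frequencies than stricter published callers.

The association test asks whether G:C→A:T mutations fall on methylated
cytosines more often than the genome-wide methylation frequency predicts,
per context and pooled ("CNN"), using a chi-square test with Yates
correction on methylated/unmethylated counts of mutated versus genomic
positions.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .rates import chi_square_yates

log = logging.getLogger(__name__)

MIN_DEPTH = 10
MIN_FRACTION = 0.10
MIN_REPLICATES = 2

STATUS_METHYLATED = "methylated"
STATUS_UNMETHYLATED = "unmethylated"
STATUS_NOT_ANALYSED = "not-analysed"

CONTEXT_ORDER = ("CG", "CHG", "CHH")


def context_of(seq: str, pos: int, strand: str) -> str:
    """Cytosine context (CG/CHG/CHH) from the two downstream bases.

    ``pos`` is 0-based.  On the minus strand the reference base is G and
    the downstream bases are read 3'→5' on the plus strand, complemented.
    """
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"base at +{pos} is {seq[pos]}, not C")
        if pos + 2 >= len(seq):
            raise ValueError("too close to the contig end for a context")
        n1, n2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"base at -{pos} is {seq[pos]}, not C on minus strand")
        if pos - 2 < 0:
            raise ValueError("too close to the contig start for a context")
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        n1, n2 = comp[seq[pos - 1]], comp[seq[pos - 2]]
    else:
        raise ValueError(f"bad strand {strand!r}")
    if n1 == "G":
        return "CG"
    if n2 == "G":
        return "CHG"
    return "CHH"


def call_methylation(profile: pd.DataFrame) -> pd.Series:
    """Per-cytosine methylation status from a replicate profile table.

    ``profile`` is wide format with columns ``depth_1..k`` / ``frac_1..k``
    (k ≥ 2 replicates).  Replicates with depth < 10 are ignored; a
    position with < 2 qualifying replicates is not analysed; it is
    methylated iff ≥ 2 qualifying replicates have fraction ≥ 0.10.
    """
    depth_cols = sorted(c for c in profile.columns if c.startswith("depth_"))
    frac_cols = sorted(c for c in profile.columns if c.startswith("frac_"))
    if len(depth_cols) < MIN_REPLICATES or len(depth_cols) != len(frac_cols):
        raise ValueError("profile needs >= 2 matched depth_/frac_ replicate columns")
    depth = profile[depth_cols].to_numpy()
    frac = profile[frac_cols].to_numpy()
    qualifying = depth >= MIN_DEPTH
    n_qual = qualifying.sum(axis=1)
    n_meth = (qualifying & (frac >= MIN_FRACTION)).sum(axis=1)
    status = np.where(
        n_qual < MIN_REPLICATES,
        STATUS_NOT_ANALYSED,
        np.where(n_meth >= MIN_REPLICATES, STATUS_METHYLATED, STATUS_UNMETHYLATED),
    )
    return pd.Series(status, index=profile.index, name="status")


def status_table(profile: pd.DataFrame) -> pd.DataFrame:
    """Profile positions with their called status attached."""
    out = profile[["chrom", "pos", "strand", "context"]].copy()
    out["status"] = call_methylation(profile)
    return out


def methylation_overlap(
    records: pd.DataFrame,
    statuses: pd.DataFrame,
    position_base: int = 1,
) -> pd.DataFrame:
    """Mutation/methylation overlap per context, with chi-square tests.

    Only G:C→A:T substitutions at analysable cytosines enter: a C→T record
    is looked up at the plus-strand cytosine at its position, a G→A record
    at the minus-strand cytosine (a C→T on the reverse strand).  The genome
    background is every analysable cytosine, stratified by context and
    pooled as "CNN".  ``records`` positions are 1-based (callers' output)
    unless ``position_base=0``.

    Returns one row per context with mutated/genomic methylated counts,
    overlap percentages, and the Yates-corrected chi-square statistic and
    p-value; contexts with no testable mutations are flagged untestable.
    """
    lookup: dict[tuple[str, int, str], tuple[str, str]] = {}
    for row in statuses.itertuples(index=False):
        lookup[(row.chrom, int(row.pos), row.strand)] = (row.context, row.status)

    gc_at = records[
        ((records["ref_allele"] == "C") & (records["mutant_allele"] == "T"))
        | ((records["ref_allele"] == "G") & (records["mutant_allele"] == "A"))
    ]
    mut_by_ctx: dict[str, list[bool]] = {c: [] for c in CONTEXT_ORDER}
    for row in gc_at.itertuples(index=False):
        strand = "+" if row.ref_allele == "C" else "-"
        pos0 = int(row.position) - position_base
        hit = lookup.get((row.chrom, pos0, strand))
        if hit is None or hit[1] == STATUS_NOT_ANALYSED:
            continue
        ctx, status = hit
        mut_by_ctx[ctx].append(status == STATUS_METHYLATED)

    analysable = statuses[statuses["status"] != STATUS_NOT_ANALYSED]
    rows = []
    for ctx in CONTEXT_ORDER + ("CNN",):
        if ctx == "CNN":
            flags = [f for c in CONTEXT_ORDER for f in mut_by_ctx[c]]
            bg = analysable
        else:
            flags = mut_by_ctx[ctx]
            bg = analysable[analysable["context"] == ctx]
        n_mut = len(flags)
        meth_mut = int(sum(flags))
        n_bg = len(bg)
        meth_bg = int((bg["status"] == STATUS_METHYLATED).sum())
        row = {
            "context": ctx,
            "n_mutations": n_mut,
            "methylated_mutations": meth_mut,
            "overlap_percent": 100.0 * meth_mut / n_mut if n_mut else np.nan,
            "n_genome": n_bg,
            "methylated_genome": meth_bg,
            "genome_percent": 100.0 * meth_bg / n_bg if n_bg else np.nan,
            "testable": n_mut > 0 and n_bg > 0,
            "chi2": np.nan,
            "p_value": np.nan,
        }
        if row["testable"]:
            try:
                stat, p = chi_square_yates(
                    [
                        [meth_mut, n_mut - meth_mut],
                        [meth_bg, n_bg - meth_bg],
                    ]
                )
                row["chi2"], row["p_value"] = stat, p
            except ValueError:
                row["testable"] = False
        else:
            log.info("context %s has no testable mutations", ctx)
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_methylation(
    records: pd.DataFrame, statuses: pd.DataFrame, position_base: int = 1
) -> pd.DataFrame:
    """Fill the ``methylated`` column of a record table from called statuses."""
    lookup = {
        (r.chrom, int(r.pos), r.strand): r.status
        for r in statuses.itertuples(index=False)
    }
    out = records.copy()
    flags = []
    for row in out.itertuples(index=False):
        strand = {"C": "+", "G": "-"}.get(row.ref_allele)
        if strand is None:
            flags.append("n.a.")
            continue
        status = lookup.get((row.chrom, int(row.position) - position_base, strand))
        if status is None or status == STATUS_NOT_ANALYSED:
            flags.append("n.a.")
        else:
            flags.append("TRUE" if status == STATUS_METHYLATED else "FALSE")
    out["methylated"] = flags
    return out
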