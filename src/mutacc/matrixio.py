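"""Per-genome base-count matrices ("genome matrices") and positional accessibility.

A genome matrix records, for every reference position of one re-sequenced
genome, the total read coverage and the individual counts of the six pileup
symbols A, C, G, T, deletion ('-') and N.  It is the only input the mutation
caller consumes: read alignment is upstream of this package and out of scope.

Coordinate conventions
----------------------
Internally everything is 0-based half-open numpy indexing.  Serialised
formats follow their own standards: the matrix TSV dialect and VCF are
1-based inclusive, BED masks are 0-based half-open.

Accessibility
-------------
A position is *accessible* — countable in the denominator of the mutation
rate — iff it is unmasked, covered by at least ``MIN_COVERAGE`` reads and its
focal classification is not 'undefined'.  Positions covered by fewer than 20
reads are low coverage and never analysed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Pileup symbol order used throughout: count columns 0..5 of the per-position
# count block.  'N' is tracked but is never a mutant allele.
ALLELES: tuple[str, ...] = ("A", "C", "G", "T", "-", "N")
ALLELE_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALLELES)}
N_SYMBOLS = len(ALLELES)

#: Positions covered by fewer than this many reads are low coverage.
MIN_COVERAGE = 20

MATRIX_COLUMNS = ["chrom", "pos", "coverage", "A", "C", "G", "T", "del", "N"]

_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODES[ord(_b)] = _i
    _BASE_CODES[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    return _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class MatrixValidationError(ValueError):
    """A matrix row violates the count-sum or coordinate invariants."""


class MaskError(ValueError):
    """A mask interval falls outside its chromosome."""


@dataclass
class GenomeMatrix:
    """Dense per-position coverage and allele counts for one genome.

    ``counts[chrom]`` is an int32 array of shape (L, 7) with columns
    (coverage, A, C, G, T, deletion, N).  ``masked[chrom]`` is a boolean
    array of length L; it is all-False until :func:`apply_mask` is called.
    """

    counts: dict[str, np.ndarray]
    masked: dict[str, np.ndarray] = field(default_factory=dict)
    genome_id: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.counts.items():
            if chrom not in self.masked:
                self.masked[chrom] = np.zeros(arr.shape[0], dtype=bool)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.counts)

    def length(self, chrom: str) -> int:
        return self.counts[chrom].shape[0]

    def validate(self) -> None:
        """Check that allele counts sum to total coverage at every position."""
        for chrom, arr in self.counts.items():
            if (arr < 0).any():
                pos = int(np.argwhere((arr < 0).any(axis=1))[0, 0])
                raise MatrixValidationError(
                    f"negative count at {chrom}:{pos + 1}"
                )
            sums = arr[:, 1:].sum(axis=1)
            bad = np.nonzero(sums != arr[:, 0])[0]
            if bad.size:
                pos = int(bad[0])
                raise MatrixValidationError(
                    f"allele counts sum to {sums[pos]} but coverage is "
                    f"{arr[pos, 0]} at {chrom}:{pos + 1}"
                )

    @classmethod
    def empty(
        cls, lengths: Mapping[str, int], genome_id: str = ""
    ) -> "GenomeMatrix":
        return cls(
            counts={c: np.zeros((n, N_SYMBOLS + 1), dtype=np.int32) for c, n in lengths.items()},
            genome_id=genome_id,
        )


def write_matrix(matrix: GenomeMatrix, path) -> None:
    """Write a genome matrix as the TSV dialect (1-based positions).

    Only covered positions are written; uncovered positions round-trip as
    all-zero rows.
    """
    frames = []
    for chrom, arr in matrix.counts.items():
        covered = np.nonzero(arr[:, 0] > 0)[0]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": covered + 1,
                    "coverage": arr[covered, 0],
                    "A": arr[covered, 1],
                    "C": arr[covered, 2],
                    "G": arr[covered, 3],
                    "T": arr[covered, 4],
                    "del": arr[covered, 5],
                    "N": arr[covered, 6],
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=MATRIX_COLUMNS)
    )
    out.to_csv(path, sep="\t", index=False)


def read_matrix(
    path,
    lengths: Mapping[str, int] | None = None,
    genome_id: str = "",
) -> GenomeMatrix:
    """Read a genome-matrix TSV.

    Parameters
    ----------
    lengths
        Chromosome lengths.  If omitted, each chromosome's length is taken
        as the largest position present (sufficient for round trips, not for
        rate denominators).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=MATRIX_COLUMNS)
    if df.empty:
        warnings.warn(f"matrix file {path} is empty", stacklevel=2)
        log.warning("matrix file %s is empty", path)
        return GenomeMatrix(
            counts={
                c: np.zeros((n, N_SYMBOLS + 1), dtype=np.int32)
                for c, n in (lengths or {}).items()
            },
            genome_id=genome_id,
        )
    missing = [c for c in MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixValidationError(f"matrix {path} lacks columns {missing}")
    num = df[MATRIX_COLUMNS[1:]].apply(pd.to_numeric, errors="coerce")
    bad_rows = num.isna().any(axis=1)
    if bad_rows.any():
        lineno = int(np.nonzero(bad_rows.to_numpy())[0][0]) + 2  # 1 header line
        raise MatrixValidationError(f"malformed matrix row at {path}:{lineno}")
    num = num.astype(np.int64)
    sums = num[["A", "C", "G", "T", "del", "N"]].sum(axis=1)
    bad = sums != num["coverage"]
    if bad.any():
        i = int(np.nonzero(bad.to_numpy())[0][0])
        lineno = i + 2
        raise MatrixValidationError(
            f"allele counts do not sum to coverage at {path}:{lineno} "
            f"({df['chrom'].iloc[i]}:{num['pos'].iloc[i]})"
        )

    if lengths is None:
        lengths = {
            str(c): int(p)
            for c, p in num.groupby(df["chrom"])["pos"].max().items()
        }
    counts = {
        c: np.zeros((n, N_SYMBOLS + 1), dtype=np.int32) for c, n in lengths.items()
    }
    for chrom, sub in num.groupby(df["chrom"].astype(str)):
        if chrom not in counts:
            raise MatrixValidationError(f"unknown chromosome {chrom!r} in {path}")
        idx = sub["pos"].to_numpy() - 1
        if (idx < 0).any() or (idx >= counts[chrom].shape[0]).any():
            raise MatrixValidationError(
                f"position outside chromosome {chrom} bounds in {path}"
            )
        counts[chrom][idx, 0] = sub["coverage"]
        for j, col in enumerate(["A", "C", "G", "T", "del", "N"], start=1):
            counts[chrom][idx, j] = sub[col]
    return GenomeMatrix(counts=counts, genome_id=genome_id)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED3 mask (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start), int(end)))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def apply_mask(
    matrix: GenomeMatrix, mask: Sequence[tuple[str, int, int]]
) -> GenomeMatrix:
    """Flag positions covered by the repeat mask (in place; returns matrix).

    Masked positions are excluded from calling and from accessible-site
    counts.  Intervals are 0-based half-open; overlapping intervals mask
    their union.  Idempotent.
    """
    for chrom, start, end in mask:
        if chrom not in matrix.masked:
            continue
        L = matrix.length(chrom)
        if start < 0 or end > L:
            raise MaskError(
                f"mask interval {chrom}:{start}-{end} outside chromosome "
                f"length {L}"
            )
        matrix.masked[chrom][start:end] = True
    return matrix


# Reason codes for inaccessible positions.
ACCESS_OK = 0
ACCESS_LOW_COVERAGE = 1
ACCESS_MASKED = 2
ACCESS_UNDEFINED = 3

REASON_NAMES = {
    ACCESS_OK: "accessible",
    ACCESS_LOW_COVERAGE: "low-coverage",
    ACCESS_MASKED: "masked",
    ACCESS_UNDEFINED: "undefined",
}


@dataclass
class AccessibilityTrack:
    """Per-position accessibility with the reason for exclusion.

    ``reason[chrom]`` holds one of the ``ACCESS_*`` codes; a position is
    accessible iff its code is ``ACCESS_OK``.
    """

    reason: dict[str, np.ndarray]

    def accessible(self, chrom: str) -> np.ndarray:
        return self.reason[chrom] == ACCESS_OK

    @property
    def accessible_sites(self) -> int:
        return int(sum((r == ACCESS_OK).sum() for r in self.reason.values()))

    @property
    def total_sites(self) -> int:
        return int(sum(r.size for r in self.reason.values()))


def accessibility(
    matrix: GenomeMatrix,
    focal_undefined: Mapping[str, np.ndarray] | None = None,
    min_coverage: int = MIN_COVERAGE,
) -> AccessibilityTrack:
    """Compute the accessibility track and accessible-site count.

    accessible <=> unmasked AND coverage >= ``min_coverage`` AND the focal
    classification is not 'undefined'.  ``focal_undefined`` is a per-chrom
    boolean array from the calling stage; omit it for a coverage/mask-only
    track.  Masking takes precedence over low coverage in the reported
    reason.
    """
    reason: dict[str, np.ndarray] = {}
    for chrom, arr in matrix.counts.items():
        r = np.zeros(arr.shape[0], dtype=np.uint8)
        r[arr[:, 0] < min_coverage] = ACCESS_LOW_COVERAGE
        if focal_undefined is not None:
            undef = focal_undefined[chrom] & (r == ACCESS_OK)
            r[undef] = ACCESS_UNDEFINED
        r[matrix.masked[chrom]] = ACCESS_MASKED
        reason[chrom] = r
    return AccessibilityTrack(reason=reason)
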