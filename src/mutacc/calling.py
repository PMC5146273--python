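"""De novo mutation calling from base-count matrices.

Each position of a focal genome is classified from the frequency of its
strongest non-reference allele:

    frequency        classification
    [0.0, 0.1)       homozygous reference          (accepted as wild type)
    [0.1, 0.3)       putative sequencing error     (not accepted)
    [0.3, 0.8)       heterozygous mutation         (accepted)
    [0.8, 0.9]       undefined                     (not accepted)
    (0.9, 1.0]       homozygous mutation           (accepted)

Positions covered by fewer than 20 reads are low coverage and not
classified; repeat-masked positions are excluded outright.  The interval
endpoints preserve the strict '>0.9' and '<0.1' bounds of the published
threshold table; the touching interior boundaries are resolved
left-closed/right-open.

A candidate variant becomes an accepted *novel* mutation only against a
background cohort of genomes of the same genotype (typically nine; the
parental genome of a later-generation focal sample is excluded first).
Acceptance requires that no background genome shows the same variant, that
none shows a different mutation at the position, that at most one background
genome is undefined, at most three are low-coverage, and at least six are
called homozygous wild type there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrixio import (
    ACCESS_OK,
    ALLELES,
    MIN_COVERAGE,
    AccessibilityTrack,
    GenomeMatrix,
    accessibility,
)

log = logging.getLogger(__name__)

#: Mutant-allele candidates, in tie-break (lexicographic/column) order.
#: 'N' is never a mutant allele.
MUTANT_ALLELES = ("A", "C", "G", "T", "-")


class Cls(IntEnum):
    """Position classification codes."""

    HOM_REF = 0
    HOM_MUT = 1
    HET = 2
    UNDEFINED = 3
    SEQ_ERROR = 4
    LOW_COVERAGE = 5
    MASKED = 6


#: Classifications that make a position a mutation candidate.
ACCEPTED_CLASSES = (Cls.HOM_MUT, Cls.HET)


@dataclass(frozen=True)
class Thresholds:
    """Allele-frequency classification thresholds and the coverage floor.

    Defaults reproduce the published classification table: reference below
    ``hom_ref_max``, sequencing error in [``hom_ref_max``, ``het_min``),
    heterozygous in [``het_min``, ``het_max``), undefined in
    [``het_max``, ``hom_mut_min``], homozygous strictly above
    ``hom_mut_min``.
    """

    hom_ref_max: float = 0.1
    het_min: float = 0.3
    het_max: float = 0.8
    hom_mut_min: float = 0.9
    min_coverage: int = MIN_COVERAGE
    #: Two non-reference alleles at or above this frequency -> undefined.
    multiallelic_min: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.hom_ref_max <= self.het_min <= self.het_max <= self.hom_mut_min <= 1):
            raise ValueError("thresholds must satisfy 0<=ref<=het_min<=het_max<=hom<=1")


DEFAULT_THRESHOLDS = Thresholds()


class NoDataError(ValueError):
    """Raised when a position has zero coverage."""


class CohortError(ValueError):
    """Raised for unusable cohort specifications."""


@dataclass(frozen=True)
class CohortSpec:
    """Focal genome plus its background cohort.

    ``parent_id`` names the focal sample's parent, which is removed from the
    background before filtering (later-generation samples would otherwise
    share true mutations with their parent).
    """

    focal_id: str
    background_ids: tuple[str, ...]
    parent_id: str | None = None

    def effective_background(self) -> tuple[str, ...]:
        bg = tuple(g for g in self.background_ids if g != self.parent_id)
        if self.focal_id in bg:
            raise CohortError(f"focal genome {self.focal_id} in its own background")
        if len(bg) < 6:
            raise CohortError(
                f"only {len(bg)} background genomes after parent exclusion; "
                "need at least 6"
            )
        return bg


@dataclass
class PositionCall:
    """Classification of a single position."""

    classification: Cls
    mutant_allele: str | None
    frequency: float
    coverage: int


@dataclass
class MutationRecord:
    """An accepted de novo mutation.

    ``position`` is 1-based.  ``mutant_allele`` is '-' for deletions, in
    which case ``ref_allele`` holds the full deleted run (1-4 bp).
    Annotation fields (``fraction``, ``coding_effect``, ``context``,
    ``methylated``) are filled by the spectra and methylome stages.
    """

    chrom: str
    position: int
    ref_allele: str
    mutant_allele: str
    zygosity: str  # 'hom' | 'het'
    frequency: float
    coverage: int
    genome_id: str = ""
    genotype: str = ""
    generation: int = 1
    treatment: str = ""
    fraction: str = ""
    coding_effect: str = ""
    context: str = ""
    methylated: str = ""


RECORD_COLUMNS = [
    "chrom", "position", "ref_allele", "mutant_allele", "zygosity",
    "frequency", "coverage", "genome_id", "genotype", "generation",
    "treatment", "fraction", "coding_effect", "context", "methylated",
]


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records],
        columns=RECORD_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Per-position classification
# ---------------------------------------------------------------------------

def mutant_allele_frequency(
    counts: Sequence[int], ref_allele: str
) -> tuple[str | None, float]:
    """Strongest non-reference allele and its frequency at one position.

    ``counts`` is the 7-vector (coverage, A, C, G, T, del, N).  Ties are
    broken toward the lexicographically smaller allele (column order); 'N'
    is never a mutant allele.  Returns ``(None, 0.0)`` when no non-reference
    allele is observed.
    """
    cov = int(counts[0])
    if cov == 0:
        raise NoDataError("no reads at position")
    allele_counts = np.asarray(counts[1:6], dtype=np.int64).copy()
    ref_idx = MUTANT_ALLELES.index(ref_allele) if ref_allele in MUTANT_ALLELES else None
    if ref_idx is not None:
        allele_counts[ref_idx] = -1
    best = int(np.argmax(allele_counts))
    if allele_counts[best] <= 0:
        return None, 0.0
    return MUTANT_ALLELES[best], allele_counts[best] / cov


def classify_position(
    frequency: float,
    coverage: int,
    masked: bool = False,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    multiallelic: bool = False,
) -> Cls:
    """Classify one position from its mutant-allele frequency.

    Masking overrides everything; low coverage overrides the frequency
    intervals; a multiallelic position (two strong non-reference alleles)
    is undefined.
    """
    t = thresholds
    if masked:
        return Cls.MASKED
    if coverage < t.min_coverage:
        return Cls.LOW_COVERAGE
    if multiallelic:
        return Cls.UNDEFINED
    if frequency < t.hom_ref_max:
        return Cls.HOM_REF
    if frequency < t.het_min:
        return Cls.SEQ_ERROR
    if frequency < t.het_max:
        return Cls.HET
    if frequency <= t.hom_mut_min:
        return Cls.UNDEFINED
    return Cls.HOM_MUT


@dataclass
class CallTrack:
    """Vectorised per-position calls for a whole genome."""

    classification: dict[str, np.ndarray]  # uint8 Cls codes
    mutant_allele: dict[str, np.ndarray]  # int8 index into MUTANT_ALLELES, -1 none
    frequency: dict[str, np.ndarray]  # float32

    def undefined_mask(self) -> dict[str, np.ndarray]:
        return {c: a == int(Cls.UNDEFINED) for c, a in self.classification.items()}


def classify_matrix(
    matrix: GenomeMatrix,
    ref_codes: Mapping[str, np.ndarray],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> CallTrack:
    """Classify every position of a genome matrix against the reference.

    ``ref_codes`` maps chromosome to uint8 base codes (A=0..T=3).  Vectorised
    equivalent of :func:`mutant_allele_frequency` + :func:`classify_position`
    at every position.
    """
    t = thresholds
    cls: dict[str, np.ndarray] = {}
    allele: dict[str, np.ndarray] = {}
    freq: dict[str, np.ndarray] = {}
    for chrom, arr in matrix.counts.items():
        codes = ref_codes[chrom]
        L = arr.shape[0]
        cov = arr[:, 0].astype(np.int64)
        counts = arr[:, 1:6].astype(np.int64).copy()  # A C G T del
        rows = np.arange(L)
        valid_ref = codes < 4
        counts[rows[valid_ref], codes[valid_ref]] = -1  # exclude reference allele
        best = counts.argmax(axis=1)  # argmax -> first max -> lexicographic tie-break
        best_count = counts[rows, best]
        safe_cov = np.maximum(cov, 1)
        f = np.where(best_count > 0, best_count / safe_cov, 0.0)
        # multiallelic: >=2 non-reference alleles at >= multiallelic_min
        strong = (counts >= t.multiallelic_min * safe_cov[:, None]) & (counts > 0)
        multi = strong.sum(axis=1) >= 2

        c = np.full(L, int(Cls.HOM_REF), dtype=np.uint8)
        c[f >= t.hom_ref_max] = int(Cls.SEQ_ERROR)
        c[f >= t.het_min] = int(Cls.HET)
        c[f >= t.het_max] = int(Cls.UNDEFINED)
        c[f > t.hom_mut_min] = int(Cls.HOM_MUT)
        c[multi] = int(Cls.UNDEFINED)
        c[cov < t.min_coverage] = int(Cls.LOW_COVERAGE)
        c[matrix.masked[chrom]] = int(Cls.MASKED)

        a = np.where(best_count > 0, best, -1).astype(np.int8)
        cls[chrom] = c
        allele[chrom] = a
        freq[chrom] = f.astype(np.float32)
    return CallTrack(classification=cls, mutant_allele=allele, frequency=freq)


# ---------------------------------------------------------------------------
# Cohort filtering
# ---------------------------------------------------------------------------

#: Rejection reasons, checked in this order.
REASONS = (
    "shared_variant",
    "undefined_background",      # (i)  >1 background undefined
    "different_mutation",        # (ii) another mutation at the position
    "low_coverage_background",   # (iii) >3 backgrounds < 20x
    "insufficient_hom_ref",      # (iv) <6 backgrounds homozygous wild type
)


def accept_novel_mutation(
    focal: PositionCall,
    background: Sequence[PositionCall],
) -> tuple[bool, str]:
    """Apply the background-cohort filter to one candidate position.

    Returns ``(accepted, reason)`` with ``reason`` empty on acceptance and
    the first failing rule's name otherwise.
    """
    if focal.classification not in ACCEPTED_CLASSES:
        raise ValueError("focal position is not a mutation candidate")
    bg_cls = np.array([int(b.classification) for b in background])
    bg_allele = [b.mutant_allele for b in background]
    is_mut = (bg_cls == int(Cls.HET)) | (bg_cls == int(Cls.HOM_MUT))
    shared = any(
        m and a == focal.mutant_allele for m, a in zip(is_mut, bg_allele)
    )
    if shared:
        return False, "shared_variant"
    if (bg_cls == int(Cls.UNDEFINED)).sum() > 1:
        return False, "undefined_background"
    if is_mut.any():
        return False, "different_mutation"
    if (bg_cls == int(Cls.LOW_COVERAGE)).sum() > 3:
        return False, "low_coverage_background"
    if (bg_cls == int(Cls.HOM_REF)).sum() < 6:
        return False, "insufficient_hom_ref"
    return True, ""


def _merge_deletion_runs(records: list[MutationRecord]) -> list[MutationRecord]:
    """Merge accepted deletion calls at adjacent positions into one record.

    Multi-base deletions appear in the matrix as runs of consecutive
    positions whose strongest allele is the deletion symbol; they are
    reported as a single record whose ``ref_allele`` is the deleted run.
    """
    out: list[MutationRecord] = []
    prev: MutationRecord | None = None
    for rec in sorted(records, key=lambda r: (r.chrom, r.position)):
        if (
            prev is not None
            and rec.mutant_allele == "-"
            and prev.mutant_allele == "-"
            and rec.chrom == prev.chrom
            and rec.position == prev.position + len(prev.ref_allele)
            and rec.zygosity == prev.zygosity
        ):
            prev.ref_allele += rec.ref_allele
            prev.frequency = (prev.frequency + rec.frequency) / 2
            continue
        if prev is not None:
            out.append(prev)
        prev = rec
    if prev is not None:
        out.append(prev)
    return out


def call_genome(
    focal: GenomeMatrix,
    ref_codes: Mapping[str, np.ndarray],
    cohort: Mapping[str, GenomeMatrix | CallTrack],
    spec: CohortSpec,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    genotype: str = "",
    generation: int = 1,
    treatment: str = "",
) -> tuple[list[MutationRecord], AccessibilityTrack, dict]:
    """Call novel mutations in one focal genome against its cohort.

    ``cohort`` maps genome id to either a :class:`GenomeMatrix` (classified
    here) or a pre-computed :class:`CallTrack`.  Masks must already be
    applied to all matrices (the cohort is assumed to share the focal
    mask).  Returns sorted records, the focal accessibility track and a
    summary dict with per-reason rejection counts.
    """
    for chrom, arr in focal.counts.items():
        if arr.shape[0] != ref_codes[chrom].shape[0]:
            raise ValueError(
                f"matrix/reference length mismatch on {chrom}: "
                f"{arr.shape[0]} vs {ref_codes[chrom].shape[0]}"
            )
    focal_calls = classify_matrix(focal, ref_codes, thresholds)
    bg_ids = spec.effective_background()
    bg_tracks: list[CallTrack] = []
    for gid in bg_ids:
        obj = cohort[gid]
        bg_tracks.append(
            obj if isinstance(obj, CallTrack) else classify_matrix(obj, ref_codes, thresholds)
        )

    ref_bases = "ACGTN"
    raw: list[MutationRecord] = []
    rejected: dict[str, int] = {r: 0 for r in REASONS}
    for chrom in focal.chromosomes:
        cls = focal_calls.classification[chrom]
        candidates = np.nonzero(
            (cls == int(Cls.HET)) | (cls == int(Cls.HOM_MUT))
        )[0]
        for p in candidates:
            fc = PositionCall(
                classification=Cls(cls[p]),
                mutant_allele=MUTANT_ALLELES[focal_calls.mutant_allele[chrom][p]],
                frequency=float(focal_calls.frequency[chrom][p]),
                coverage=int(focal.counts[chrom][p, 0]),
            )
            bg = [
                PositionCall(
                    classification=Cls(t.classification[chrom][p]),
                    mutant_allele=(
                        MUTANT_ALLELES[t.mutant_allele[chrom][p]]
                        if t.mutant_allele[chrom][p] >= 0
                        else None
                    ),
                    frequency=float(t.frequency[chrom][p]),
                    coverage=0,
                )
                for t in bg_tracks
            ]
            ok, reason = accept_novel_mutation(fc, bg)
            if not ok:
                rejected[reason] += 1
                continue
            code = int(ref_codes[chrom][p])
            raw.append(
                MutationRecord(
                    chrom=chrom,
                    position=int(p) + 1,
                    ref_allele=ref_bases[code] if code < 4 else "N",
                    mutant_allele=fc.mutant_allele,
                    zygosity="hom" if fc.classification is Cls.HOM_MUT else "het",
                    frequency=fc.frequency,
                    coverage=fc.coverage,
                    genome_id=focal.genome_id or spec.focal_id,
                    genotype=genotype,
                    generation=generation,
                    treatment=treatment,
                )
            )
    records = _merge_deletion_runs(raw)
    access = accessibility(
        focal,
        focal_undefined=focal_calls.undefined_mask(),
        min_coverage=thresholds.min_coverage,
    )
    summary = {
        "accepted": len(records),
        "rejected": rejected,
        "accessible_sites": access.accessible_sites,
        "total_sites": access.total_sites,
        "focal_calls": focal_calls,
    }
    log.info(
        "%s: %d accepted, %s rejected, %d/%d accessible",
        spec.focal_id, summary["accepted"], rejected,
        access.accessible_sites, access.total_sites,
    )
    return records, access, summary


# ---------------------------------------------------------------------------
# Caller evaluation against a truth set
# ---------------------------------------------------------------------------

@dataclass
class CallerEvaluation:
    """False-negative/false-positive accounting of a spike-in run."""

    truth_total: int
    truth_accessible: int
    identified: int
    fn_rate: float  # fraction of accessible truth missed
    fp_count: int
    histogram_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    histogram_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def fn_percent(self) -> float:
        return 100.0 * self.fn_rate


def evaluate_caller(
    truth: pd.DataFrame,
    records: Sequence[MutationRecord],
    access: AccessibilityTrack,
    focal_calls: CallTrack | None = None,
    bins: int = 50,
) -> CallerEvaluation:
    """Score called mutations against simulator ground truth.

    ``truth`` needs columns chrom, pos (0-based), mut_allele.  Truth
    mutations at inaccessible sites are excluded from the false-negative
    denominator: rates are normalised over accessible sites, so missing
    them does not bias rate estimates.  A call matches a truth record when
    position and mutant allele agree (deletion records match any position
    of the merged run).  All other calls are false positives.

    When ``focal_calls`` is given, the mutant-allele-frequency histogram
    over all positions with a non-zero mutant allele is attached — the
    distribution whose minimum near 0.3 motivates the heterozygous cutoff.
    """
    called_keys: set[tuple[str, int, str]] = set()
    for r in records:
        if r.mutant_allele == "-":
            for off in range(len(r.ref_allele)):
                called_keys.add((r.chrom, r.position - 1 + off, "-"))
        else:
            called_keys.add((r.chrom, r.position - 1, r.mutant_allele))

    truth_keys: set[tuple[str, int, str]] = set()
    n_accessible = 0
    n_identified = 0
    for row in truth.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.mut_allele)
        truth_keys.add(key)
        if access.reason[row.chrom][int(row.pos)] != ACCESS_OK:
            continue
        n_accessible += 1
        if key in called_keys:
            n_identified += 1
    fp = sum(1 for k in called_keys if k not in truth_keys)
    fn_rate = (
        (n_accessible - n_identified) / n_accessible if n_accessible else 0.0
    )
    edges = np.array([])
    counts = np.array([])
    if focal_calls is not None:
        freqs = np.concatenate(
            [
                f[focal_calls.mutant_allele[c] >= 0]
                for c, f in focal_calls.frequency.items()
            ]
        )
        freqs = freqs[freqs > 0]
        counts, edges = np.histogram(freqs, bins=bins, range=(0.0, 1.0))
    return CallerEvaluation(
        truth_total=len(truth),
        truth_accessible=n_accessible,
        identified=n_identified,
        fn_rate=fn_rate,
        fp_count=fp,
        histogram_edges=edges,
        histogram_counts=counts,
    )


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_vcf(records: Sequence[MutationRecord], reference: Mapping[str, str], path) -> None:
    """Write accepted mutations as minimal VCF v4.2.

    Deletions are left-anchored on the preceding reference base, per VCF
    convention.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity">\n')
        fh.write('##INFO=<ID=GENOME,Number=1,Type=String,Description="Genome id">\n')
        fh.write('##INFO=<ID=GEN,Number=1,Type=Integer,Description="Generation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for r in sorted(records, key=lambda x: (x.chrom, x.position)):
            if r.mutant_allele == "-":
                pos = r.position - 1
                anchor = reference[r.chrom][pos - 1]
                ref, alt = anchor + r.ref_allele, anchor
            else:
                pos = r.position
                ref, alt = r.ref_allele, r.mutant_allele
            gt = "1/1" if r.zygosity == "hom" else "0/1"
            info = f"ZYG={r.zygosity};GENOME={r.genome_id};GEN={r.generation}"
            fh.write(
                f"{r.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gt}\n"
            )


def write_records_tsv(records: Sequence[MutationRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
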