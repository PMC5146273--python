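"""Mutation spectra, genomic fractions, coding effects and context motifs.

Single-base substitutions collapse into six strand-symmetric classes
(G:C→A:T, A:T→G:C, A:T→T:A, G:C→T:A, A:T→C:G, G:C→C:G), so a C→T change and
its complementary G→A change are counted once.  G:C→A:T transitions are the
canonical UV signature (C→T at pyrimidine dimers).

Each mutation is assigned to exactly one genome fraction — gene, transposable
element (TE) or intergenic — with TEs taking precedence over overlapping gene
models (TE sequence is typically methylated in all cytosine contexts), and
TE-genes counted as TEs.  Gene fractions include UTRs and introns; coding
effects are evaluated against CDS models only.

Sequence context is the ±3 bp window around the mutated base, reported on
the pyrimidine strand: a G→A event is re-oriented by reverse complement so
that all G:C→A:T events align in the C→T frame with the mutated base at
offset 0.  Motif matrices score each context column by its relative entropy
(bits) against the genome background (A=T=0.3, C=G=0.2 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

log = logging.getLogger(__name__)

SIX_CLASSES = (
    "G:C>A:T",
    "A:T>G:C",
    "A:T>T:A",
    "G:C>T:A",
    "A:T>C:G",
    "G:C>C:G",
)

FRACTIONS = ("gene", "TE", "intergenic")
FRACTION_CODE = {"intergenic": 0, "gene": 1, "TE": 2}
FRACTION_NAME = {v: k for k, v in FRACTION_CODE.items()}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Default background base probabilities for motif scoring (AT-rich genome).
DEFAULT_BACKGROUND = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_class(ref: str, alt: str) -> str:
    """Map a substitution to its strand-symmetric class label."""
    if ref == alt:
        raise ValueError("reference and mutant allele are identical")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not a base substitution: {ref}>{alt}")
    if ref in "CT":  # normalise to the purine strand
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    pair = {"A": "A:T", "G": "G:C"}[ref]
    target = {"A": "A:T", "C": "C:G", "G": "G:C", "T": "T:A"}[alt]
    return f"{pair}>{target}"


def spectrum_table(
    records: pd.DataFrame, by: Sequence[str] | None = None
) -> pd.DataFrame:
    """Counts and proportions over the six substitution classes.

    Deletions (mutant allele '-') are excluded: the spectrum concerns
    single-nucleotide changes only.  ``by`` optionally stratifies (e.g. by
    treatment or fraction); proportions sum to 1 within each group.
    """
    subs = records[
        records["mutant_allele"].isin(list("ACGT"))
        & records["ref_allele"].isin(list("ACGT"))
    ].copy()
    subs["substitution_class"] = [
        collapse_class(r, a)
        for r, a in zip(subs["ref_allele"], subs["mutant_allele"])
    ]
    keys = (list(by) if by else []) + ["substitution_class"]
    counts = subs.groupby(keys, observed=True).size().rename("count").reset_index()
    # ensure all six classes appear
    if by:
        full = []
        for g, sub in counts.groupby(list(by), observed=True):
            g = g if isinstance(g, tuple) else (g,)
            base = pd.DataFrame({"substitution_class": SIX_CLASSES})
            for k, v in zip(by, g):
                base[k] = v
            full.append(
                base.merge(sub, on=keys, how="left").fillna({"count": 0})
            )
        counts = pd.concat(full, ignore_index=True)
        counts["proportion"] = counts["count"] / counts.groupby(list(by), observed=True)[
            "count"
        ].transform("sum")
    else:
        base = pd.DataFrame({"substitution_class": SIX_CLASSES})
        counts = base.merge(counts, on="substitution_class", how="left").fillna(
            {"count": 0}
        )
        total = counts["count"].sum()
        counts["proportion"] = counts["count"] / total if total else 0.0
    counts["count"] = counts["count"].astype(int)
    return counts


# ---------------------------------------------------------------------------
# Annotation: genome fractions and CDS models
# ---------------------------------------------------------------------------

@dataclass
class CDSModel:
    """Coding-sequence model of one gene (segments in genomic order)."""

    gene_id: str
    chrom: str
    strand: str  # '+' | '-'
    segments: list[tuple[int, int]]  # 0-based half-open

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.segments)
        if total % 3 != 0:
            raise ValueError(
                f"CDS of {self.gene_id} has length {total}, not a multiple of 3"
            )


@dataclass
class Annotation:
    """Resolved per-position fraction labels plus CDS models."""

    fraction: dict[str, np.ndarray]  # uint8 FRACTION_CODE labels
    cds_models: list[CDSModel] = field(default_factory=list)

    def label(self, chrom: str, pos: int) -> str:
        arr = self.fraction[chrom]
        if pos < 0 or pos >= arr.size:
            raise IndexError(f"position {chrom}:{pos} outside reference")
        return FRACTION_NAME[int(arr[pos])]


def resolve_fractions(
    lengths: Mapping[str, int],
    genes: Iterable[tuple[str, int, int]],
    tes: Iterable[tuple[str, int, int]],
) -> dict[str, np.ndarray]:
    """Build per-position fraction labels; TE wins gene/TE overlaps."""
    labels = {c: np.zeros(n, dtype=np.uint8) for c, n in lengths.items()}
    for chrom, s, e in genes:
        labels[chrom][s:e] = FRACTION_CODE["gene"]
    for chrom, s, e in tes:
        labels[chrom][s:e] = FRACTION_CODE["TE"]
    return labels


#: GFF3 feature types counted as TEs ("TE genes" are TEs for this analysis).
TE_FEATURE_TYPES = (
    "transposable_element",
    "transposable_element_gene",
    "transposon_fragment",
)


def load_annotation_gff(path, lengths: Mapping[str, int]) -> Annotation:
    """Load gene/TE/CDS annotation from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes, tes = [], []
    cds_by_gene: dict[str, CDSModel] = {}
    for feat in db.all_features():
        iv = (feat.seqid, feat.start - 1, feat.end)  # GFF is 1-based inclusive
        if feat.featuretype in TE_FEATURE_TYPES:
            tes.append(iv)
        elif feat.featuretype == "gene":
            genes.append(iv)
        elif feat.featuretype == "CDS":
            parent = (feat.attributes.get("Parent") or [feat.id or "cds"])[0]
            model = cds_by_gene.setdefault(
                parent,
                CDSModel.__new__(CDSModel),  # defer length check until complete
            )
            if not hasattr(model, "segments"):
                model.gene_id = parent
                model.chrom = feat.seqid
                model.strand = feat.strand
                model.segments = []
            model.segments.append((feat.start - 1, feat.end))
    models = []
    for m in cds_by_gene.values():
        m.segments.sort()
        m.__post_init__()
        models.append(m)
    return Annotation(
        fraction=resolve_fractions(lengths, genes, tes), cds_models=models
    )


def assign_fraction(chrom: str, pos: int, annotation: Annotation) -> str:
    """Fraction label (gene/TE/intergenic) of a 0-based position."""
    return annotation.label(chrom, pos)


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------

def coding_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    annotation: Annotation,
    sequences: Mapping[str, str],
) -> str:
    """Classify a substitution as synonymous / non-synonymous / noncoding.

    ``pos`` is 0-based.  Deletions are frameshifts and excluded from the
    synonymous/non-synonymous tally.  Stop gain/loss counts as
    non-synonymous.
    """
    if alt == "-":
        return "frameshift"
    for model in annotation.cds_models:
        if model.chrom != chrom:
            continue
        offset = 0
        hit = None
        for s, e in model.segments:
            if s <= pos < e:
                hit = offset + (pos - s)
                break
            offset += e - s
        if hit is None:
            continue
        coding = "".join(sequences[chrom][s:e] for s, e in model.segments)
        total = len(coding)
        if model.strand == "-":
            coding = revcomp(coding)
            hit = total - 1 - hit
            ref_c = ref.translate(_COMPLEMENT)
            alt_c = alt.translate(_COMPLEMENT)
        else:
            ref_c, alt_c = ref, alt
        if coding[hit] != ref_c:
            log.warning(
                "reference base mismatch in CDS %s at %s:%d", model.gene_id,
                chrom, pos + 1,
            )
        codon_i = hit // 3
        within = hit % 3
        codon = list(coding[codon_i * 3 : codon_i * 3 + 3])
        old_aa = str(Seq("".join(codon)).translate())
        codon[within] = alt_c
        new_aa = str(Seq("".join(codon)).translate())
        return "synonymous" if old_aa == new_aa else "non-synonymous"
    return "noncoding"


# ---------------------------------------------------------------------------
# Sequence context
# ---------------------------------------------------------------------------

CONTEXT_FLANK = 3  # three bases up- and downstream


def extract_context(seq: str, pos: int, ref: str) -> str | None:
    """±3 bp context of a substitution, oriented to the pyrimidine strand.

    Returns the 7-mer with the mutated base at offset 0 (index 3).  When the
    reference allele is a purine (G or A) the reverse complement is returned
    so complementary events align — e.g. every G:C→A:T event is expressed in
    the C→T frame.  Returns None within 3 bp of a contig end (such records
    are skipped with a warning upstream).
    """
    if pos < CONTEXT_FLANK or pos + CONTEXT_FLANK >= len(seq):
        return None
    window = seq[pos - CONTEXT_FLANK : pos + CONTEXT_FLANK + 1]
    if ref in "GA":
        return revcomp(window)
    return window


def contexts_of_records(
    records: pd.DataFrame, sequences: Mapping[str, str]
) -> list[str]:
    """Pyrimidine-strand 7-mers for substitution records (edges skipped)."""
    out = []
    skipped = 0
    for row in records.itertuples(index=False):
        if row.mutant_allele not in "ACGT":
            continue
        ctx = extract_context(
            sequences[row.chrom], int(row.position) - 1, row.ref_allele
        )
        if ctx is None:
            skipped += 1
            continue
        out.append(ctx)
    if skipped:
        log.warning("%d records within 3 bp of a contig end skipped", skipped)
    return out


# ---------------------------------------------------------------------------
# Motif scoring
# ---------------------------------------------------------------------------

@dataclass
class MotifMatrix:
    """Per-column base frequencies and relative-entropy scores of a motif.

    ``frequencies`` has shape (7, 4) over positions −3..+3 and bases ACGT.
    ``scores`` is the column information content in bits,
    D_j = Σ_b f_bj · log2(f_bj / p_b); ``heights`` = f_bj · D_j are the
    per-base logo heights.  ``display_heights`` caps the mutated column
    (offset 0) at 1 bit — a figure convention only; stored scores are
    unchanged.
    """

    frequencies: np.ndarray
    scores: np.ndarray
    heights: np.ndarray
    background: dict[str, float]
    n_contexts: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-CONTEXT_FLANK, CONTEXT_FLANK + 1)

    @property
    def display_heights(self) -> np.ndarray:
        h = self.heights.copy()
        centre = CONTEXT_FLANK
        total = h[centre].sum()
        if total > 1.0:
            h[centre] *= 1.0 / total
        return h

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.frequencies, columns=list("ACGT"), index=self.positions
        )
        df.index.name = "offset"
        df["score_bits"] = self.scores
        return df


def motif_scores(
    contexts: Sequence[str],
    background: Mapping[str, float] | None = None,
) -> MotifMatrix:
    """Relative-entropy motif matrix from aligned 7-mer contexts."""
    if not contexts:
        raise ValueError("no contexts supplied")
    bg = dict(background or DEFAULT_BACKGROUND)
    p = np.array([bg[b] for b in "ACGT"])
    width = 2 * CONTEXT_FLANK + 1
    counts = np.zeros((width, 4))
    index = {b: i for i, b in enumerate("ACGT")}
    for ctx in contexts:
        if len(ctx) != width:
            raise ValueError(f"context {ctx!r} is not {width} bp")
        for j, b in enumerate(ctx):
            counts[j, index[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    if not np.allclose(freqs.sum(axis=1), 1.0):
        raise AssertionError("column frequencies do not sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs / p), 0.0)
    scores = terms.sum(axis=1)
    heights = freqs * scores[:, None]
    return MotifMatrix(
        frequencies=freqs,
        scores=scores,
        heights=heights,
        background=bg,
        n_contexts=len(contexts),
    )


def annotate_records(
    records: pd.DataFrame,
    annotation: Annotation,
    sequences: Mapping[str, str],
) -> pd.DataFrame:
    """Fill fraction, coding-effect and context columns of a record table."""
    out = records.copy()
    fractions, effects, ctxs = [], [], []
    for row in out.itertuples(index=False):
        pos = int(row.position) - 1
        fractions.append(annotation.label(row.chrom, pos))
        if row.mutant_allele in "ACGT":
            effects.append(
                coding_effect(
                    row.chrom, pos, row.ref_allele, row.mutant_allele,
                    annotation, sequences,
                )
            )
            ctx = extract_context(sequences[row.chrom], pos, row.ref_allele)
            ctxs.append(ctx or "")
        else:
            effects.append("frameshift")
            ctxs.append("")
    out["fraction"] = fractions
    out["coding_effect"] = effects
    out["context"] = ctxs
    return out


def fraction_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of mutations per genome fraction."""
    counts = records.groupby("fraction", observed=True).size()
    counts = counts.reindex(FRACTIONS, fill_value=0)
    total = counts.sum()
    return pd.DataFrame(
        {
            "fraction": counts.index,
            "count": counts.to_numpy(),
            "proportion": counts.to_numpy() / total if total else 0.0,
        }
    )
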