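"""Synthetic inputs with the statistical structure the analysis assumes.

This module generates everything the caller consumes, desk-scale:

* a diploid reference genome partitioned into genes (with CDS models),
  transposable elements and intergenic sequence, with a low-complexity
  mask and a cytosine methylome in CG/CHG/CHH contexts;
* ground-truth mutation sets — uniform spike-ins for caller validation, a
  UV-B-like process (G:C→A:T dominated, TC(C/T) context preference,
  methyl-cytosine enrichment) and a spontaneous-like process;
* per-position base-count matrices with Poisson sequencing coverage and a
  symmetric per-read-base error model;
* Mendelian inheritance: selfing of a mutation-carrying parent and
  reciprocal crosses, preserving each mutation's developmental origin.

Simulation operates at the pileup-count level: read simulation and
alignment are replaced by direct Poisson-coverage count sampling, which
preserves the downstream contract (the caller only ever sees the genome
matrix).  Default parameters mirror the validation design this package
reproduces: 41× mean coverage, 2% per-base sequencing error, 308
homozygous + 592 heterozygous spiked mutations, and an 88% G:C→A:T share
for the UV-B process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrixio import GenomeMatrix, N_SYMBOLS, encode_bases
from .spectra import CONTEXT_FLANK, FRACTION_NAME, extract_context, resolve_fractions

log = logging.getLogger(__name__)

BASES = "ACGT"
#: Base composition of the synthetic genome (AT-rich, matching the motif
#: background A=T=0.3, C=G=0.2).
BASE_PROBS = np.array([0.3, 0.2, 0.2, 0.3])

CONTEXTS = ("CG", "CHG", "CHH")

#: Default fraction of cytosines methylated per context.  Chosen so that
#: roughly 15% of analysable cytosines are methylated overall — the genome
#: background against which mutation/methylation overlap is tested.
DEFAULT_METHYLATION_RATES = {"CG": 0.45, "CHG": 0.22, "CHH": 0.03}

ORIGIN_PRE_SPLIT = "somatic-pre-split"
ORIGIN_POST_MATERNAL = "post-split-maternal"
ORIGIN_POST_PATERNAL = "post-split-paternal"


class SizingError(ValueError):
    """The genome is too small for the requested annotation or spikes."""


@dataclass
class UVBParams:
    """UV-B-like mutational process parameters.

    ``gc_at_fraction``
        Share of mutations that are G:C→A:T transitions (0.88 under UV-B
        treatment, against ~0.52 spontaneously).
    ``tc_context_weight``
        Multiplier on the sampling weight of cytosines in a TC(C/T)
        context (the dipyrimidine 3'-base preference); 1 disables the
        preference.
    ``methylation_multiplier``
        Multiplier on the weight of methylated cytosines; 1 is the null.
        The default of 2.1 yields ≈27% of mutated cytosines methylated
        against a 15% genome background.
    """

    gc_at_fraction: float = 0.88
    tc_context_weight: float = 8.0
    methylation_multiplier: float = 2.1

    def __post_init__(self) -> None:
        if not 0 <= self.gc_at_fraction <= 1:
            raise ValueError("gc_at_fraction must be in [0,1]")
        if self.tc_context_weight < 0 or self.methylation_multiplier < 0:
            raise ValueError("process multipliers must be >= 0")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults are the validation conditions this package emulates: a 41×
    Poisson sequencing depth, a 2% per-read-base error rate and a 900-site
    spike-in (308 homozygous, 592 heterozygous).
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    gene_fraction: float = 0.3
    te_fraction: float = 0.2
    masked_fraction: float = 0.025  # low-complexity stand-in (~2.95/119 Mb)
    coverage_mean: float = 41.0
    error_rate: float = 0.02
    del_error_rate: float = 0.0  # sub-rate of errors reported as deletions
    n_error_rate: float = 0.0  # sub-rate of errors reported as N
    n_hom: int = 308
    n_het: int = 592
    uvb: UVBParams = field(default_factory=UVBParams)
    methylation_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_METHYLATION_RATES)
    )
    generations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must satisfy 0 <= eps < 0.5")
        if self.coverage_mean <= 0:
            raise ValueError("coverage mean must be positive")
        if self.gene_fraction < 0 or self.te_fraction < 0:
            raise ValueError("fractions must be non-negative")
        if self.gene_fraction + self.te_fraction + self.masked_fraction > 1:
            raise ValueError("gene/TE/mask fractions exceed the genome")
        if isinstance(self.uvb, dict):
            self.uvb = UVBParams(**self.uvb)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Feature:
    """One annotated interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    kind: str  # 'gene' | 'TE'
    strand: str = "+"
    cds: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticReference:
    """Reference genome plus annotation, mask, fractions and methylome.

    ``cyt_context[chrom]`` is a (L, 2) uint8 array over strands (+, −):
    0=CG, 1=CHG, 2=CHH, 255=no cytosine.  ``methylated[chrom]`` is the
    matching boolean array.
    """

    sequences: dict[str, str]
    codes: dict[str, np.ndarray]
    features: list[Feature]
    mask: list[tuple[str, int, int]]
    fraction: dict[str, np.ndarray]
    cyt_context: dict[str, np.ndarray]
    methylated: dict[str, np.ndarray]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def masked_array(self, chrom: str) -> np.ndarray:
        m = np.zeros(len(self.sequences[chrom]), dtype=bool)
        for c, s, e in self.mask:
            if c == chrom:
                m[s:e] = True
        return m

    def fraction_label(self, chrom: str, pos: int) -> str:
        return FRACTION_NAME[int(self.fraction[chrom][pos])]


@dataclass
class TruthSet:
    """Simulator-emitted ground truth mutations.

    Wraps a DataFrame with columns: chrom, pos (0-based), ref_allele,
    mut_allele, zygosity (hom/het), origin, fraction, methylated, context,
    parent_of_origin (crosses only, else '').
    """

    df: pd.DataFrame

    COLUMNS = [
        "chrom", "pos", "ref_allele", "mut_allele", "zygosity", "origin",
        "fraction", "methylated", "context", "parent_of_origin",
    ]

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.df.columns:
                self.df[col] = "" if col != "methylated" else False
        self.df = self.df[self.COLUMNS].reset_index(drop=True)
        dup = self.df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate truth positions")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "TruthSet":
        return cls(pd.DataFrame(columns=cls.COLUMNS))

    @classmethod
    def concat(cls, parts: Sequence["TruthSet"]) -> "TruthSet":
        frames = [p.df for p in parts if len(p)]
        if not frames:
            return cls.empty()
        return cls(pd.concat(frames, ignore_index=True))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}).fillna({"context": "", "parent_of_origin": ""})
        return cls(df)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _layout_features(
    chrom: str, L: int, cfg: SimulationConfig, rng: np.random.Generator
) -> list[Feature]:
    """Tile one chromosome with gene and TE blocks separated by gaps."""
    mean_gene, mean_te = 2000, 1200
    target_gene = cfg.gene_fraction * L
    target_te = cfg.te_fraction * L
    n_gene = int(round(target_gene / mean_gene))
    n_te = int(round(target_te / mean_te))
    if (cfg.gene_fraction > 0 and n_gene == 0) or (cfg.te_fraction > 0 and n_te == 0):
        raise SizingError(
            f"chromosome of {L} bp too small for requested gene/TE fractions"
        )

    def lengths(n: int, target: float, mean: float) -> np.ndarray:
        if n == 0:
            return np.array([], dtype=int)
        raw = rng.normal(mean, mean / 6, size=n).clip(mean / 3, None)
        return np.maximum((raw * (target / raw.sum())).round().astype(int), 30)

    blocks = [("gene", l) for l in lengths(n_gene, target_gene, mean_gene)]
    blocks += [("TE", l) for l in lengths(n_te, target_te, mean_te)]
    rng.shuffle(blocks)
    total_feat = sum(l for _, l in blocks)
    if total_feat >= L:
        raise SizingError(
            f"features ({total_feat} bp) do not fit in chromosome ({L} bp)"
        )
    n_gaps = len(blocks) + 1
    gap_total = L - total_feat
    gaps = rng.multinomial(gap_total, np.full(n_gaps, 1 / n_gaps))
    feats: list[Feature] = []
    pos = int(gaps[0])
    for (kind, length), gap in zip(blocks, gaps[1:]):
        start, end = pos, pos + int(length)
        strand = "+" if rng.random() < 0.5 else "-"
        feat = Feature(chrom, start, end, kind, strand)
        if kind == "gene":
            utr = min(150, (end - start) // 5)
            cs, ce = start + utr, end - utr
            clen = ((ce - cs) // 3) * 3
            if clen >= 3:
                feat.cds = [(cs, cs + clen)]
        feats.append(feat)
        pos = end + int(gap)
    return feats


def _add_gene_te_overlap(
    feats: list[Feature], rng: np.random.Generator
) -> None:
    """Overlay a TE on the tail of one gene so TE-precedence is exercised."""
    for i, f in enumerate(feats):
        if f.kind != "gene" or f.end - f.start < 600:
            continue
        nxt_start = feats[i + 1].start if i + 1 < len(feats) else f.end + 400
        overlap = 200
        te_end = min(f.end + 200, nxt_start)
        feats.insert(
            i + 1, Feature(f.chrom, f.end - overlap, te_end, "TE", "+")
        )
        return
    log.warning("no gene long enough for a gene/TE overlap on this layout")


def _methylome(
    codes: np.ndarray, rates: Mapping[str, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position cytosine contexts and methylation states, both strands."""
    L = codes.size
    ctx = np.full((L, 2), 255, dtype=np.uint8)
    # forward strand: C at i, context from i+1, i+2
    is_c = codes == 1
    nxt1 = np.full(L, 255, dtype=np.uint8)
    nxt2 = np.full(L, 255, dtype=np.uint8)
    nxt1[:-1] = codes[1:]
    nxt2[:-2] = codes[2:]
    fwd = is_c & (nxt1 != 255) & (nxt2 != 255)
    ctx_f = np.where(nxt1 == 2, 0, np.where(nxt2 == 2, 1, 2))
    ctx[fwd, 0] = ctx_f[fwd]
    # reverse strand: G at i (= C on −), context from i-1, i-2
    is_g = codes == 2
    prv1 = np.full(L, 255, dtype=np.uint8)
    prv2 = np.full(L, 255, dtype=np.uint8)
    prv1[1:] = codes[:-1]
    prv2[2:] = codes[:-2]
    rev = is_g & (prv1 != 255) & (prv2 != 255)
    ctx_r = np.where(prv1 == 1, 0, np.where(prv2 == 1, 1, 2))
    ctx[rev, 1] = ctx_r[rev]

    meth = np.zeros((L, 2), dtype=bool)
    rate_arr = np.array([rates["CG"], rates["CHG"], rates["CHH"]])
    for s in (0, 1):
        has = ctx[:, s] != 255
        p = rate_arr[ctx[has, s]]
        meth[has, s] = rng.random(p.size) < p
    return ctx, meth


def generate_reference(config: SimulationConfig) -> SyntheticReference:
    """Generate a synthetic reference genome (deterministic for a seed)."""
    if config.genome_length < 10_000:
        raise SizingError("genome length must be at least 10 kb")
    rng = np.random.default_rng(config.seed)
    names = _chrom_names(config.n_chromosomes)
    per = config.genome_length // config.n_chromosomes
    sequences: dict[str, str] = {}
    codes: dict[str, np.ndarray] = {}
    features: list[Feature] = []
    mask: list[tuple[str, int, int]] = []
    cyt_context: dict[str, np.ndarray] = {}
    methylated: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(names):
        L = per if ci < len(names) - 1 else config.genome_length - per * (len(names) - 1)
        code = rng.choice(4, size=L, p=BASE_PROBS).astype(np.uint8)
        seq = "".join(BASES[b] for b in code) if L < 200_000 else None
        if seq is None:
            seq = np.frombuffer(b"ACGT", dtype=np.uint8)[code].tobytes().decode()
        sequences[chrom] = seq
        codes[chrom] = code
        feats = _layout_features(chrom, L, config, rng)
        if ci == 0 and config.gene_fraction > 0 and config.te_fraction > 0:
            _add_gene_te_overlap(feats, rng)
        features.extend(feats)
        # low-complexity mask: random intervals of ~500 bp
        mask_total = int(config.masked_fraction * L)
        placed = 0
        while placed < mask_total:
            length = min(int(rng.integers(200, 800)), mask_total - placed)
            start = int(rng.integers(0, max(L - length, 1)))
            mask.append((chrom, start, start + length))
            placed += length
        ctx, meth = _methylome(code, config.methylation_rates, rng)
        cyt_context[chrom] = ctx
        methylated[chrom] = meth
    fraction = resolve_fractions(
        {c: len(s) for c, s in sequences.items()},
        [(f.chrom, f.start, f.end) for f in features if f.kind == "gene"],
        [(f.chrom, f.start, f.end) for f in features if f.kind == "TE"],
    )
    return SyntheticReference(
        sequences=sequences,
        codes=codes,
        features=features,
        mask=mask,
        fraction=fraction,
        cyt_context=cyt_context,
        methylated=methylated,
    )


# ---------------------------------------------------------------------------
# Truth-set annotation helpers
# ---------------------------------------------------------------------------

def _annotate_truth(ref: SyntheticReference, df: pd.DataFrame) -> pd.DataFrame:
    """Attach fraction label, methylation flag and pyrimidine context."""
    fractions, meths, ctxs = [], [], []
    for row in df.itertuples(index=False):
        p = int(row.pos)
        fractions.append(ref.fraction_label(row.chrom, p))
        strand = {"C": 0, "G": 1}.get(row.ref_allele)
        meths.append(
            bool(ref.methylated[row.chrom][p, strand]) if strand is not None else False
        )
        ctx = (
            extract_context(ref.sequences[row.chrom], p, row.ref_allele)
            if row.ref_allele in "ACGT"
            else None
        )
        ctxs.append(ctx or "")
    out = df.copy()
    out["fraction"] = fractions
    out["methylated"] = meths
    out["context"] = ctxs
    return out


def _eligible_positions(ref: SyntheticReference, chrom: str) -> np.ndarray:
    """Unmasked positions at least 3 bp from the contig ends."""
    L = len(ref.sequences[chrom])
    ok = ~ref.masked_array(chrom)
    ok[:CONTEXT_FLANK] = False
    ok[L - CONTEXT_FLANK :] = False
    return np.nonzero(ok)[0]


# ---------------------------------------------------------------------------
# Mutational processes
# ---------------------------------------------------------------------------

def spike_mutations(
    ref: SyntheticReference,
    n_hom: int,
    n_het: int,
    seed: int,
    origin: str = ORIGIN_PRE_SPLIT,
) -> TruthSet:
    """Spike uniform random substitutions into unmasked positions.

    Alleles are drawn uniformly from the three non-reference bases;
    positions are unique.  Every record carries its fraction label,
    methylation flag and pyrimidine-strand context.
    """
    n = n_hom + n_het
    if n == 0:
        return TruthSet.empty()
    rng = np.random.default_rng(seed)
    chroms, offsets = [], []
    for chrom in ref.sequences:
        pos = _eligible_positions(ref, chrom)
        chroms.extend([chrom] * pos.size)
        offsets.append(pos)
    flat = np.concatenate(offsets)
    if n > flat.size:
        raise SizingError(
            f"{n} spikes requested but only {flat.size} unmasked positions"
        )
    pick = rng.choice(flat.size, size=n, replace=False)
    chrom_arr = np.array(chroms)[pick]
    pos_arr = flat[pick]
    refs = [
        BASES[ref.codes[c][p]] for c, p in zip(chrom_arr, pos_arr)
    ]
    alts = [
        rng.choice([b for b in BASES if b != r]) for r in refs
    ]
    zyg = np.array(["hom"] * n_hom + ["het"] * n_het)
    rng.shuffle(zyg)
    df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "ref_allele": refs,
            "mut_allele": alts,
            "zygosity": zyg,
            "origin": origin,
        }
    )
    return TruthSet(_annotate_truth(ref, df))


def spike_deletions(
    ref: SyntheticReference, n: int, seed: int, max_len: int = 4,
    zygosity: str = "hom",
) -> TruthSet:
    """Spike 1–4 bp deletions (one truth record per deleted position)."""
    if n == 0:
        return TruthSet.empty()
    rng = np.random.default_rng(seed)
    rows = []
    used: set[tuple[str, int]] = set()
    chrom_list = list(ref.sequences)
    for _ in range(n):
        for _attempt in range(100):
            chrom = chrom_list[rng.integers(len(chrom_list))]
            elig = _eligible_positions(ref, chrom)
            length = int(rng.integers(1, max_len + 1))
            start = int(elig[rng.integers(elig.size)])
            run = [(chrom, start + k) for k in range(length)]
            if any(k in used for k in run):
                continue
            if start + length + CONTEXT_FLANK > len(ref.sequences[chrom]):
                continue
            used.update(run)
            for c, p in run:
                rows.append(
                    {
                        "chrom": c,
                        "pos": p,
                        "ref_allele": ref.sequences[c][p],
                        "mut_allele": "-",
                        "zygosity": zygosity,
                        "origin": ORIGIN_PRE_SPLIT,
                    }
                )
            break
        else:
            raise SizingError("could not place deletion spikes without collision")
    return TruthSet(_annotate_truth(ref, pd.DataFrame(rows)))


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of k items sampled without replacement with prob ∝ weight."""
    # Efraimidis–Spirakis exponential-key trick
    keys = rng.exponential(1.0, size=weights.size) / weights
    return np.argpartition(keys, k)[:k]


def simulate_uvb_process(
    ref: SyntheticReference,
    n: int,
    params: UVBParams,
    seed: int,
    zygosity: str = "het",
    origin: str = ORIGIN_POST_MATERNAL,
) -> TruthSet:
    """Sample n mutations from the UV-B-like process.

    A configured fraction of events are G:C→A:T transitions placed at
    cytosines (either strand) with weight proportional to the TC(C/T)
    context multiplier and the methylation multiplier; the remainder are
    uniformly distributed over the five other substitution classes.
    """
    if n == 0:
        return TruthSet.empty()
    rng = np.random.default_rng(seed)
    n_gc = rng.binomial(n, params.gc_at_fraction)

    # --- eligible cytosines on both strands, with process weights ---
    recs: list[dict] = []
    all_chrom, all_pos, all_strand, all_w = [], [], [], []
    for chrom, codes in ref.codes.items():
        elig = _eligible_positions(ref, chrom)
        masked_ok = np.zeros(codes.size, dtype=bool)
        masked_ok[elig] = True
        for strand, base_code in ((0, 1), (1, 2)):  # (+, C) and (−, G)
            at = np.nonzero((codes == base_code) & masked_ok)[0]
            if at.size == 0:
                continue
            w = np.ones(at.size)
            if strand == 0:
                tc = (codes[at - 1] == 3) & np.isin(codes[at + 1], (1, 3))
            else:
                # pyrimidine strand is −: 5' neighbour is complement of i+1
                tc = (codes[at + 1] == 0) & np.isin(codes[at - 1], (2, 0))
            w[tc] *= params.tc_context_weight
            meth = ref.methylated[chrom][at, strand]
            w[meth] *= params.methylation_multiplier
            all_chrom.extend([chrom] * at.size)
            all_pos.append(at)
            all_strand.append(np.full(at.size, strand))
            all_w.append(w)
    if not all_pos:
        raise SizingError("no eligible cytosines for the UV-B process")
    pos = np.concatenate(all_pos)
    strand = np.concatenate(all_strand)
    weights = np.concatenate(all_w)
    chrom_arr = np.array(all_chrom)
    if weights.sum() == 0 or n_gc > pos.size:
        raise SizingError("not enough eligible cytosines under the context constraint")
    if n_gc > 0:
        idx = _weighted_sample_without_replacement(weights, n_gc, rng)
        for i in idx:
            c, p, s = chrom_arr[i], int(pos[i]), int(strand[i])
            ref_b = "C" if s == 0 else "G"
            alt_b = "T" if s == 0 else "A"
            recs.append(
                {"chrom": c, "pos": p, "ref_allele": ref_b, "mut_allele": alt_b}
            )

    # --- remaining events: other five classes, uniform over eligible sites ---
    other_classes = [
        ("A", "G"), ("A", "T"), ("G", "T"), ("A", "C"), ("G", "C"),
    ]  # purine-strand representatives of the five non-G:C→A:T classes
    used = {(r["chrom"], r["pos"]) for r in recs}
    chrom_list = list(ref.sequences)
    elig_cache = {c: _eligible_positions(ref, c) for c in chrom_list}
    weights_chrom = np.array([elig_cache[c].size for c in chrom_list], dtype=float)
    weights_chrom /= weights_chrom.sum()
    for _ in range(n - n_gc):
        for _attempt in range(1000):
            cls_ref, cls_alt = other_classes[rng.integers(5)]
            c = chrom_list[rng.choice(len(chrom_list), p=weights_chrom)]
            elig = elig_cache[c]
            p = int(elig[rng.integers(elig.size)])
            b = ref.sequences[c][p]
            if b not in (cls_ref, _comp(cls_ref)) or (c, p) in used:
                continue
            alt = cls_alt if b == cls_ref else _comp(cls_alt)
            used.add((c, p))
            recs.append({"chrom": c, "pos": p, "ref_allele": b, "mut_allele": alt})
            break
        else:
            raise SizingError("could not place non-G:C→A:T events")
    df = pd.DataFrame(recs)
    df["zygosity"] = zygosity
    df["origin"] = origin
    return TruthSet(_annotate_truth(ref, df))


def _comp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[b]


def simulate_spontaneous_process(
    ref: SyntheticReference, n: int, seed: int, zygosity: str = "het",
    origin: str = ORIGIN_PRE_SPLIT, gc_at_fraction: float = 0.52,
) -> TruthSet:
    """Spontaneous-like process: ~52% G:C→A:T, no context preference."""
    params = UVBParams(
        gc_at_fraction=gc_at_fraction,
        tc_context_weight=1.0,
        methylation_multiplier=2.1,  # methylation-driven, like spontaneous C→T
    )
    return simulate_uvb_process(ref, n, params, seed, zygosity, origin)


# ---------------------------------------------------------------------------
# Sequencing-count simulation
# ---------------------------------------------------------------------------

def _error_pvals(source: int, del_rate: float, n_rate: float) -> np.ndarray:
    """Error target distribution over count columns (A,C,G,T,del,N)."""
    p = np.zeros(N_SYMBOLS)
    if source < 4:
        others = [b for b in range(4) if b != source]
        for b in others:
            p[b] = (1.0 - del_rate - n_rate) / 3
        p[4] = del_rate
        p[5] = n_rate
    else:  # deletion reads mis-report as a uniform base
        for b in range(4):
            p[b] = (1.0 - n_rate) / 4
        p[5] = n_rate
    return p


def simulate_matrix(
    ref: SyntheticReference,
    truth: TruthSet,
    coverage_mean: float,
    error_rate: float,
    seed: int,
    genome_id: str = "",
    del_error_rate: float = 0.0,
    n_error_rate: float = 0.0,
) -> GenomeMatrix:
    """Simulate a noisy base-count matrix for one genome.

    Coverage is Poisson(λ) per position; each read-base reports the
    genotype allele (homozygous: mutant on both haplotypes; heterozygous:
    mutant with probability 1/2) and is then corrupted to a different
    symbol with probability ε — uniformly over the three other bases, with
    optional sub-rates for deletion and N symbols.
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, np.ndarray] = {}
    allele_codes = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    truth_by_chrom = dict(tuple(truth.df.groupby("chrom"))) if len(truth) else {}
    for chrom, codes in ref.codes.items():
        L = codes.size
        cov = rng.poisson(coverage_mean, size=L).astype(np.int64)
        mut_reads = np.zeros(L, dtype=np.int64)
        mut_allele = np.full(L, -1, dtype=np.int8)
        sub = truth_by_chrom.get(chrom)
        if sub is not None:
            tp = sub["pos"].to_numpy(dtype=np.int64)
            zyg = sub["zygosity"].to_numpy()
            alle = np.array([allele_codes[a] for a in sub["mut_allele"]], dtype=np.int8)
            hom = zyg == "hom"
            mut_reads[tp[hom]] = cov[tp[hom]]
            het_pos = tp[~hom]
            mut_reads[het_pos] = rng.binomial(cov[het_pos], 0.5)
            mut_allele[tp] = alle
        ref_reads = cov - mut_reads

        arr = np.zeros((L, N_SYMBOLS + 1), dtype=np.int64)
        arr[:, 0] = cov

        def scatter(reads: np.ndarray, source_of: np.ndarray) -> None:
            """Distribute reads into columns, applying the error model."""
            if error_rate > 0:
                err = rng.binomial(reads, error_rate)
            else:
                err = np.zeros_like(reads)
            clean = reads - err
            for src in range(5):
                sel = source_of == src
                if not sel.any():
                    continue
                arr[sel, 1 + src] += clean[sel]
                e = err[sel]
                if e.sum() == 0:
                    continue
                pv = _error_pvals(src, del_error_rate, n_error_rate)
                dist = rng.multinomial(e, pv)
                arr[sel, 1:] += dist

        scatter(ref_reads, codes.astype(np.int16))
        at = np.nonzero(mut_reads > 0)[0]
        if at.size:
            sources = np.full(L, -1, dtype=np.int16)
            sources[at] = mut_allele[at]
            mr = np.zeros(L, dtype=np.int64)
            mr[at] = mut_reads[at]
            scatter(mr, sources)
        counts[chrom] = arr.astype(np.int32)
    matrix = GenomeMatrix(counts=counts, genome_id=genome_id)
    return matrix


# ---------------------------------------------------------------------------
# Inheritance
# ---------------------------------------------------------------------------

def simulate_selfing(
    parental: TruthSet, n_progeny: int, seed: int
) -> pd.DataFrame:
    """Self a mutation-carrying parent and genotype each progeny.

    Heterozygous mutations that arose before the split of male and female
    cell lineages segregate 1:2:1 (absent : het : hom); among carriers the
    expected het:hom ratio is 2:1.  Post-split mutations are transmitted
    heterozygous to every assayed progeny (the sequenced progeny descends
    from the affected gamete lineage).  Homozygous parental mutations are
    transmitted homozygous.

    Returns a long table with one row per (progeny, mutation) including
    zygosity 'absent' rows, preserving origin labels for recovery tests.
    """
    rng = np.random.default_rng(seed)
    df = parental.df
    n_mut = len(df)
    frames = []
    pre_het = (
        (df["origin"] == ORIGIN_PRE_SPLIT) & (df["zygosity"] == "het")
    ).to_numpy()
    post = df["origin"].str.startswith("post-split").to_numpy()
    parental_hom = (df["zygosity"] == "hom").to_numpy()
    for j in range(n_progeny):
        zyg = np.empty(n_mut, dtype=object)
        draws = rng.choice(
            np.array(["absent", "het", "hom"]), size=n_mut, p=[0.25, 0.5, 0.25]
        )
        zyg[:] = draws
        zyg[post] = "het"
        zyg[parental_hom & ~post] = "hom"
        # pre-split hom parents transmit hom; pre-split het segregate (drawn)
        frames.append(
            pd.DataFrame(
                {
                    "progeny": f"progeny_{j}",
                    "chrom": df["chrom"],
                    "pos": df["pos"],
                    "ref_allele": df["ref_allele"],
                    "mut_allele": df["mut_allele"],
                    "zygosity": zyg,
                    "origin": df["origin"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_reciprocal_cross(
    mother_truth: TruthSet, father_truth: TruthSet, seed: int = 0
) -> TruthSet:
    """Cross two parents and emit the F1 truth set.

    A homozygous parental mutation is always transmitted; a heterozygous
    one with probability 1/2.  Every transmitted mutation is heterozygous
    in the F1 (the other parent contributes the wild-type allele) and is
    tagged with its parent of origin.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for truth, parent in ((mother_truth, "maternal"), (father_truth, "paternal")):
        df = truth.df
        if not len(df):
            continue
        hom = (df["zygosity"] == "hom").to_numpy()
        keep = hom | (rng.random(len(df)) < 0.5)
        sub = df[keep].copy()
        sub["zygosity"] = "het"
        sub["parent_of_origin"] = parent
        parts.append(sub)
    if not parts:
        return TruthSet.empty()
    out = pd.concat(parts, ignore_index=True)
    # collisions between parents are vanishingly rare; keep first
    out = out.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return TruthSet(out)


# ---------------------------------------------------------------------------
# Methylation profiles
# ---------------------------------------------------------------------------

def emit_methylation_profiles(
    ref: SyntheticReference,
    n_replicates: int = 3,
    depth_mean: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate bisulfite-style profiles consistent with the methylome.

    Methylated cytosines draw per-replicate methylation fractions in
    [0.2, 1.0]; unmethylated ones in [0, 0.05], so re-calling with the
    ≥10-read / ≥10%-in-≥2-replicates rule reproduces the simulated states
    wherever enough replicates pass the depth filter.
    """
    rng = np.random.default_rng(seed)
    rows = {"chrom": [], "pos": [], "strand": [], "context": []}
    meth_flags = []
    for chrom, ctx in ref.cyt_context.items():
        for s, strand in ((0, "+"), (1, "-")):
            at = np.nonzero(ctx[:, s] != 255)[0]
            rows["chrom"].extend([chrom] * at.size)
            rows["pos"].extend(at.tolist())
            rows["strand"].extend([strand] * at.size)
            rows["context"].extend(
                [CONTEXTS[k] for k in ctx[at, s]]
            )
            meth_flags.append(ref.methylated[chrom][at, s])
    df = pd.DataFrame(rows)
    meth = np.concatenate(meth_flags) if meth_flags else np.array([], dtype=bool)
    n = len(df)
    for k in range(1, n_replicates + 1):
        depth = rng.poisson(depth_mean, size=n)
        frac = np.where(
            meth,
            rng.uniform(0.2, 1.0, size=n),
            rng.uniform(0.0, 0.05, size=n),
        )
        df[f"depth_{k}"] = depth
        df[f"frac_{k}"] = frac.round(4)
    return df


# ---------------------------------------------------------------------------
# Writers (FASTA / GFF3 / BED / TSV)
# ---------------------------------------------------------------------------

def write_fasta(ref: SyntheticReference, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ref.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(ref: SyntheticReference, path) -> None:
    """Write the annotation as GFF3 (gene, CDS, transposable_element)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        gi = 0
        for f in ref.features:
            gi += 1
            if f.kind == "gene":
                gid = f"gene{gi}"
                fh.write(
                    f"{f.chrom}\tmutacc\tgene\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={gid}\n"
                )
                for s, e in f.cds:
                    fh.write(
                        f"{f.chrom}\tmutacc\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{f.strand}\t0\tID={gid}.cds;Parent={gid}\n"
                    )
            else:
                fh.write(
                    f"{f.chrom}\tmutacc\ttransposable_element\t{f.start + 1}\t"
                    f"{f.end}\t.\t{f.strand}\t.\tID=te{gi}\n"
                )


def write_methylome_tsv(ref: SyntheticReference, path) -> None:
    rows = {"chrom": [], "pos": [], "strand": [], "context": [], "methylated": []}
    for chrom, ctx in ref.cyt_context.items():
        for s, strand in ((0, "+"), (1, "-")):
            at = np.nonzero(ctx[:, s] != 255)[0]
            rows["chrom"].extend([chrom] * at.size)
            rows["pos"].extend((at + 1).tolist())
            rows["strand"].extend([strand] * at.size)
            rows["context"].extend([CONTEXTS[k] for k in ctx[at, s]])
            rows["methylated"].extend(ref.methylated[chrom][at, s].tolist())
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
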