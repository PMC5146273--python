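"""End-to-end orchestration: simulate → call → annotate → summarize.

Two entry points:

* :func:`run_validation_experiment` reproduces the spike-in validation
  design — spike known mutations into a synthetic reference, simulate
  noisy count matrices for the focal genome and a background cohort, run
  the caller, and score false negatives/positives against the truth set.

* :func:`run_full_analysis` runs the whole analysis on a simulated
  two-group experiment (control vs UV-B-like treatment): calling, rate
  normalization, spectra and motifs, methylation overlap and germline
  timing, with every table written as TSV plus a minimal VCF and a run
  manifest.

Both are deterministic for a fixed seed: all stage seeds derive from the
config seed through a SeedSequence.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    CohortSpec,
    DEFAULT_THRESHOLDS,
    Thresholds,
    call_genome,
    classify_matrix,
    evaluate_caller,
    records_to_frame,
    write_records_tsv,
    write_vcf,
)
from .germline import compare_timing, timing_summary
from .matrixio import apply_mask
from .methylome import methylation_overlap, annotate_methylation, status_table
from .rates import compare_groups, rate_summary, summaries_to_frame
from .simgen import (
    SimulationConfig,
    SyntheticReference,
    TruthSet,
    emit_methylation_profiles,
    generate_reference,
    simulate_matrix,
    simulate_spontaneous_process,
    simulate_uvb_process,
    spike_mutations,
    write_fasta,
    write_gff3,
    write_methylome_tsv,
)
from .matrixio import write_bed
from .spectra import (
    Annotation,
    CDSModel,
    annotate_records,
    contexts_of_records,
    fraction_distribution,
    motif_scores,
    spectrum_table,
)

log = logging.getLogger(__name__)


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent stage seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def annotation_from_reference(ref: SyntheticReference) -> Annotation:
    """Build the spectra-stage annotation directly from a synthetic reference."""
    models = [
        CDSModel(
            gene_id=f"gene_{f.chrom}_{f.start}",
            chrom=f.chrom,
            strand=f.strand,
            segments=list(f.cds),
        )
        for f in ref.features
        if f.kind == "gene" and f.cds
    ]
    return Annotation(fraction=ref.fraction, cds_models=models)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ValidationReport:
    """Outcome of one spike-in validation run."""

    n_spiked: int
    n_hom: int
    n_het: int
    accessible_sites: int
    total_sites: int
    accessible_fraction: float
    truth_accessible: int
    identified: int
    fn_rate: float
    fn_percent: float
    fp_count: int
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    records: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_spiked": self.n_spiked,
            "n_hom": self.n_hom,
            "n_het": self.n_het,
            "accessible_sites": self.accessible_sites,
            "total_sites": self.total_sites,
            "accessible_fraction": self.accessible_fraction,
            "truth_accessible": self.truth_accessible,
            "identified": self.identified,
            "fn_rate": self.fn_rate,
            "fn_percent": self.fn_percent,
            "fp_count": self.fp_count,
        }


def run_validation_experiment(
    config: SimulationConfig,
    n_background: int = 9,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    truth: TruthSet | None = None,
) -> ValidationReport:
    """Spike-in validation: simulate, call, and score against ground truth.

    The focal genome carries ``config.n_hom + config.n_het`` spiked
    mutations; ``n_background`` mutation-free cohort genomes are simulated
    with the same coverage and error model.  Truth mutations falling at
    inaccessible sites are excluded from the false-negative denominator.
    """
    seeds = _stage_seeds(config.seed, 2 + n_background)
    try:
        ref = generate_reference(config)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"reference generation failed: {e}") from e
    if truth is None:
        truth = spike_mutations(ref, config.n_hom, config.n_het, seed=seeds[0])
    try:
        focal = simulate_matrix(
            ref, truth, config.coverage_mean, config.error_rate, seeds[1],
            genome_id="focal", del_error_rate=config.del_error_rate,
            n_error_rate=config.n_error_rate,
        )
        apply_mask(focal, ref.mask)
        cohort = {}
        bg_ids = []
        for i in range(n_background):
            gid = f"bg{i}"
            m = simulate_matrix(
                ref, TruthSet.empty(), config.coverage_mean, config.error_rate,
                seeds[2 + i], genome_id=gid,
                del_error_rate=config.del_error_rate,
                n_error_rate=config.n_error_rate,
            )
            apply_mask(m, ref.mask)
            cohort[gid] = classify_matrix(m, ref.codes, thresholds)
            bg_ids.append(gid)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"matrix simulation failed: {e}") from e
    spec = CohortSpec(focal_id="focal", background_ids=tuple(bg_ids))
    records, access, summary = call_genome(
        focal, ref.codes, cohort, spec, thresholds
    )
    evaluation = evaluate_caller(
        truth.df, records, access, focal_calls=summary["focal_calls"]
    )
    return ValidationReport(
        n_spiked=len(truth),
        n_hom=int((truth.df["zygosity"] == "hom").sum()),
        n_het=int((truth.df["zygosity"] == "het").sum()),
        accessible_sites=access.accessible_sites,
        total_sites=access.total_sites,
        accessible_fraction=access.accessible_sites / access.total_sites,
        truth_accessible=evaluation.truth_accessible,
        identified=evaluation.identified,
        fn_rate=evaluation.fn_rate,
        fn_percent=evaluation.fn_percent,
        fp_count=evaluation.fp_count,
        histogram_edges=evaluation.histogram_edges,
        histogram_counts=evaluation.histogram_counts,
        records=records,
    )


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full simulated analysis run.

    ``post_split_fraction_uvb`` sets the share of UV-B-group mutations
    arising after the germline lineage split (transmitted heterozygous);
    the remainder segregate 1:2:1.  All classification thresholds default
    to the published values; overrides are echoed into the manifest.
    """

    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(genome_length=200_000)
    )
    genomes_per_group: int = 10
    mutations_per_genome_control: int = 25
    mutations_per_genome_uvb: int = 60
    post_split_fraction_control: float = 0.0
    post_split_fraction_uvb: float = 0.67
    include_methylome: bool = True
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _segregated_truth(
    ref: SyntheticReference,
    n: int,
    q_post: float,
    process: str,
    seed: int,
) -> TruthSet:
    """Draw one progeny genome's inherited mutations.

    A fraction ``q_post`` of mutations arose post-split (heterozygous);
    the rest were heterozygous in the meristem and segregate 2:1 het:hom
    among carriers.
    """
    rng = np.random.default_rng(seed)
    if process == "uvb":
        truth = simulate_uvb_process(
            ref, n, SimulationConfig().uvb, seed=int(rng.integers(2**31 - 1))
        )
    else:
        truth = simulate_spontaneous_process(
            ref, n, seed=int(rng.integers(2**31 - 1))
        )
    df = truth.df.copy()
    post = rng.random(len(df)) < q_post
    zyg = np.where(
        post, "het", np.where(rng.random(len(df)) < 2 / 3, "het", "hom")
    )
    df["zygosity"] = zyg
    df["origin"] = np.where(post, "post-split-maternal", "somatic-pre-split")
    return TruthSet(df)


def run_full_analysis(config: RunConfig, outdir) -> dict:
    """Run the whole simulated analysis and write all summary tables.

    Returns a dict of in-memory results (DataFrames and dataclasses); the
    same content lands under ``outdir`` as TSV/VCF/FASTA/GFF3/BED plus a
    ``manifest.yaml`` recording version, seed and thresholds.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.verbosity)
    sim = config.simulation
    seeds = _stage_seeds(config.seed, 4)

    try:
        ref = generate_reference(sim)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"reference stage failed: {e}") from e
    write_fasta(ref, out / "reference.fasta")
    write_gff3(ref, out / "annotation.gff3")
    write_bed(ref.mask, out / "mask.bed")
    write_methylome_tsv(ref, out / "methylome.tsv")
    annotation = annotation_from_reference(ref)

    groups = {
        "control": (
            config.mutations_per_genome_control,
            config.post_split_fraction_control,
            "spontaneous",
        ),
        "uvb": (
            config.mutations_per_genome_uvb,
            config.post_split_fraction_uvb,
            "uvb",
        ),
    }
    all_records: list = []
    summaries = []
    group_counts: dict[str, dict] = {}
    rng = np.random.default_rng(seeds[0])
    for group, (n_mut, q_post, process) in groups.items():
        truths, tracks, matrices = {}, {}, {}
        ids = [f"{group}_{i}" for i in range(config.genomes_per_group)]
        for gid in ids:
            truth = _segregated_truth(
                ref, n_mut, q_post, process, seed=int(rng.integers(2**31 - 1))
            )
            m = simulate_matrix(
                ref, truth, sim.coverage_mean, sim.error_rate,
                seed=int(rng.integers(2**31 - 1)), genome_id=gid,
            )
            apply_mask(m, ref.mask)
            truths[gid] = truth
            matrices[gid] = m
            tracks[gid] = classify_matrix(m, ref.codes, config.thresholds)
        group_mut, group_acc = 0, 0
        for gid in ids:
            spec = CohortSpec(
                focal_id=gid,
                background_ids=tuple(g for g in ids if g != gid),
            )
            records, access, _ = call_genome(
                matrices[gid], ref.codes, tracks, spec, config.thresholds,
                genotype=group, treatment=group,
            )
            all_records.extend(records)
            summaries.append(
                rate_summary(
                    gid, len(records), access.accessible_sites,
                    ref.total_length,
                )
            )
            group_mut += len(records)
            group_acc += access.accessible_sites
        group_counts[group] = {"mutations": group_mut, "accessible": group_acc}
        del matrices, tracks

    records_df = records_to_frame(all_records)
    try:
        records_df = annotate_records(records_df, annotation, ref.sequences)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"spectra stage failed: {e}") from e

    results: dict = {"reference": ref, "records": records_df}

    # rates
    rates_df = summaries_to_frame(summaries)
    comparison = compare_groups(
        group_counts["uvb"]["mutations"],
        group_counts["uvb"]["accessible"],
        group_counts["control"]["mutations"],
        group_counts["control"]["accessible"],
    )
    results["rates"] = rates_df
    results["group_comparison"] = comparison
    rates_df.to_csv(out / "rates.tsv", sep="\t", index=False)
    pd.DataFrame([
        {
            "contrast": "uvb_vs_control",
            "odds_ratio": comparison["odds_ratio"],
            "p_value": comparison["p_value"],
        }
    ]).to_csv(out / "comparisons.tsv", sep="\t", index=False)

    # spectra + fractions + motif
    spect = spectrum_table(records_df, by=["treatment"])
    spect.to_csv(out / "spectra.tsv", sep="\t", index=False)
    results["spectra"] = spect
    frac = fraction_distribution(records_df)
    frac.to_csv(out / "fractions.tsv", sep="\t", index=False)
    results["fractions"] = frac
    uvb_gc_at = records_df[
        (records_df["treatment"] == "uvb")
        & (
            ((records_df["ref_allele"] == "C") & (records_df["mutant_allele"] == "T"))
            | ((records_df["ref_allele"] == "G") & (records_df["mutant_allele"] == "A"))
        )
    ]
    if len(uvb_gc_at):
        motif = motif_scores(contexts_of_records(uvb_gc_at, ref.sequences))
        motif.to_frame().to_csv(out / "motif_uvb.tsv", sep="\t")
        results["motif"] = motif

    # methylation
    if config.include_methylome:
        profiles = emit_methylation_profiles(ref, seed=seeds[1])
        statuses = status_table(profiles)
        records_df = annotate_methylation(records_df, statuses)
        overlap = methylation_overlap(
            records_df[records_df["treatment"] == "uvb"], statuses
        )
        overlap.to_csv(out / "methylation_overlap.tsv", sep="\t", index=False)
        results["methylation_overlap"] = overlap
    else:
        log.warning("methylome stage skipped: no methylome configured")

    # germline timing
    timing = []
    for group in groups:
        sub = records_df[records_df["treatment"] == group]
        timing.append(
            timing_summary(
                group,
                het=int((sub["zygosity"] == "het").sum()),
                hom=int((sub["zygosity"] == "hom").sum()),
            )
        )
    compare_timing(timing)
    timing_df = pd.DataFrame(
        [
            {
                "group": t.label,
                "het": t.het,
                "hom": t.hom,
                "ratio": t.ratio,
                "post_split_fraction": t.post_split_fraction,
                **{f"fisher_p_vs_{k}": v for k, v in t.fisher_vs.items()},
            }
            for t in timing
        ]
    )
    timing_df.to_csv(out / "timing.tsv", sep="\t", index=False)
    results["timing"] = timing_df

    write_records_tsv(all_records, out / "mutations.tsv")
    records_df.to_csv(out / "mutations_annotated.tsv", sep="\t", index=False)
    write_vcf(all_records, ref.sequences, out / "mutations.vcf")

    manifest = {
        "mutacc_version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "simulation": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(sim).items()
        },
        "genomes_per_group": config.genomes_per_group,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    results["manifest"] = manifest
    return results
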