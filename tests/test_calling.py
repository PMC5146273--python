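import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutacc.calling import (
    ACCEPTED_CLASSES,
    Cls,
    CohortSpec,
    CohortError,
    MutationRecord,
    NoDataError,
    PositionCall,
    Thresholds,
    _merge_deletion_runs,
    accept_novel_mutation,
    call_genome,
    classify_matrix,
    classify_position,
    evaluate_caller,
    mutant_allele_frequency,
)
from mutacc.matrixio import GenomeMatrix, apply_mask, encode_bases
from mutacc.simgen import (
    SimulationConfig,
    TruthSet,
    generate_reference,
    simulate_matrix,
    spike_mutations,
)


def _call(cls, allele="T", freq=0.5, cov=40):
    return PositionCall(cls, allele, freq, cov)


class TestMutantAlleleFrequency:
    def test_single_strong_alt(self):
        # ref C, T=29 of 30 reads
        allele, freq = mutant_allele_frequency([30, 0, 1, 0, 29, 0, 0], "C")
        assert allele == "T"
        assert freq == pytest.approx(0.9667, abs=1e-4)

    def test_tie_breaks_to_lexicographically_smaller(self):
        allele, freq = mutant_allele_frequency([40, 10, 20, 0, 10, 0, 0], "C")
        assert allele == "A"
        assert freq == 0.25

    def test_pure_reference_site(self):
        assert mutant_allele_frequency([30, 0, 30, 0, 0, 0, 0], "C") == (None, 0.0)

    def test_n_never_mutant(self):
        allele, _ = mutant_allele_frequency([30, 0, 25, 0, 0, 0, 5], "C")
        assert allele is None

    def test_zero_coverage_raises(self):
        with pytest.raises(NoDataError):
            mutant_allele_frequency([0, 0, 0, 0, 0, 0, 0], "C")


class TestClassifyPosition:
    @pytest.mark.parametrize(
        "freq,cov,expected",
        [
            (0.95, 30, Cls.HOM_MUT),
            (0.5, 40, Cls.HET),
            (0.2, 50, Cls.SEQ_ERROR),
            (0.5, 15, Cls.LOW_COVERAGE),
            (0.05, 40, Cls.HOM_REF),
            # interval boundaries: [0.1,0.3) error, [0.3,0.8) het,
            # [0.8,0.9] undefined, strictly >0.9 hom
            (0.1, 40, Cls.SEQ_ERROR),
            (0.3, 40, Cls.HET),
            (0.8, 40, Cls.UNDEFINED),
            (0.9, 40, Cls.UNDEFINED),
            (0.9000001, 40, Cls.HOM_MUT),
            (1.0, 40, Cls.HOM_MUT),
            (0.0, 40, Cls.HOM_REF),
            (0.5, 19, Cls.LOW_COVERAGE),
            (0.5, 20, Cls.HET),
        ],
    )
    def test_threshold_table(self, freq, cov, expected):
        assert classify_position(freq, cov) is expected

    def test_masked_overrides_everything(self):
        assert classify_position(0.95, 40, masked=True) is Cls.MASKED
        assert classify_position(0.5, 10, masked=True) is Cls.MASKED

    def test_multiallelic_is_undefined(self):
        assert classify_position(0.25, 40, multiallelic=True) is Cls.UNDEFINED

    @given(
        freq=st.floats(min_value=0.0, max_value=1.0),
        cov=st.integers(min_value=20, max_value=200),
    )
    @settings(max_examples=200, deadline=None)
    def test_interval_semantics_property(self, freq, cov):
        got = classify_position(freq, cov)
        if freq < 0.1:
            assert got is Cls.HOM_REF
        elif freq < 0.3:
            assert got is Cls.SEQ_ERROR
        elif freq < 0.8:
            assert got is Cls.HET
        elif freq <= 0.9:
            assert got is Cls.UNDEFINED
        else:
            assert got is Cls.HOM_MUT


class TestCohortFilter:
    def test_clean_background_accepts(self):
        ok, reason = accept_novel_mutation(
            _call(Cls.HET), [_call(Cls.HOM_REF, None, 0.0)] * 9
        )
        assert ok and reason == ""

    def test_shared_variant_rejected(self):
        bg = [_call(Cls.HOM_REF, None, 0.0)] * 8 + [_call(Cls.HET, "T", 0.4)]
        ok, reason = accept_novel_mutation(_call(Cls.HET, "T"), bg)
        assert not ok and reason == "shared_variant"

    def test_two_undefined_rejected(self):
        bg = [_call(Cls.HOM_REF, None, 0.0)] * 7 + [
            _call(Cls.UNDEFINED, "G", 0.85)
        ] * 2
        ok, reason = accept_novel_mutation(_call(Cls.HET, "T"), bg)
        assert not ok and reason == "undefined_background"

    def test_different_mutation_rejected(self):
        bg = [_call(Cls.HOM_REF, None, 0.0)] * 8 + [_call(Cls.HOM_MUT, "G", 0.95)]
        ok, reason = accept_novel_mutation(_call(Cls.HET, "T"), bg)
        assert not ok and reason == "different_mutation"

    def test_four_low_coverage_rejected(self):
        bg = [_call(Cls.HOM_REF, None, 0.0)] * 5 + [
            _call(Cls.LOW_COVERAGE, None, 0.0, 10)
        ] * 4
        ok, reason = accept_novel_mutation(_call(Cls.HET, "T"), bg)
        assert not ok and reason == "low_coverage_background"

    def test_five_hom_ref_rejected(self):
        bg = [_call(Cls.HOM_REF, None, 0.0)] * 5 + [
            _call(Cls.SEQ_ERROR, "G", 0.2)
        ] * 4
        ok, reason = accept_novel_mutation(_call(Cls.HET, "T"), bg)
        assert not ok and reason == "insufficient_hom_ref"

    def test_shared_variant_reported_before_undefined(self):
        bg = (
            [_call(Cls.HOM_REF, None, 0.0)] * 6
            + [_call(Cls.UNDEFINED, "G", 0.85)] * 2
            + [_call(Cls.HET, "T", 0.4)]
        )
        _, reason = accept_novel_mutation(_call(Cls.HET, "T"), bg)
        assert reason == "shared_variant"

    def test_non_candidate_focal_raises(self):
        with pytest.raises(ValueError):
            accept_novel_mutation(_call(Cls.HOM_REF), [])


class TestCohortSpec:
    def test_parent_excluded(self):
        spec = CohortSpec("f", tuple(f"g{i}" for i in range(9)), parent_id="g0")
        assert "g0" not in spec.effective_background()
        assert len(spec.effective_background()) == 8

    def test_too_few_backgrounds_raises(self):
        spec = CohortSpec("f", ("a", "b", "c", "d", "e", "p"), parent_id="p")
        with pytest.raises(CohortError):
            spec.effective_background()

    def test_focal_in_background_raises(self):
        spec = CohortSpec("f", ("f", "a", "b", "c", "d", "e", "g"))
        with pytest.raises(CohortError):
            spec.effective_background()


def _noiseless_cohort(cfg, truth, n_bg=9):
    ref = generate_reference(cfg)
    focal = simulate_matrix(ref, truth, 60.0, 0.0, seed=101, genome_id="focal")
    apply_mask(focal, ref.mask)
    cohort = {}
    for i in range(n_bg):
        m = simulate_matrix(ref, TruthSet.empty(), 60.0, 0.0, seed=200 + i,
                            genome_id=f"bg{i}")
        apply_mask(m, ref.mask)
        cohort[f"bg{i}"] = m
    spec = CohortSpec("focal", tuple(cohort))
    return ref, focal, cohort, spec


class TestCallGenome:
    def test_noiseless_recovery_of_spikes(self):
        cfg = SimulationConfig(genome_length=50_000, seed=11)
        ref = generate_reference(cfg)
        truth = spike_mutations(ref, 8, 12, seed=42)
        ref2, focal, cohort, spec = _noiseless_cohort(cfg, truth)
        records, access, summary = call_genome(focal, ref.codes, cohort, spec)
        got = {(r.chrom, r.position - 1, r.mutant_allele) for r in records}
        want = {
            (t.chrom, int(t.pos), t.mut_allele) for t in truth.df.itertuples()
        }
        assert got == want
        zyg = {(r.chrom, r.position - 1): r.zygosity for r in records}
        for t in truth.df.itertuples():
            assert zyg[(t.chrom, int(t.pos))] == t.zygosity

    def test_focal_also_in_background_yields_nothing(self):
        cfg = SimulationConfig(genome_length=50_000, seed=11)
        ref = generate_reference(cfg)
        truth = spike_mutations(ref, 8, 12, seed=42)
        _, focal, cohort, spec = _noiseless_cohort(cfg, truth, n_bg=8)
        cohort["twin"] = focal  # the same genome as a background
        spec = CohortSpec("focal", tuple(cohort))
        records, _, summary = call_genome(focal, ref.codes, cohort, spec)
        assert records == []
        assert summary["rejected"]["shared_variant"] == 20

    def test_parent_exclusion_recovers_inherited_mutation(self):
        """A generation-2 focal genome shares its true mutations with its
        parent; they are only callable when the parent leaves the cohort."""
        cfg = SimulationConfig(genome_length=50_000, seed=11)
        ref = generate_reference(cfg)
        truth = spike_mutations(ref, 5, 0, seed=9)
        _, focal, cohort, _ = _noiseless_cohort(cfg, truth, n_bg=8)
        parent = simulate_matrix(ref, truth, 60.0, 0.0, seed=999,
                                 genome_id="parent")
        apply_mask(parent, ref.mask)
        cohort["parent"] = parent
        with_parent = CohortSpec("focal", tuple(cohort))
        records, _, _ = call_genome(focal, ref.codes, cohort, with_parent)
        assert records == []
        excluded = CohortSpec("focal", tuple(cohort), parent_id="parent")
        records, _, _ = call_genome(focal, ref.codes, cohort, excluded)
        assert len(records) == 5

    def test_length_mismatch_raises(self):
        m = GenomeMatrix.empty({"chr1": 100})
        codes = {"chr1": encode_bases("A" * 90)}
        spec = CohortSpec("f", tuple(f"g{i}" for i in range(6)))
        with pytest.raises(ValueError, match="mismatch"):
            call_genome(m, codes, {}, spec)


class TestDeletions:
    def test_adjacent_deletion_calls_merge_into_one_record(self):
        recs = [
            MutationRecord("chr1", 10, "A", "-", "hom", 1.0, 40),
            MutationRecord("chr1", 11, "C", "-", "hom", 1.0, 40),
            MutationRecord("chr1", 12, "G", "-", "hom", 1.0, 40),
            MutationRecord("chr1", 50, "T", "-", "hom", 1.0, 40),
            MutationRecord("chr1", 60, "T", "A", "het", 0.5, 40),
        ]
        merged = _merge_deletion_runs(recs)
        assert len(merged) == 3
        run = merged[0]
        assert (run.position, run.ref_allele, run.mutant_allele) == (10, "ACG", "-")

    def test_deletion_called_from_matrix_counts(self):
        """A homozygous 3 bp deletion appears as deletion-column counts at
        three adjacent positions and is reported as one merged record."""
        cfg = SimulationConfig(genome_length=50_000, seed=11)
        ref = generate_reference(cfg)
        # hand-build a deletion run at an unmasked spot
        elig = np.nonzero(~ref.masked_array("chr1"))[0]
        start = int(elig[(elig > 100) & (elig + 3 < 49_000)][0])
        import pandas as pd

        truth = TruthSet(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": [start, start + 1, start + 2],
                    "ref_allele": [ref.sequences["chr1"][start + k] for k in range(3)],
                    "mut_allele": "-",
                    "zygosity": "hom",
                    "origin": "somatic-pre-split",
                }
            )
        )
        _, focal, cohort, spec = _noiseless_cohort(cfg, truth)
        records, _, _ = call_genome(focal, ref.codes, cohort, spec)
        assert len(records) == 1
        rec = records[0]
        assert rec.position == start + 1  # 1-based
        assert len(rec.ref_allele) == 3
        assert rec.mutant_allele == "-"


class TestSeparationAndMonotonicity:
    def test_het_hom_rarely_cross_classify(self):
        """At 41x and 2% error, hom truth essentially never classifies het
        and vice versa (<0.1% crossover)."""
        cfg = SimulationConfig(genome_length=500_000, seed=5)
        ref = generate_reference(cfg)
        truth = spike_mutations(ref, 5000, 5000, seed=6)
        m = simulate_matrix(ref, truth, 41.0, 0.02, seed=7)
        apply_mask(m, ref.mask)
        track = classify_matrix(m, ref.codes)
        cross = 0
        for t in truth.df.itertuples():
            c = track.classification[t.chrom][t.pos]
            if t.zygosity == "hom" and c == int(Cls.HET):
                cross += 1
            if t.zygosity == "het" and c == int(Cls.HOM_MUT):
                cross += 1
        assert cross / len(truth) < 0.001

    def test_lower_error_rate_never_loses_more_truth(self):
        """Pooled over seeds, a much higher error rate misses at least as
        many accessible spikes as a lower one."""
        from mutacc.pipeline import run_validation_experiment

        missed = {}
        for eps in (0.25, 0.02):
            total = 0
            for seed in range(3):
                cfg = SimulationConfig(
                    genome_length=200_000, n_hom=20, n_het=40,
                    error_rate=eps, seed=seed,
                )
                rep = run_validation_experiment(cfg)
                total += rep.truth_accessible - rep.identified
            missed[eps] = total
        assert missed[0.25] >= missed[0.02]


class TestEvaluateCaller:
    def test_perfect_calls_zero_rates(self):
        import pandas as pd

        from mutacc.matrixio import AccessibilityTrack

        truth = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [5, 9], "mut_allele": ["T", "-"]}
        )
        records = [
            MutationRecord("chr1", 6, "C", "T", "het", 0.5, 40),
            MutationRecord("chr1", 10, "A", "-", "hom", 1.0, 40),
        ]
        access = AccessibilityTrack({"chr1": np.zeros(20, dtype=np.uint8)})
        ev = evaluate_caller(truth, records, access)
        assert ev.fn_rate == 0.0
        assert ev.fp_count == 0

    def test_inaccessible_truth_excluded_from_denominator(self):
        import pandas as pd

        from mutacc.matrixio import ACCESS_MASKED, AccessibilityTrack

        truth = pd.DataFrame(
            {"chrom": ["chr1"] * 4, "pos": [1, 2, 3, 4], "mut_allele": list("TTTT")}
        )
        reason = np.zeros(10, dtype=np.uint8)
        reason[3:5] = ACCESS_MASKED
        access = AccessibilityTrack({"chr1": reason})
        records = [MutationRecord("chr1", 2, "C", "T", "het", 0.5, 40)]
        ev = evaluate_caller(truth, records, access)
        assert ev.truth_accessible == 2  # positions 1 and 2 only
        assert ev.identified == 1
        assert ev.fn_rate == pytest.approx(0.5)
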