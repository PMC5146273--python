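import numpy as np
import pandas as pd
import pytest

from mutacc.calling import classify_matrix, Cls
from mutacc.matrixio import apply_mask
from mutacc.simgen import (
    ORIGIN_POST_MATERNAL,
    ORIGIN_PRE_SPLIT,
    SimulationConfig,
    SizingError,
    TruthSet,
    UVBParams,
    emit_methylation_profiles,
    generate_reference,
    simulate_matrix,
    simulate_reciprocal_cross,
    simulate_selfing,
    simulate_uvb_process,
    spike_deletions,
    spike_mutations,
)


class TestGenerateReference:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(genome_length=100_000, seed=7)
        a = generate_reference(cfg)
        b = generate_reference(cfg)
        assert a.sequences == b.sequences
        assert a.mask == b.mask
        for c in a.methylated:
            np.testing.assert_array_equal(a.methylated[c], b.methylated[c])
        assert [f.__dict__ for f in a.features] == [f.__dict__ for f in b.features]

    def test_different_seed_differs(self):
        a = generate_reference(SimulationConfig(genome_length=20_000, seed=1))
        b = generate_reference(SimulationConfig(genome_length=20_000, seed=2))
        assert a.sequences != b.sequences

    def test_zero_te_fraction_emits_no_tes(self):
        cfg = SimulationConfig(genome_length=50_000, te_fraction=0.0, seed=3)
        ref = generate_reference(cfg)
        assert all(f.kind != "TE" for f in ref.features)

    def test_fraction_proportions_near_targets(self, small_reference):
        labels = np.concatenate(list(small_reference.fraction.values()))
        gene = (labels == 1).mean()
        te = (labels == 2).mean()
        assert 0.28 <= gene <= 0.32
        assert 0.18 <= te <= 0.22

    def test_gene_te_overlap_exists(self, small_reference):
        genes = [f for f in small_reference.features if f.kind == "gene"]
        tes = [f for f in small_reference.features if f.kind == "TE"]
        assert any(
            g.chrom == t.chrom and g.start < t.end and t.start < g.end
            for g in genes
            for t in tes
        )

    def test_cds_lengths_multiple_of_three(self, small_reference):
        for f in small_reference.features:
            for s, e in f.cds:
                assert (e - s) % 3 == 0

    def test_methylation_only_at_cytosines(self, small_reference):
        ref = small_reference
        for chrom, code in ref.codes.items():
            meth = ref.methylated[chrom]
            assert not meth[code != 1, 0].any()  # + strand needs C
            assert not meth[code != 2, 1].any()  # − strand needs G

    def test_too_small_genome_raises(self):
        with pytest.raises(SizingError):
            generate_reference(SimulationConfig(genome_length=5_000))

    def test_methylated_background_near_fifteen_percent(self, small_reference):
        ref = small_reference
        tot = m = 0
        for c in ref.cyt_context:
            has = ref.cyt_context[c] != 255
            tot += has.sum()
            m += ref.methylated[c][has].sum()
        assert 0.10 <= m / tot <= 0.20


class TestSpikeMutations:
    def test_spike_counts_and_zygosity(self, small_reference):
        truth = spike_mutations(small_reference, 308, 592, seed=1)
        assert len(truth) == 900
        assert (truth.df["zygosity"] == "hom").sum() == 308
        assert (truth.df["zygosity"] == "het").sum() == 592

    def test_zero_spikes_empty(self, small_reference):
        assert len(spike_mutations(small_reference, 0, 0, seed=1)) == 0

    def test_positions_unique_even_when_dense(self):
        ref = generate_reference(SimulationConfig(genome_length=10_000, seed=2))
        truth = spike_mutations(ref, 10, 490, seed=3)
        keys = list(zip(truth.df["chrom"], truth.df["pos"]))
        assert len(set(keys)) == 500

    def test_alleles_never_reference(self, small_reference):
        truth = spike_mutations(small_reference, 50, 50, seed=4)
        assert (truth.df["ref_allele"] != truth.df["mut_allele"]).all()

    def test_more_spikes_than_positions_raises(self):
        ref = generate_reference(SimulationConfig(genome_length=10_000, seed=2))
        with pytest.raises(SizingError):
            spike_mutations(ref, 9_000, 9_000, seed=5)

    def test_records_annotated(self, small_reference):
        truth = spike_mutations(small_reference, 10, 10, seed=6)
        assert set(truth.df["fraction"]) <= {"gene", "TE", "intergenic"}
        assert truth.df["context"].str.len().eq(7).all()


class TestUVBProcess:
    def test_pure_gc_at_in_tc_context_limit(self, small_reference):
        params = UVBParams(
            gc_at_fraction=1.0, tc_context_weight=1e12, methylation_multiplier=1.0
        )
        truth = simulate_uvb_process(small_reference, 300, params, seed=1)
        assert set(zip(truth.df["ref_allele"], truth.df["mut_allele"])) <= {
            ("C", "T"),
            ("G", "A"),
        }
        # pyrimidine-frame context: T at −1, C/T at +1
        ctx = truth.df["context"]
        assert (ctx.str[2] == "T").all()
        assert ctx.str[4].isin(["C", "T"]).all()

    def test_gc_at_fraction_recovered(self, small_reference):
        truth = simulate_uvb_process(
            small_reference, 2000, UVBParams(), seed=2
        )
        share = (
            truth.df["ref_allele"].isin(["C", "G"])
            & truth.df["mut_allele"].isin(["T", "A"])
        ).mean()
        assert 0.84 <= share <= 0.92

    def test_null_methylation_multiplier(self, small_reference):
        """With multiplier 1 the methylated share of mutated cytosines
        matches the methylated share of eligible cytosines."""
        ref = small_reference
        params = UVBParams(
            gc_at_fraction=1.0, tc_context_weight=1.0, methylation_multiplier=1.0
        )
        truth = simulate_uvb_process(ref, 3000, params, seed=3)
        observed = truth.df["methylated"].mean()
        tot = m = 0
        for c in ref.cyt_context:
            has = ref.cyt_context[c] != 255
            tot += has.sum()
            m += ref.methylated[c][has].sum()
        assert observed == pytest.approx(m / tot, abs=0.03)

    def test_deterministic(self, small_reference):
        a = simulate_uvb_process(small_reference, 100, UVBParams(), seed=9)
        b = simulate_uvb_process(small_reference, 100, UVBParams(), seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestSimulateMatrix:
    def test_noiseless_hom_site_frequency_one(self, small_reference):
        truth = spike_mutations(small_reference, 20, 0, seed=1)
        m = simulate_matrix(small_reference, truth, 40.0, 0.0, seed=2)
        idx = {"A": 1, "C": 2, "G": 3, "T": 4, "-": 5}
        for t in truth.df.itertuples():
            row = m.counts[t.chrom][t.pos]
            assert row[idx[t.mut_allele]] == row[0]

    def test_noiseless_het_mean_frequency_half(self, small_reference):
        truth = spike_mutations(small_reference, 0, 400, seed=3)
        idx = {"A": 1, "C": 2, "G": 3, "T": 4, "-": 5}
        freqs = []
        for seed in range(3):
            m = simulate_matrix(small_reference, truth, 40.0, 0.0, seed=seed)
            for t in truth.df.itertuples():
                row = m.counts[t.chrom][t.pos]
                if row[0]:
                    freqs.append(row[idx[t.mut_allele]] / row[0])
        assert 0.49 <= np.mean(freqs) <= 0.51

    def test_error_rate_reproduced_at_clean_sites(self, small_reference):
        m = simulate_matrix(small_reference, TruthSet.empty(), 41.0, 0.02, seed=4)
        chrom = "chr1"
        arr = m.counts[chrom]
        codes = small_reference.codes[chrom]
        cov = arr[:, 0]
        ref_count = arr[np.arange(arr.shape[0]), 1 + codes]
        ok = cov > 0
        err_frac = 1 - ref_count[ok].sum() / cov[ok].sum()
        assert err_frac == pytest.approx(0.02, abs=0.002)

    def test_coverage_is_poisson_lambda(self, small_reference):
        m = simulate_matrix(small_reference, TruthSet.empty(), 41.0, 0.0, seed=5)
        cov = m.counts["chr1"][:, 0]
        assert cov.mean() == pytest.approx(41.0, rel=0.01)
        assert cov.var() == pytest.approx(41.0, rel=0.05)

    def test_deletion_truth_fills_deletion_column(self, small_reference):
        truth = spike_deletions(small_reference, 5, seed=6)
        m = simulate_matrix(small_reference, truth, 40.0, 0.0, seed=7)
        for t in truth.df.itertuples():
            row = m.counts[t.chrom][t.pos]
            assert row[5] == row[0]  # all reads report the deletion

    def test_counts_sum_to_coverage(self, small_reference):
        truth = spike_mutations(small_reference, 10, 10, seed=8)
        m = simulate_matrix(small_reference, truth, 41.0, 0.02, seed=9)
        m.validate()  # raises on any mismatch


class TestFrequencySeparation:
    def test_het_and_error_frequencies_form_separated_modes(self, small_reference):
        """Simulated het mutant frequencies sit in the accepted band while
        error-driven frequencies stay below the 0.3 cutoff."""
        ref = small_reference
        truth = spike_mutations(ref, 0, 300, seed=10)
        m = simulate_matrix(ref, truth, 41.0, 0.02, seed=11)
        apply_mask(m, ref.mask)
        track = classify_matrix(m, ref.codes)
        truth_pos = {(t.chrom, t.pos) for t in truth.df.itertuples()}
        het_freqs, error_freqs = [], []
        for chrom, f in track.frequency.items():
            nz = np.nonzero(track.mutant_allele[chrom] >= 0)[0]
            for p in nz:
                if (chrom, p) in truth_pos:
                    het_freqs.append(f[p])
                elif f[p] > 0:
                    error_freqs.append(f[p])
        het_freqs = np.array(het_freqs)
        error_freqs = np.array(error_freqs)
        assert (het_freqs >= 0.3).mean() > 0.95
        assert (error_freqs < 0.3).mean() > 0.999


class TestInheritance:
    def test_pre_split_carriers_segregate_two_to_one(self, small_reference):
        truth = spike_mutations(small_reference, 0, 2000, seed=1)
        table = simulate_selfing(truth, n_progeny=5, seed=2)
        carriers = table[table["zygosity"] != "absent"]
        ratio = (carriers["zygosity"] == "het").sum() / (
            carriers["zygosity"] == "hom"
        ).sum()
        assert ratio == pytest.approx(2.0, rel=0.1)
        # genotype draw is 1:2:1 overall
        absent = (table["zygosity"] == "absent").mean()
        assert absent == pytest.approx(0.25, abs=0.02)

    def test_post_split_always_heterozygous(self, small_reference):
        truth = simulate_uvb_process(
            small_reference, 500, UVBParams(), seed=3,
            origin=ORIGIN_POST_MATERNAL,
        )
        table = simulate_selfing(truth, n_progeny=3, seed=4)
        assert (table["zygosity"] == "het").all()

    def test_mixture_ratio_follows_mendelian_algebra(self, small_reference):
        """het:hom among carriers = (2+q)/(1−q), where q is the post-split
        share of the *inherited* mutations (pre-split ones are only carried
        by 3/4 of selfed progeny)."""
        pre = spike_mutations(small_reference, 0, 2000, seed=5)
        post_df = spike_mutations(small_reference, 0, 2000, seed=6).df
        post_df["origin"] = ORIGIN_POST_MATERNAL
        post_df = post_df[~post_df.set_index(["chrom", "pos"]).index.isin(
            pre.df.set_index(["chrom", "pos"]).index
        )]
        truth = TruthSet(pd.concat([pre.df, post_df], ignore_index=True))
        table = simulate_selfing(truth, n_progeny=3, seed=7)
        carriers = table[table["zygosity"] != "absent"]
        q = carriers["origin"].str.startswith("post-split").mean()
        ratio = (carriers["zygosity"] == "het").sum() / (
            carriers["zygosity"] == "hom"
        ).sum()
        assert ratio == pytest.approx((2 + q) / (1 - q), rel=0.1)

    def test_cross_hom_mother_transmits_all_as_het(self, small_reference):
        mother = spike_mutations(small_reference, 10, 0, seed=8)
        f1 = simulate_reciprocal_cross(mother, TruthSet.empty(), seed=9)
        assert len(f1) == 10
        assert (f1.df["zygosity"] == "het").all()
        assert (f1.df["parent_of_origin"] == "maternal").all()

    def test_cross_empty_parents_empty_f1(self):
        f1 = simulate_reciprocal_cross(TruthSet.empty(), TruthSet.empty())
        assert len(f1) == 0

    def test_cross_het_transmission_is_binomial_half(self, small_reference):
        father = spike_mutations(small_reference, 0, 100, seed=10)
        transmitted = [
            len(simulate_reciprocal_cross(TruthSet.empty(), father, seed=s))
            for s in range(40)
        ]
        assert np.mean(transmitted) == pytest.approx(50, abs=3)
        f1 = simulate_reciprocal_cross(TruthSet.empty(), father, seed=1)
        assert (f1.df["parent_of_origin"] == "paternal").all()


class TestMethylationProfiles:
    def test_profiles_cover_all_cytosines(self):
        ref = generate_reference(SimulationConfig(genome_length=10_000, seed=3))
        prof = emit_methylation_profiles(ref, seed=1)
        n_cyt = sum(
            (ref.cyt_context[c] != 255).sum() for c in ref.cyt_context
        )
        assert len(prof) == n_cyt
        assert set(prof["context"]) <= {"CG", "CHG", "CHH"}
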