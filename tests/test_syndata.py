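"""Demography models, the moment engine and the frequency simulator."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fourstrand import syndata
from fourstrand.genodata import PSEUDO_HAPLOID
from fourstrand.syndata import (
    AncestralFreqSpec,
    AdmixtureEvent,
    DemographyModel,
    Edge,
    SamplingSpec,
    build_preset,
    expected_f_moments,
    random_model,
    simulate_frequencies,
    time_to_drift,
)


class TestPreset:
    def test_jones2015_split_times(self, preset_model):
        t = preset_model.node_times
        assert t["south"] == 25_000.0  # CHG vs EF divergence
        assert t["eurasia"] == 45_000.0  # WHG vs (CHG, EF)

    def test_yamnaya_even_mixture_of_chg_and_ehg(self, preset_model):
        (adm,) = preset_model.admixture
        assert adm.alpha == 0.5
        assert {adm.source_a, adm.source_b} == {"chg_src", "ehg_src"}

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="jones2015"):
            build_preset("nosuch")

    def test_preset_validates_and_roundtrips_config(self, preset_model, tmp_path):
        path = tmp_path / "model.yaml"
        syndata.write_model(preset_model, str(path))
        again = syndata.read_model(str(path))
        assert syndata.model_to_config(again) == syndata.model_to_config(preset_model)


class TestTimeToDrift:
    def test_zero_time_is_zero_drift(self):
        assert time_to_drift(0.0, 10_000, 29.0) == 0.0

    def test_two_ne_generations(self):
        # t = 2*Ne generations -> exponent exactly 1
        t = 2 * 10_000 * 29.0
        assert time_to_drift(t, 10_000, 29.0) == pytest.approx(1 - math.exp(-1))

    def test_paper_scale_value(self):
        assert time_to_drift(45_000, 10_000, 29.0) == pytest.approx(0.0746528, abs=1e-6)

    @pytest.mark.parametrize("ne,gen", [(0, 29), (-1, 29), (100, 0)])
    def test_invalid_parameters(self, ne, gen):
        with pytest.raises(ValueError):
            time_to_drift(1000, ne, gen)


class TestMomentEngine:
    def test_two_leaf_f2_closed_form(self):
        # Uniform(0.05, 0.95) root: E[p(1-p)] = 0.5 - 0.3175 = 0.1825,
        # so f2 across two d=0.01 branches is 2 * 0.01 * 0.1825 = 0.00365.
        model = DemographyModel(
            edges=[Edge("root", "A", drift=0.01), Edge("root", "B", drift=0.01)]
        )
        table = expected_f_moments(model)
        assert table.f2("A", "B") == pytest.approx(0.00365, abs=1e-12)

    def test_zero_drift_gives_zero_f_statistics(self):
        model = DemographyModel(
            edges=[Edge("root", "A", drift=0.0), Edge("root", "B", drift=0.0)]
        )
        table = expected_f_moments(model)
        assert table.f2("A", "B") == pytest.approx(0.0, abs=1e-15)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_moment_table_invariants(self, seed):
        table = expected_f_moments(random_model(seed))
        assert np.allclose(table.m2, table.m2.T)
        assert (table.m2 >= -1e-12).all() and (table.m2 <= 1 + 1e-12).all()
        # Cauchy-Schwarz-style bound: E[p^2] >= E[p]^2
        assert (np.diag(table.m2) >= table.m1**2 - 1e-12).all()

    def test_admixture_linearity_exact(self, preset_model):
        # Yamnaya = 0.5 chg_src + 0.5 ehg_src; f4 involves only cross
        # moments, so it is exactly linear in the sources even though
        # Yamnaya drifts after the admixture event.
        t = expected_f_moments(preset_model)
        lhs = t.f4("Outgroup", "Satsurblia", "Kotias", "Yamnaya")
        rhs = 0.5 * t.f4("Outgroup", "Satsurblia", "Kotias", "chg_src") + 0.5 * t.f4(
            "Outgroup", "Satsurblia", "Kotias", "ehg_src"
        )
        assert lhs == pytest.approx(rhs, abs=1e-15)

    def test_cycle_detection(self):
        model = DemographyModel(
            edges=[Edge("a", "b", drift=0.01), Edge("b", "a", drift=0.01)]
        )
        with pytest.raises(ValueError):
            expected_f_moments(model)


class TestSimulateFrequencies:
    def test_zero_drift_branch_copies_parent(self):
        model = DemographyModel(
            edges=[Edge("root", "A", drift=0.0), Edge("root", "B", drift=0.05)]
        )
        freqs = simulate_frequencies(model, 500, seed=1)
        assert np.array_equal(freqs.of("A"), freqs.of("root"))
        assert not np.array_equal(freqs.of("B"), freqs.of("root"))

    def test_absorbing_boundary_at_zero(self):
        model = DemographyModel(
            edges=[Edge("root", "A", drift=0.1), Edge("A", "B", drift=0.1)],
            ancestral=AncestralFreqSpec("uniform", (0.0, 0.0)),
        )
        freqs = simulate_frequencies(model, 200, seed=2)
        assert (freqs.freqs == 0.0).all()

    def test_balding_nichols_variance(self):
        d = 0.02
        model = DemographyModel(edges=[Edge("root", "A", drift=d)])
        freqs = simulate_frequencies(model, 50_000, seed=3)
        p0, p1 = freqs.of("root"), freqs.of("A")
        sq = (p1 - p0) ** 2
        het = p0 * (1 - p0)
        ratio = sq.mean() / het.mean()
        mc_se = sq.std() / np.sqrt(len(sq)) / het.mean()
        assert abs(ratio - d) < 3 * mc_se

    def test_seed_determinism(self, preset_model):
        a = simulate_frequencies(preset_model, 1_000, seed=9)
        b = simulate_frequencies(preset_model, 1_000, seed=9)
        c = simulate_frequencies(preset_model, 1_000, seed=10)
        assert np.array_equal(a.freqs, b.freqs)
        assert not np.array_equal(a.freqs, c.freqs)

    def test_degenerate_drift_rejected(self):
        model = DemographyModel(edges=[Edge("root", "A", drift=1.0)])
        with pytest.raises(ValueError):
            simulate_frequencies(model, 10, seed=0)


class TestSampleGenotypes:
    def test_pseudo_haploid_dosages_are_homozygous(self, small_sim):
        panel = small_sim["panel"]
        ph = (panel.samples["ploidy_mode"] == PSEUDO_HAPLOID).to_numpy()
        vals = np.unique(panel.dosages[ph])
        assert set(vals.tolist()) <= {0, 2}

    def test_zero_frequency_snp_gives_zero_dosage(self):
        model = DemographyModel(
            edges=[Edge("root", "A", drift=0.1)],
            ancestral=AncestralFreqSpec("uniform", (0.0, 0.0)),
            sampling={"A": SamplingSpec(n_diploid=3, n_pseudo_haploid=2)},
        )
        freqs = simulate_frequencies(model, 100, seed=4)
        panel, _ = syndata.sample_genotypes(freqs, model, seed=5)
        assert (panel.dosages == 0).all()

    def test_binomial_sampling_mean(self):
        model = DemographyModel(
            edges=[Edge("root", "A", drift=0.05)],
            sampling={"A": SamplingSpec(n_diploid=10)},
        )
        freqs = simulate_frequencies(model, 20_000, seed=6)
        panel, _ = syndata.sample_genotypes(freqs, model, seed=7)
        p = freqs.of("A")
        observed = panel.dosages.mean() / 2.0
        se = np.sqrt((p * (1 - p) / (2 * 10)).sum()) / len(p)
        assert abs(observed - p.mean()) < 3 * se

    def test_snps_span_multiple_chromosomes(self, small_sim):
        assert small_sim["snps"]["chrom"].nunique() >= 2

    def test_mismatched_model_rejected(self, preset_model):
        other = DemographyModel(
            edges=[Edge("root", "Q", drift=0.01)],
            sampling={"Q": SamplingSpec(n_diploid=1)},
        )
        freqs = simulate_frequencies(preset_model, 50, seed=1)
        freqs_q = syndata.PopulationFrequencies(["X"], freqs.freqs[:1])
        with pytest.raises(ValueError):
            syndata.sample_genotypes(freqs_q, other, seed=1)


class TestSimulatePileup:
    def _fixed_freq_model(self, value):
        return DemographyModel(
            edges=[Edge("root", "A", drift=0.0)],
            ancestral=AncestralFreqSpec("uniform", (value, value)),
        )

    def test_no_error_homozygote_has_single_base(self):
        model = self._fixed_freq_model(1.0)
        freqs = simulate_frequencies(model, 300, seed=8)
        pileup, genotype = syndata.simulate_pileup(
            freqs, coverage=5.0, error_rate=0.0, seed=9, population="A"
        )
        assert (genotype == 2).all()
        counts = pileup[["countA", "countC", "countG", "countT"]].to_numpy()
        assert ((counts > 0).sum(axis=1) == 1).all()

    def test_mean_depth_matches_coverage(self, preset_model):
        freqs = simulate_frequencies(preset_model, 10_000, seed=10)
        pileup, _ = syndata.simulate_pileup(
            freqs, coverage=1.4, error_rate=0.01, seed=11, population="Satsurblia"
        )
        total_reads = pileup[["countA", "countC", "countG", "countT"]].to_numpy().sum()
        mean_depth = total_reads / 10_000  # zero-depth SNPs just absent
        se = np.sqrt(1.4 / 10_000)
        assert abs(mean_depth - 1.4) < 3 * se

    def test_zero_depth_sites_absent(self, preset_model):
        freqs = simulate_frequencies(preset_model, 5_000, seed=12)
        pileup, _ = syndata.simulate_pileup(
            freqs, coverage=0.5, error_rate=0.0, seed=13, population="Kotias"
        )
        assert len(pileup) < 5_000
        counts = pileup[["countA", "countC", "countG", "countT"]].to_numpy()
        assert (counts.sum(axis=1) > 0).all()

    def test_error_rate_bounds(self, preset_model):
        freqs = simulate_frequencies(preset_model, 10, seed=1)
        with pytest.raises(ValueError):
            syndata.simulate_pileup(freqs, coverage=1.0, error_rate=0.3, seed=1)


class TestSimulateRohGenome:
    def test_planted_segment_is_homozygous_without_error(self):
        panel, snps, _ = syndata.simulate_roh_genome(
            chrom_lengths=[20_000_000],
            het_density=3e-5,
            planted_segments=[(1, 5_000_000, 10_000_000)],
            error_het_rate=0.0,
            seed=14,
        )
        pos = snps["position"].to_numpy()
        inside = (pos >= 5_000_000) & (pos <= 10_000_000)
        assert (panel.dosages[0, inside] != 1).all()
        assert (panel.dosages[0, ~inside] == 1).any()

    def test_zero_het_density_all_homozygous(self):
        panel, _, _ = syndata.simulate_roh_genome(
            chrom_lengths=[5_000_000],
            het_density=0.0,
            planted_segments=[],
            error_het_rate=0.0,
            seed=15,
        )
        assert (panel.dosages != 1).all()

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            syndata.simulate_roh_genome(
                chrom_lengths=[10_000_000],
                het_density=1e-5,
                planted_segments=[(1, 1_000_000, 3_000_000), (1, 2_000_000, 4_000_000)],
                error_het_rate=0.0,
                seed=16,
            )
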