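from fractions import Fraction

import numpy as np
import pytest

from kinphase.inheritance import simplex_nulliplex_priors
from kinphase.simulate import (
    SimulationConfig,
    _sample_gametes,
    simulate_cross,
    simulate_parents,
)


class TestConfig:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.k == 4 and cfg.coverage == 6.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=3),
            dict(coverage=0),
            dict(fraction_simplex_nulliplex=0.8, fraction_simplex_simplex=0.3),
            dict(recombination_rate=1.5),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestParents:
    def test_simplex_nulliplex_structure(self):
        cfg = SimulationConfig(k=4, m=100, p=5, seed=1)
        dos_p, dos_o, truth = simulate_parents(cfg)
        assert (truth.hap_sprime.sum(axis=0) == 1).all()
        assert (truth.hap_other == 0).all()
        assert (dos_p == 1).all() and (dos_o == 0).all()

    def test_truth_dosage_consistency(self):
        cfg = SimulationConfig(
            k=4, m=300, p=5,
            fraction_simplex_nulliplex=0.5,
            fraction_simplex_simplex=0.25,
            fraction_duplex_nulliplex=0.25,
            seed=3,
        )
        dos_p, dos_o, truth = simulate_parents(cfg)
        np.testing.assert_array_equal(truth.hap_sprime.sum(axis=0), dos_p)
        np.testing.assert_array_equal(truth.hap_other.sum(axis=0), dos_o)

    def test_marker_haplotypes_near_uniform(self):
        from scipy.stats import chisquare

        cfg = SimulationConfig(k=4, m=10000, p=5, seed=5)
        _, _, truth = simulate_parents(cfg)
        counts = truth.hap_sprime.sum(axis=1)
        assert chisquare(counts).pvalue > 1e-4

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(k=4, m=50, p=10, seed=9)
        a = simulate_cross(cfg)
        b = simulate_cross(cfg)
        np.testing.assert_array_equal(a.depth_minor, b.depth_minor)
        np.testing.assert_array_equal(a.truth.hap_sprime, b.truth.hap_sprime)


class TestTransmission:
    def test_gamete_size(self):
        gam = _sample_gametes(np.random.default_rng(0), 4, 500)
        assert (gam.sum(axis=1) == 2).all()

    @pytest.mark.parametrize("same_hap", [True, False])
    def test_empirical_frequencies_match_priors(self, same_hap):
        """Simulated transmission reproduces the closed-form L=/L!= tables."""
        k, n = 4, 20000
        rng = np.random.default_rng(123 if same_hap else 321)
        hap = np.zeros((k, 2), dtype=int)
        hap[0, 0] = 1
        hap[0 if same_hap else 1, 1] = 1
        gam = _sample_gametes(rng, k, n)
        inherited = gam @ hap  # (n, 2) dosage pairs
        priors = simplex_nulliplex_priors(k)
        table = priors.same if same_hap else priors.diff
        for cell in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            q = float(table.get(cell, Fraction(0)))
            freq = np.mean((inherited[:, 0] == cell[0]) & (inherited[:, 1] == cell[1]))
            se = max(np.sqrt(q * (1 - q) / n), 1e-9)
            assert abs(freq - q) <= 4 * se, (cell, freq, q)

    def test_minority_read_fraction(self):
        """E[minority fraction] = P(inherit) * dosage/k = 0.5 * 0.25."""
        cfg = SimulationConfig(k=4, m=20, p=5000, coverage=6.0, seed=17)
        sim = simulate_cross(cfg)
        total = sim.depth_major + sim.depth_minor
        frac = sim.depth_minor.sum() / total.sum()
        assert frac == pytest.approx(0.125, abs=0.005)

    def test_no_recombination_keeps_inheritance_constant(self):
        cfg = SimulationConfig(k=4, m=200, p=50, seed=2)
        sim = simulate_cross(cfg)
        # inherited dosage at every variant must equal the static gamete dosage
        expected = sim.truth.inherited_sprime @ sim.truth.hap_sprime
        # reconstruct inherited dosages from depth-free rerun of the model:
        # minority reads can never exceed binomial n with p = n_dosage/k = 0
        zero_dosage = expected.T == 0
        assert (sim.depth_minor[zero_dosage] == 0).all()

    def test_recombination_changes_inheritance(self):
        cfg = SimulationConfig(k=4, m=400, p=30, seed=2, recombination_rate=0.02)
        sim = simulate_cross(cfg)
        expected_static = (sim.truth.inherited_sprime @ sim.truth.hap_sprime).T
        # with crossovers some zero-dosage-under-static-model sites show reads
        assert (sim.depth_minor[expected_static == 0] > 0).any()


class TestFixtureRoundTrip:
    def test_vcf_round_trip(self, tmp_path, small_cross):
        from kinphase.io import read_inputs, read_truth_table
        from kinphase.simulate import emit_fixture
        from kinphase.variants import PloidyConfig

        vcf = str(tmp_path / "sim.vcf")
        truth = str(tmp_path / "sim.truth.tsv")
        samples = emit_fixture(small_cross, vcf, truth)
        config = PloidyConfig(4, samples[0], samples[1], samples[2:])
        data = read_inputs(vcf, config)
        assert data.n_sites == small_cross.config.m
        np.testing.assert_array_equal(data.dosage_sprime, small_cross.dosage_sprime)
        np.testing.assert_array_equal(data.depth_major, small_cross.depth_major)
        np.testing.assert_array_equal(data.depth_minor, small_cross.depth_minor)

        positions, classes, hap = read_truth_table(truth)
        np.testing.assert_array_equal(hap, small_cross.truth.hap_sprime)
        assert classes[0] == small_cross.truth.classes[0].value
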