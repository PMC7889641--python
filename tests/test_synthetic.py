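import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import kstest

from cgphase.constants import KB
from cgphase.synthetic import (
    TOY_CLASSES,
    ToyPairClass,
    make_sequence,
    sample_umbrella_windows,
    sample_windows_from_potential,
    synth_coexistence_points,
    synth_droplet_mask,
    toy_pair_potential,
)

R_GRID = np.linspace(0.25, 1.6, 600)


class TestToyPairPotential:
    def test_charged_opposite_weakens_with_salt(self):
        mins = [toy_pair_potential(R_GRID, "charged_opposite", s).min()
                for s in (0.0, 1.5, 3.0)]
        assert mins[0] < mins[1] < mins[2] < 0

    def test_hydrophobic_deepens_with_salt(self):
        mins = [toy_pair_potential(R_GRID, "hydrophobic", s).min()
                for s in (0.0, 1.5, 3.0)]
        assert mins[0] > mins[1] > mins[2]

    def test_arg_arg_like_switches_sign(self):
        contact = R_GRID[R_GRID < 0.6]
        u0 = toy_pair_potential(contact, "charged_like_pi", 0.0)
        u3 = toy_pair_potential(R_GRID, "charged_like_pi", 3.0)
        assert u0.min() > 0  # purely repulsive near contact at low salt
        assert u3.min() < 0  # attractive once screened

    def test_hybrid_dips_then_recovers_allowed(self):
        mins = [toy_pair_potential(R_GRID, "cation_pi_hybrid", s).min()
                for s in (0.0, 1.5, 3.0)]
        assert mins[0] < -2 and mins[2] < -2  # strong at both extremes

    def test_magnitudes_in_expected_regime(self):
        for name in TOY_CLASSES:
            for s in (0.0, 1.5, 3.0):
                m = toy_pair_potential(R_GRID, name, s).min()
                assert -14.0 < m < 6.0

    def test_negative_salt_rejected(self):
        with pytest.raises(ValueError):
            toy_pair_potential(0.5, "hydrophobic", -1.0)

    def test_invalid_class_parameters_rejected(self):
        with pytest.raises(ValueError):
            ToyPairClass("bad", 0.0, 1.0, -0.5)
        with pytest.raises(ValueError):
            ToyPairClass("bad", 0.0, 1.0, 0.5, well_width=-1.0)


class TestUmbrellaSampler:
    def test_stiff_bias_centers_on_constrained_minimum(self):
        u = lambda x: toy_pair_potential(x, "hydrophobic", 1.5)
        k_bias = 6000.0
        center = 0.6
        wins = sample_windows_from_potential(
            u, [center], k_bias=k_bias, n_per_window=8000, rng_seed=2
        )
        biased = lambda x: u(np.array([x]))[0] + 0.5 * k_bias * (x - center) ** 2
        xmin = minimize_scalar(biased, bounds=(0.3, 0.9), method="bounded").x
        samples = wins[0].samples
        se = samples.std() / np.sqrt(samples.size / 10)  # thinned chain
        assert abs(samples.mean() - xmin) < 3 * se + 1e-3

    def test_distribution_matches_boltzmann(self):
        u = lambda x: toy_pair_potential(x, "hydrophobic", 0.0)
        center, k_bias = 0.55, 2000.0
        wins = sample_windows_from_potential(
            u, [center], k_bias=k_bias, n_per_window=10_000, rng_seed=3
        )
        kT = KB * 298.15
        xs = np.linspace(0.3, 0.9, 4001)
        dens = np.exp(-(u(xs) + 0.5 * k_bias * (xs - center) ** 2) / kT)
        cdf_grid = np.cumsum(dens)
        cdf_grid /= cdf_grid[-1]
        cdf = lambda x: np.interp(x, xs, cdf_grid)
        stat = kstest(wins[0].samples, cdf)
        assert stat.pvalue > 0.01

    def test_seed_determinism(self):
        a = sample_umbrella_windows("hydrophobic", 1.0, [0.5, 0.6],
                                    n_per_window=500, rng_seed=9)
        b = sample_umbrella_windows("hydrophobic", 1.0, [0.5, 0.6],
                                    n_per_window=500, rng_seed=9)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.samples, wb.samples)

    def test_default_protocol_shape(self):
        wins = sample_umbrella_windows("hydrophobic", 0.0, n_per_window=50,
                                       rng_seed=1)
        centers = [w.center for w in wins]
        assert len(wins) == 31
        assert centers[0] == pytest.approx(0.1)
        assert centers[-1] == pytest.approx(1.6)
        assert all(w.k_bias == 6000.0 for w in wins)


class TestMakeSequence:
    def test_pr25(self):
        seq = make_sequence("PR25")
        assert len(seq) == 25
        assert seq.count("R") == 13 and seq.count("P") == 12
        assert all(a != b for a, b in zip(seq, seq[1:]))  # alternating
        assert seq[0] == "R" and seq[-1] == "R"

    def test_homopolymer(self):
        assert make_sequence("homopolymer", res="A", n=50) == "A" * 50

    def test_pld_like_composition(self):
        seq = make_sequence("PLD_like")
        assert len(seq) == 100
        assert seq.count("R") == 5  # slightly net-positive
        assert seq.count("Y") >= 20  # aromatic-rich

    def test_fus_pld_from_fasta(self, fus_fasta):
        seq = make_sequence("FUS_PLD", fus_fasta)
        assert len(seq) == 163
        full = make_sequence("FUS_full", fus_fasta)
        assert len(full) == 526
        assert full.startswith(seq)

    def test_fus_requires_fasta(self):
        with pytest.raises(ValueError, match="K7DPS7"):
            make_sequence("FUS_PLD")

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_sequence("collagen")


class TestSynthCoexistence:
    def test_noiseless_points_on_curve(self):
        temps = np.array([350.0, 370.0, 390.0])
        pts = synth_coexistence_points(400.0, 900.0, 0.325, temps, 0.0, 0)
        for p in pts:
            drho = 900.0 * (1 - p.temperature / 400.0) ** 0.325
            assert p.rho_dense - p.rho_dilute == pytest.approx(drho, rel=1e-12)

    def test_supercritical_temperature_rejected(self):
        with pytest.raises(ValueError):
            synth_coexistence_points(400.0, 900.0, 0.325, [401.0], 0.0, 0)

    def test_seed_determinism(self):
        a = synth_coexistence_points(400.0, 900.0, 0.325, [350.0], 0.05, 7)
        b = synth_coexistence_points(400.0, 900.0, 0.325, [350.0], 0.05, 7)
        assert a[0].rho_dense == b[0].rho_dense


class TestSynthDropletMask:
    def test_single_disk_area(self):
        mask, truth = synth_droplet_mask([30.0], [(64.0, 64.0)], (128, 128))
        assert mask.max() == 1
        assert (mask == 1).sum() == pytest.approx(np.pi * 900, rel=0.02)

    def test_labels_and_truth_table(self):
        mask, truth = synth_droplet_mask(
            [20.0, 12.0], [(50.0, 50.0), (50.0, 120.0)], (100, 160)
        )
        assert sorted(np.unique(mask)) == [0, 1, 2]
        assert list(truth["label"]) == [1, 2]
        assert truth["circularity"].iloc[0] == 1.0  # zero noise

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth_droplet_mask([20.0, 20.0], [(50.0, 50.0), (50.0, 80.0)],
                               (128, 128))

    def test_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            synth_droplet_mask([30.0], [(10.0, 64.0)], (128, 128))

    def test_seed_determinism_with_noise(self):
        a, _ = synth_droplet_mask([25.0], [(64.0, 64.0)], (128, 128), 0.05, 3)
        b, _ = synth_droplet_mask([25.0], [(64.0, 64.0)], (128, 128), 0.05, 3)
        np.testing.assert_array_equal(a, b)
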