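import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import constants as sc

from cgphase import (
    InteractionScaling,
    apply_regime,
    build_topology,
    debye_length,
    pair_energy,
    system_energy_forces,
)
from cgphase.constants import EPS_AH

RMIN = 2.0 ** (1.0 / 6.0)


class TestDebyeLength:
    def test_zero_ionic_strength_unscreened(self):
        assert math.isinf(debye_length(0.0))

    def test_physiological_value_matches_closed_form(self):
        # independent evaluation of sqrt(eps0 epsr kB T / (2 NA e^2 I))
        i_si = 0.15 * 1000.0
        expected = 1e9 * math.sqrt(
            sc.epsilon_0 * 80.0 * sc.k * 298.0 / (2 * sc.N_A * sc.e**2 * i_si)
        )
        assert debye_length(0.15, 298.0, 80.0) == pytest.approx(expected, rel=1e-12)
        assert 0.75 < expected < 0.82

    def test_monotone_in_ionic_strength(self):
        lam = [debye_length(i) for i in (0.01, 0.1, 0.5, 1.5, 3.0)]
        assert all(a > b for a, b in zip(lam, lam[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            debye_length(-0.1)


class TestPairEnergy:
    def test_full_lambda_reduces_to_lj_minimum(self, params):
        sij = params["F"].sigma
        pe = pair_energy(
            RMIN * sij, "F", "F", params, InteractionScaling(chi=0),
            hydro_cutoff=100.0,
        )
        assert pe.hydrophobic == pytest.approx(-EPS_AH, rel=1e-6)
        assert pe.total == pe.hydrophobic + pe.electrostatic + pe.cation_pi

    def test_zero_lambda_shift_cancels_minimum(self, params):
        sij = params["R"].sigma  # lambda_R = 0
        pe = pair_energy(
            RMIN * sij, "R", "R", params, InteractionScaling(chi=0),
            hydro_cutoff=100.0,
        )
        assert pe.hydrophobic == pytest.approx(0.0, abs=1e-12)

    def test_electrostatic_linear_in_chi(self, params):
        r = 0.8
        e1 = pair_energy(r, "R", "K", params, InteractionScaling(chi=1.0))
        e2 = pair_energy(r, "R", "K", params, InteractionScaling(chi=2.0))
        assert e2.electrostatic == pytest.approx(2.0 * e1.electrostatic, rel=1e-12)
        assert e1.electrostatic > 0  # like charges repel

    def test_cation_pair_salt_regime_switch(self, params):
        """Like-charged pairs: strongly repulsive at low salt (chi=4),
        neutral-to-attractive once screening removes the Coulomb term.
        Arg carries lambda = 0 in the hydrophobicity table, so its
        high-salt limit is neutral; Lys (lambda 0.514) switches sign."""
        for res, attractive in (("R", False), ("K", True)):
            sij = params[res].sigma
            r = RMIN * sij
            high = pair_energy(
                r, res, res, params,
                InteractionScaling(chi=0.0, hydro_scale=1.3),
            )
            low = pair_energy(
                r, res, res, params,
                InteractionScaling(chi=4.0, hydro_scale=1.0),
            )
            assert low.total > 1.0  # dominated by Coulomb repulsion
            if attractive:
                assert high.total < 0
            else:
                assert high.total <= 0

    def test_cation_pi_only_on_cation_aromatic(self, params):
        sc_on = InteractionScaling(chi=0, cation_pi_eps=3.0)
        ry = pair_energy(0.7, "R", "Y", params, sc_on)
        yr = pair_energy(0.7, "Y", "R", params, sc_on)
        rr = pair_energy(0.7, "R", "R", params, sc_on)
        assert ry.cation_pi < 0
        assert ry.cation_pi == yr.cation_pi
        assert rr.cation_pi == 0.0

    def test_buried_scaling_reduces_attraction(self, params):
        r = RMIN * params["F"].sigma
        free = pair_energy(r, "F", "F", params, InteractionScaling(chi=0))
        buried = pair_energy(
            r, "F", "F", params, InteractionScaling(chi=0),
            buried_i=True, buried_j=True,
        )
        assert buried.hydrophobic > free.hydrophobic  # shallower well

    def test_zero_distance_rejected(self, params):
        with pytest.raises(ValueError):
            pair_energy(0.0, "G", "G", params, InteractionScaling())

    @settings(max_examples=60, deadline=None)
    @given(
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        st.floats(min_value=0.3, max_value=1.9),
    )
    def test_pair_symmetry(self, params, res_i, res_j, r):
        scl = InteractionScaling(chi=2.0, hydro_scale=1.1, cation_pi_eps=3.0)
        a = pair_energy(r, res_i, res_j, params, scl)
        b = pair_energy(r, res_j, res_i, params, scl)
        assert a.total == pytest.approx(b.total, rel=1e-12, abs=1e-15)

    def test_continuity_at_crossover(self, params):
        """The Ashbaugh-Hatch form is continuous at r = 2^(1/6) sigma_ij
        for every lambda."""
        sij = 0.5 * (params["A"].sigma + params["Y"].sigma)
        rm = RMIN * sij
        for hs in np.linspace(0.05, 1.6, 12):
            scl = InteractionScaling(chi=0, hydro_scale=hs)
            left = pair_energy(rm * (1 - 1e-11), "A", "Y", params, scl)
            right = pair_energy(rm * (1 + 1e-11), "A", "Y", params, scl)
            assert abs(left.hydrophobic - right.hydrophobic) < 1e-8

    def test_terms_vanish_at_cutoff(self, params):
        scl = InteractionScaling(chi=4.0, cation_pi_eps=3.0)
        pe = pair_energy(1.9999, "R", "Y", params, scl, hydro_cutoff=2.0)
        assert abs(pe.hydrophobic) < 1e-4
        assert abs(pe.cation_pi) < 1e-4
        pe = pair_energy(3.4999, "R", "K", params, scl, elec_cutoff=3.5)
        assert abs(pe.electrostatic) < 1e-4

    def test_minimum_depth_monotone_in_hydro_scale(self, params):
        r = RMIN * params["S"].sigma
        depths = [
            pair_energy(
                r, "S", "S", params, InteractionScaling(chi=0, hydro_scale=h)
            ).hydrophobic
            for h in (0.4, 0.8, 1.2, 1.6)
        ]
        assert all(a > b for a, b in zip(depths, depths[1:]))


class TestRegimePresets:
    def test_low_regime(self):
        s = apply_regime("low", "fus_like")
        assert s.chi == 4.0 and s.hydro_scale == 1.0 and s.cation_pi_eps > 0

    def test_moderate_regime(self):
        s = apply_regime("moderate", "fus_like")
        assert s.chi == 2.0 and s.hydro_scale == 1.0 and s.cation_pi_eps == 0

    def test_high_regime_by_class(self):
        assert apply_regime("high", "fus_like").hydro_scale == pytest.approx(1.1)
        assert apply_regime("high", "pr_like").hydro_scale == pytest.approx(1.3)
        assert apply_regime("high", "pr_like").chi == 1.0

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            apply_regime("brackish", "fus_like")


def _random_relaxed_system(params, rng):
    """Three 10-mers with bonded neighbors near r0 and no hard overlaps."""
    topo = build_topology("RPGYSDEKAF")
    box = np.array([6.0, 6.0, 6.0])
    while True:
        pos = np.empty((30, 3))
        for c in range(3):
            pos[c * 10] = rng.uniform(1, 5, 3)
            for i in range(1, 10):
                d = rng.normal(size=3)
                d *= 0.38 / np.linalg.norm(d)
                pos[c * 10 + i] = pos[c * 10 + i - 1] + d
        diffs = pos[None, :, :] - pos[:, None, :]
        diffs -= box * np.rint(diffs / box)
        dist = np.sqrt((diffs**2).sum(-1)) + np.eye(30) * 10
        if dist.min() > 0.35:
            return topo, box, pos


class TestSystemEnergyForces:
    def test_two_bonded_beads_at_rest_length(self, params):
        topo = build_topology("GG", r0=0.38)
        box = np.array([5.0, 5.0, 5.0])
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.38]])
        e, f = system_energy_forces(
            pos, box, [topo], params, InteractionScaling(chi=0)
        )
        assert e == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(f, 0.0, atol=1e-8)

    def test_forces_match_finite_differences(self, params):
        rng = np.random.default_rng(11)
        topo, box, pos = _random_relaxed_system(params, rng)
        scl = InteractionScaling(chi=2.0, hydro_scale=1.1, cation_pi_eps=3.0)
        e0, f = system_energy_forces(pos, box, [(topo, 3)], params, scl)
        h = 1e-6
        fd = np.zeros_like(f)
        for i in range(pos.shape[0]):
            for d in range(3):
                pp = pos.copy()
                pp[i, d] += h
                pm = pos.copy()
                pm[i, d] -= h
                ep, _ = system_energy_forces(pp, box, [(topo, 3)], params, scl)
                em, _ = system_energy_forces(pm, box, [(topo, 3)], params, scl)
                fd[i, d] = -(ep - em) / (2 * h)
        rel = np.max(np.abs(fd - f)) / np.max(np.abs(f))
        assert rel < 1e-5

    def test_chi_decouples_from_uncharged_system(self, params):
        rng = np.random.default_rng(3)
        topo = build_topology("GYSGPAQSTW")  # no charges
        box = np.array([6.0, 6.0, 6.0])
        pos = rng.uniform(1, 5, (10, 3))
        e1, _ = system_energy_forces(
            pos, box, [topo], params, InteractionScaling(chi=1.0)
        )
        e2, _ = system_energy_forces(
            pos, box, [topo], params, InteractionScaling(chi=2.0)
        )
        assert e1 == e2

    def test_translation_and_image_invariance(self, params):
        rng = np.random.default_rng(5)
        topo, box, pos = _random_relaxed_system(params, rng)
        scl = InteractionScaling(chi=1.0, cation_pi_eps=2.0)
        e0, _ = system_energy_forces(pos, box, [(topo, 3)], params, scl)
        e1, _ = system_energy_forces(pos + 1.234, box, [(topo, 3)], params, scl)
        shifted = pos.copy()
        shifted[7] += box  # full periodic image shift of one bead
        e2, _ = system_energy_forces(shifted, box, [(topo, 3)], params, scl)
        assert e1 == pytest.approx(e0, rel=1e-9, abs=1e-9)
        assert e2 == pytest.approx(e0, rel=1e-9, abs=1e-9)

    def test_hard_overlap_reports_pair(self, params):
        topo = build_topology("GGG")
        box = np.array([5.0, 5.0, 5.0])
        pos = np.array([[1.0, 1, 1], [1.38, 1, 1], [1.0, 1.0, 1.05]])
        with pytest.raises(ValueError, match="beads 0 and 2"):
            system_energy_forces(
                pos, box, [topo], params, InteractionScaling(chi=0)
            )
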