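import numpy as np
import pytest

from cgphase import (
    ForceField,
    InteractionScaling,
    build_topology,
    make_sequence,
)
from cgphase.constants import BAR, KB
from cgphase.dynamics import (
    SystemState,
    default_slab_box,
    init_slab,
    langevin_run,
    npt_equilibrate,
    relax_overlaps,
    run_direct_coexistence,
)


@pytest.fixture(scope="module")
def pr25_topo():
    return build_topology(make_sequence("PR25"), name="PR25")


class TestInitSlab:
    def test_pr25_slab_placement(self, params, pr25_topo):
        box = np.array([8.0, 8.0, 32.0])
        st = init_slab([pr25_topo], [50], box, params, slab_fraction=0.25,
                       rng_seed=1)
        assert st.positions.shape == (1250, 3)
        z = st.positions[:, 2]
        lo, hi = 0.5 * 32 * (1 - 0.25), 0.5 * 32 * (1 + 0.25)
        assert np.all(z >= lo - pr25_topo.r0 - 1e-9)
        assert np.all(z <= hi + pr25_topo.r0 + 1e-9)
        # minimum separation contract
        from scipy.spatial import cKDTree

        tree = cKDTree(np.mod(st.positions, box), boxsize=box)
        sig_min = min(params[r].sigma for r in pr25_topo.sequence)
        close = tree.query_pairs(0.7 * sig_min - 1e-9)
        bonded = {(i, i + 1) for i in range(1250) if (i + 1) % 25 != 0}
        assert set(map(tuple, map(sorted, close))) <= bonded

    def test_seed_determinism(self, params, pr25_topo):
        box = np.array([8.0, 8.0, 32.0])
        a = init_slab([pr25_topo], [10], box, params, rng_seed=7)
        b = init_slab([pr25_topo], [10], box, params, rng_seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_impossible_density_raises(self, params, pr25_topo):
        box = np.array([3.0, 3.0, 12.0])
        with pytest.raises(RuntimeError, match="larger"):
            init_slab([pr25_topo], [200], box, params, max_retries=5)


def _bound(params, topo, count, scaling=None, **kw):
    ff = ForceField(
        params, scaling or InteractionScaling(chi=0.0), **kw
    )
    return ff


class TestLangevin:
    def test_seed_reproducibility(self, params):
        topo = build_topology("GYSRG")
        box = np.array([6.0, 6.0, 24.0])
        st = init_slab([topo], [6], box, params, rng_seed=3)
        ff = ForceField(params, InteractionScaling(chi=1.0))
        system = ff.bind([(topo, 6)])
        st = relax_overlaps(st, system)
        out = []
        for _ in range(2):
            traj = langevin_run(
                st, system, 300.0, n_steps=2000, thin=500, rng_seed=9
            )
            out.append(traj.frames.copy())
        assert np.array_equal(out[0], out[1])

    def test_zero_temperature_descends_potential(self, params):
        topo = build_topology("GYSRG")
        box = np.array([6.0, 6.0, 24.0])
        st = init_slab([topo], [6], box, params, rng_seed=3, temperature=300)
        st.velocities[:] = 0.0
        ff = ForceField(params, InteractionScaling(chi=0.0))
        system = ff.bind([(topo, 6)])
        st = relax_overlaps(st, system)
        st.velocities[:] = 0.0
        traj = langevin_run(
            st, system, 0.0, n_steps=4000, thin=200, rng_seed=1,
            friction_time_ps=0.5, zero_com=False,
        )
        e = traj.energy_log["E_pot"].to_numpy()
        assert e[-1] <= e[0]
        assert np.all(np.diff(e) < 1e-6)  # monotone within roundoff

    def test_equipartition_in_harmonic_trap(self, params):
        """Relative coordinate of an r0=0 harmonic bond: per-component
        variance kB T / k."""
        k = 400.0
        topo = build_topology("GG", r0=0.0, bond_k=k)
        ff = ForceField(params, InteractionScaling(chi=0.0), eps=0.0)
        system = ff.bind([(topo, 1)])
        box = np.array([10.0, 10.0, 10.0])
        st = SystemState(
            np.array([[5.0, 5, 5], [5.0, 5, 5.01]]),
            np.zeros((2, 3)),
            box,
            np.zeros(2, dtype=int),
            np.arange(2),
        )
        traj = langevin_run(
            st, system, 300.0, n_steps=400_000, thin=100, rng_seed=4,
            zero_com=False,
        )
        d = traj.frames[:, 0, :] - traj.frames[:, 1, :]
        d -= box * np.rint(d / box)
        var = d.var(axis=0).mean()
        expected = KB * 300.0 / k
        # standard error from blocking over 20 segments
        blocks = np.array_split(np.sum(d**2, axis=1) / 3.0, 20)
        se = np.std([b.mean() for b in blocks]) / np.sqrt(20)
        assert abs(var - expected) < 3 * se

    def test_unstable_dt_rejected(self, params):
        topo = build_topology("GG", bond_k=1e6)
        ff = ForceField(params, InteractionScaling(chi=0.0))
        system = ff.bind([(topo, 1)])
        st = SystemState(
            np.array([[1.0, 1, 1], [1.0, 1, 1.38]]),
            np.zeros((2, 3)),
            np.array([5.0, 5, 5]),
            np.zeros(2, dtype=int),
            np.arange(2),
        )
        with pytest.raises(ValueError, match="unstable"):
            langevin_run(st, system, 300.0, dt_fs=10.0, n_steps=100, thin=10)


class TestNpt:
    def _gas(self, params, n=216, box_edge=12.0):
        topo = build_topology("G")  # single-bead chains, no bonds
        box = np.array([box_edge] * 3)
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, box_edge, (n, 3))
        vel = rng.normal(size=(n, 3)) * np.sqrt(KB * 300.0 / params["G"].mass)
        st = SystemState(pos, vel, box, np.arange(n), np.zeros(n, dtype=int))
        ff = ForceField(params, InteractionScaling(chi=0.0), eps=0.0)
        system = ff.bind([(topo, n)])
        return st, system

    def test_infinite_tau_keeps_volume(self, params):
        st, system = self._gas(params, n=64, box_edge=8.0)
        out = npt_equilibrate(
            st, system, 300.0, pressure_bar=1.0, tau_p_ps=np.inf, n_steps=400
        )
        assert np.allclose(out.box, st.box)

    def test_ideal_gas_volume_approaches_equation_of_state(self, params):
        n = 216
        target_v = n * KB * 300.0 / (1.0 * BAR)
        start_edge = (0.55 * target_v) ** (1 / 3)
        st, system = self._gas(params, n=n, box_edge=start_edge)
        out = npt_equilibrate(
            st,
            system,
            300.0,
            pressure_bar=1.0,
            tau_p_ps=2.0,
            n_steps=6000,
            n_inner=10,
            rng_seed=2,
        )
        vol = float(np.prod(out.box))
        assert abs(vol - target_v) / target_v < 0.2


class TestDirectCoexistence:
    def test_temperature_ladder_keys(self, params):
        topo = build_topology("GYSRG")
        trajs = run_direct_coexistence(
            topo, 6, params, "moderate", [280.0, 320.0],
            n_steps=2000, thin=500, rng_seed=1,
        )
        assert set(trajs) == {280.0, 320.0}
        for T, tr in trajs.items():
            assert tr.temperature == T
            assert tr.n_frames == 4

    def test_no_cohesion_slab_spreads(self, params):
        topo = build_topology("GYSGS" * 4)
        scaling = InteractionScaling(chi=0.0, hydro_scale=1e-6)
        trajs = run_direct_coexistence(
            topo, 8, params, scaling, [300.0],
            n_steps=40_000, thin=2000, rng_seed=2, friction_time_ps=50.0,
        )
        tr = trajs[300.0]
        axis = int(np.argmax(tr.box))
        L = tr.box[axis]

        def spread(frame):
            theta = 2 * np.pi * np.mod(frame[:, axis], L) / L
            # circular standard deviation
            R = np.hypot(np.sin(theta).mean(), np.cos(theta).mean())
            return np.sqrt(-2 * np.log(max(R, 1e-12))) * L / (2 * np.pi)

        assert spread(tr.frames[-1]) > 1.5 * spread(tr.frames[0])

    def test_thermostat_on_slab(self, params, pr25_topo):
        trajs = run_direct_coexistence(
            pr25_topo, 12, params, "high", [240.0],
            protein_class="pr_like",
            n_steps=20_000, thin=500, rng_seed=3,
        )
        log = trajs[240.0].energy_log
        t_mean = log["T_inst"].iloc[10:].mean()
        assert abs(t_mean - 240.0) / 240.0 < 0.02
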