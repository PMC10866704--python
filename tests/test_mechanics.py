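"""Force field, Langevin stepping, and Bell kinetics against physics oracles."""

import copy
import math

import numpy as np
import pytest

from fibrelax.core import (
    Connector,
    Domain,
    Fibril,
    NetworkState,
    SimParams,
)
from fibrelax.mechanics import (
    bell_rate,
    bell_unbinding_step,
    bending_forces,
    compute_forces,
    connector_forces,
    euler_step,
    pack_state,
    rebinding_step,
    stretching_forces,
    thermal_displacement,
    total_energy,
)

BIG = Domain(Lx=1000.0, Ly=1000.0, Lz=1000.0)


def free_fibril(positions, l0=0.5, fid=0):
    return Fibril(id=fid, positions=positions, l0=l0)


class TestStretching:
    def test_rest_length_gives_zero_force(self):
        st = NetworkState(BIG, [free_fibril([[0, 5, 5], [0.5, 5, 5]])], [])
        F = stretching_forces(st, SimParams())
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_hooke_magnitude(self):
        # l = l0 + 0.1 at kappa_s = 100 pN/µm -> 10 pN axial tension
        st = NetworkState(BIG, [free_fibril([[0, 5, 5], [0.6, 5, 5]])], [])
        p = SimParams(kappa_s=100.0, dt=1e-5)
        F = stretching_forces(st, p)
        np.testing.assert_allclose(F[0], [10.0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(F[1], [-10.0, 0, 0], atol=1e-9)

    def test_isolated_fibril_forces_sum_to_zero(self):
        rng = np.random.default_rng(0)
        st = NetworkState(BIG, [free_fibril(500 + rng.normal(0, 0.3, (5, 3)))],
                          [])
        F = stretching_forces(st, SimParams())
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-10)

    def test_zero_length_segment_rejected(self):
        st = NetworkState(BIG, [free_fibril([[1, 1, 1], [1, 1, 1]])], [])
        with pytest.raises(ValueError):
            stretching_forces(st, SimParams())


class TestBending:
    def test_straight_fibril_unbent(self):
        st = NetworkState(
            BIG, [free_fibril([[0, 5, 5], [0.5, 5, 5], [1.0, 5, 5]])], [])
        F = bending_forces(st, SimParams())
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_right_angle_energy(self):
        # unit legs at rest length, one right angle: E = 1/2 κ_b (π/2)²
        p = SimParams(kappa_b=0.7)
        st = NetworkState(
            BIG, [free_fibril([[0, 5, 5], [1, 5, 5], [1, 6, 5]], l0=1.0)], [])
        E = total_energy(pack_state(st), p)
        assert E == pytest.approx(0.5 * 0.7 * (math.pi / 2) ** 2, rel=1e-12)


def random_state(rng):
    """Small two-fibril state with bound connectors, general position."""
    f0 = free_fibril(500 + rng.normal(0, 0.4, (4, 3)), fid=0)
    f1 = free_fibril(500 + rng.normal(0, 0.4, (4, 3)), fid=1)
    cons = [
        Connector("crosslinker", 0, float(rng.uniform(0, 1.5)),
                  1, float(rng.uniform(0, 1.5)), float(rng.uniform(0, 0.4))),
        Connector("bundler", 0, float(rng.uniform(0, 1.5)),
                  1, float(rng.uniform(0, 1.5)), float(rng.uniform(0, 0.4))),
    ]
    return NetworkState(BIG, [f0, f1], cons)


class TestForceEnergyConsistency:
    def test_forces_match_numerical_gradient(self):
        """Total deterministic force equals −∇E by central differences."""
        p = SimParams(kappa_s=3.0, kappa_b=0.8, kappa_c=2.0, dt=1e-4)
        rng = np.random.default_rng(11)
        h = 1e-6
        for _ in range(20):
            ps = pack_state(random_state(rng))
            F, _ = compute_forces(ps, p)
            G = np.zeros_like(F)
            for i in range(ps.n_beads):
                for ax in range(3):
                    orig = ps.pos[i, ax]
                    ps.pos[i, ax] = orig + h
                    ep = total_energy(ps, p)
                    ps.pos[i, ax] = orig - h
                    em = total_energy(ps, p)
                    ps.pos[i, ax] = orig
                    G[i, ax] = -(ep - em) / (2 * h)
            scale = max(np.abs(F).max(), 1e-9)
            np.testing.assert_allclose(F, G, atol=1e-6 * scale)


class TestConnectorForces:
    def two_fibril_pair(self, gap, rest):
        f0 = free_fibril([[0, 5, 5], [1, 5, 5]], l0=1.0, fid=0)
        f1 = free_fibril([[0, 5 + gap, 5], [1, 5 + gap, 5]], l0=1.0, fid=1)
        con = Connector("crosslinker", 0, 0.5, 1, 0.5, rest)
        return NetworkState(BIG, [f0, f1], [con])

    def test_rest_separation_gives_zero_tension(self):
        st = self.two_fibril_pair(gap=0.3, rest=0.3)
        _, T = connector_forces(st, SimParams())
        assert T[0] == pytest.approx(0.0, abs=1e-12)

    def test_hooke_tension(self):
        # d = rest + 0.05 at kappa_c = 200 -> 10 pN
        st = self.two_fibril_pair(gap=0.35, rest=0.3)
        p = SimParams(kappa_c=200.0, dt=5e-6)
        _, T = connector_forces(st, p)
        assert T[0] == pytest.approx(10.0, rel=1e-9)

    def test_interpolation_weights_partition_force(self):
        """Forces on the two beads flanking an attachment sum to the full
        connector force, split by the arc interpolation weights."""
        f0 = free_fibril([[0, 5, 5], [1, 5, 5]], l0=1.0, fid=0)
        f1 = free_fibril([[0, 6, 5], [1, 6, 5]], l0=1.0, fid=1)
        # both attachments at arc 0.25 -> separation purely along y
        con = Connector("crosslinker", 0, 0.25, 1, 0.25, 0.5)
        st = NetworkState(BIG, [f0, f1], [con])
        p = SimParams()
        F, T = connector_forces(st, p)
        total = p.kappa_c * (1.0 - 0.5)  # stretched by 0.5 µm
        np.testing.assert_allclose(F[0] + F[1], [0, total, 0], atol=1e-9)
        assert F[0][1] == pytest.approx(0.75 * total)
        assert F[1][1] == pytest.approx(0.25 * total)

    def test_unbound_connector_exerts_nothing(self):
        st = self.two_fibril_pair(gap=0.5, rest=0.1)
        st.connectors[0].bound = False
        F, T = connector_forces(st, SimParams())
        np.testing.assert_allclose(F, 0.0, atol=1e-12)
        assert T[0] == 0.0


class TestThermalDisplacement:
    def test_athermal_limit_is_zero(self):
        p = SimParams(kBT=0.0)
        d = thermal_displacement(p, np.random.default_rng(0), n=100)
        np.testing.assert_array_equal(d, 0.0)

    def test_moments_and_isotropy(self):
        p = SimParams()
        d = thermal_displacement(p, np.random.default_rng(5), n=10**6)
        target = p.thermal_step_sd
        for ax in range(3):
            assert d[:, ax].std() == pytest.approx(target, rel=0.01)
            assert abs(d[:, ax].mean()) < 5 * target / 1000
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            r = np.corrcoef(d[:, a], d[:, b])[0, 1]
            assert abs(r) < 0.01


class TestEulerStep:
    def test_rest_state_at_zero_temperature_is_fixed_point(self):
        p = SimParams(kBT=0.0)
        st = NetworkState(BIG, [free_fibril([[0, 5, 5], [0.5, 5, 5]])], [])
        before = st.fibrils[0].positions.copy()
        euler_step(st, p, np.random.default_rng(0))
        np.testing.assert_allclose(st.fibrils[0].positions, before,
                                   atol=1e-15)

    def test_displacement_is_force_over_drag_times_dt(self):
        # segment stretched 1 µm at kappa_s=1 -> 1 pN; Δx = F Δt/ζ = 0.01 µm
        p = SimParams(kappa_s=1.0, kappa_c=1.0, kBT=0.0, zeta=0.01, dt=1e-4)
        st = NetworkState(BIG, [free_fibril([[0, 5, 5], [1.5, 5, 5]])], [])
        euler_step(st, p, np.random.default_rng(0))
        pos = st.fibrils[0].positions
        assert pos[0, 0] == pytest.approx(0.01, rel=1e-9)
        assert pos[1, 0] == pytest.approx(1.5 - 0.01, rel=1e-9)

    def test_free_bead_diffusion_matches_einstein(self):
        """MSD of force-free beads = 6 (k_BT/ζ) t within 5%."""
        p = SimParams(kappa_s=1e-9, kappa_b=1e-9, kappa_c=1e-9,
                      dt=1e-3, zeta=0.01)
        rng = np.random.default_rng(99)
        fibs = [free_fibril(rng.uniform(400, 600, (2, 3)), fid=i)
                for i in range(1000)]
        st = NetworkState(BIG, fibs, [])
        ps = pack_state(st)
        start = ps.pos.copy()
        n_steps = 500
        for _ in range(n_steps):
            euler_step(ps, p, rng)
        t = n_steps * p.dt
        msd = float(np.mean(np.sum((ps.pos - start) ** 2, axis=1)))
        assert msd == pytest.approx(6 * p.kBT / p.zeta * t, rel=0.05)

    def test_anchored_beads_do_not_move(self):
        p = SimParams(kBT=0.0)
        f = free_fibril([[0, 0, 5], [2.0, 0, 5]])  # violently stretched
        f.anchored[:] = 1
        st = NetworkState(BIG, [f], [])
        euler_step(st, p, np.random.default_rng(0))
        np.testing.assert_array_equal(st.fibrils[0].positions,
                                      [[0, 0, 5], [2.0, 0, 5]])

    def test_trajectory_determinism(self):
        p = SimParams()
        rng_a = np.random.default_rng(31)
        rng_b = np.random.default_rng(31)
        st_a = random_state(np.random.default_rng(2))
        st_b = copy.deepcopy(st_a)
        for _ in range(50):
            euler_step(st_a, p, rng_a)
            euler_step(st_b, p, rng_b)
        np.testing.assert_array_equal(st_a.fibrils[0].positions,
                                      st_b.fibrils[0].positions)


def clamped_pair_state(n_connectors, tension, params, gap=1.0):
    """Two anchored parallel fibrils with n identical loaded crosslinkers."""
    f0 = Fibril(id=0, positions=[[0, 5, 5], [1, 5, 5]], l0=1.0,
                anchored=[1, 1])
    f1 = Fibril(id=1, positions=[[0, 5 + gap, 5], [1, 5 + gap, 5]], l0=1.0,
                anchored=[1, 1])
    rest = gap - tension / params.kappa_c
    assert rest >= 0
    cons = [Connector("crosslinker", 0, 0.5, 1, 0.5, rest)
            for _ in range(n_connectors)]
    return NetworkState(BIG, [f0, f1], cons)


class TestBellKinetics:
    def test_rate_limits(self):
        p = SimParams()
        assert bell_rate(0.0, p) == pytest.approx(p.k0)
        # F = k_BT/λ gives exactly one e-fold
        assert bell_rate(p.kBT / p.bell_lambda, p) == \
            pytest.approx(math.e * p.k0, rel=1e-12)

    def test_bundlers_never_unbind(self):
        f0 = Fibril(id=0, positions=[[0, 5, 5], [1, 5, 5]], l0=1.0)
        f1 = Fibril(id=1, positions=[[0, 6, 5], [1, 6, 5]], l0=1.0)
        st = NetworkState(BIG, [f0, f1],
                          [Connector("bundler", 0, 0.5, 1, 0.5, 0.0)])
        p = SimParams(k0=1e6, dt=1e-4, kappa_s=1.0, kappa_c=1.0)
        rng = np.random.default_rng(0)
        for _ in range(100):
            bell_unbinding_step(st, p, rng)
        assert st.connectors[0].bound

    def test_mean_lifetime_matches_bell_rate(self):
        """Empirical bound lifetime at held tension F is 1/(k0 e^{Fλ/kBT})
        within 3% over 10⁴ trials."""
        # large drag keeps the stability bound permissive; only kinetics run
        p = SimParams(dt=5e-3, zeta=1.0, kappa_s=1.0, kappa_c=5.0,
                      rebinding_enabled=False)
        tension = 2.0 * p.kBT / p.bell_lambda  # two e-folds of speed-up
        rate = p.k0 * math.exp(2.0)
        st = clamped_pair_state(10_000, tension, p)
        ps = pack_state(st)
        rng = np.random.default_rng(123)
        steps_alive = np.zeros(ps.c_kind.shape[0], dtype=np.int64)
        alive_prev = np.ones_like(steps_alive, dtype=bool)
        for step in range(1, 20000):
            bell_unbinding_step(ps, p, rng)
            alive = ps.c_bound.astype(bool)
            died = alive_prev & ~alive
            steps_alive[died] = step
            alive_prev = alive
            if not alive.any():
                break
        assert not alive_prev.any(), "some bonds never unbound"
        mean_life = steps_alive.mean() * p.dt
        assert mean_life == pytest.approx(1.0 / rate, rel=0.03)

    def test_rebinding_disabled_is_noop(self):
        p = SimParams(rebinding_enabled=False)
        st = clamped_pair_state(5, 0.0, p)
        for c in st.connectors:
            c.bound = False
        rebinding_step(st, p, np.random.default_rng(0))
        assert not any(c.bound for c in st.connectors)

    def test_unbound_with_no_fibril_in_range_stays_unbound(self):
        p = SimParams(capture_radius=0.2)
        f0 = Fibril(id=0, positions=[[0, 5, 5], [1, 5, 5]], l0=1.0,
                    anchored=[1, 1])
        f1 = Fibril(id=1, positions=[[0, 50, 5], [1, 50, 5]], l0=1.0,
                    anchored=[1, 1])
        con = Connector("crosslinker", 0, 0.5, 1, 0.5, 45.0, bound=False)
        st = NetworkState(BIG, [f0, f1], [con])
        rng = np.random.default_rng(0)
        for _ in range(200):
            rebinding_step(st, p, rng)
        assert not st.connectors[0].bound

    def test_two_state_occupancy_closed_form(self):
        """Unloaded bind/unbind equilibrium: occupancy = r/(r+k0) ± 3%."""
        p = SimParams(dt=1e-2, zeta=1.0, kappa_s=1.0, kappa_c=5.0,
                      k0=0.1, rebind_rate=1.0, capture_radius=1.5)
        st = clamped_pair_state(200, 0.0, p)
        ps = pack_state(st)
        rng = np.random.default_rng(77)
        occ = []
        n_steps = 30_000
        for step in range(n_steps):
            bell_unbinding_step(ps, p, rng)
            rebinding_step(ps, p, rng)
            if step > 500:
                occ.append(ps.c_bound.mean())
        target = p.rebind_rate / (p.rebind_rate + p.k0)
        assert np.mean(occ) == pytest.approx(target, rel=0.03)
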