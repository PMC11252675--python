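"""Center-based mechanics: expansion bookkeeping, pair forces, overdamped
relaxation and detachment."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from iceprop.mechanics import (
    MechanicsError,
    MechParams,
    MechState,
    StabilityError,
    detect_detachment,
    freeze_expand,
    net_forces,
    pair_force,
    radius_of_volume,
    step_positions,
)

PARAMS = MechParams()


def scalar_force(d: float, s: float, params: MechParams = PARAMS) -> float:
    """Signed centre-line force magnitude (positive = repulsive) for a pair."""
    reach = params.adh_reach * s
    f = 0.0
    if d < s:
        f += params.c_rep * (1.0 - d / s) ** 2
    if d < reach:
        f -= params.c_adh * (1.0 - d / reach) ** 2
    return f


def two_cell_state(d: float, V: float = 4849.048260815845) -> MechState:
    return MechState(
        positions=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        volumes=np.full(2, V),
        frozen=np.zeros(2, bool),
    )


class TestFreezeExpand:
    def test_no_water_means_no_change(self):
        assert freeze_expand(100.0, 0.0) == 100.0

    def test_printed_expansion_factor(self):
        assert freeze_expand(100.0, 50.0, 1.09) == pytest.approx(104.5)

    def test_isotonic_hepatocyte_expands_on_water_only(self, hepatocyte):
        V = hepatocyte.V_iso
        Vw = (1.0 - hepatocyte.v_b) * V
        got = freeze_expand(V, Vw, 1.09)
        assert got == pytest.approx(V - Vw + 1.09 * Vw)
        assert got == pytest.approx(V * (1.0 + 0.09 * (1.0 - 0.51)))

    def test_rejects_water_exceeding_volume(self):
        with pytest.raises(MechanicsError):
            freeze_expand(10.0, 11.0)


class TestPairForce:
    def test_zero_beyond_adhesive_reach(self):
        f = pair_force(np.zeros(3), np.array([30.0, 0, 0]), 10.5, 10.5, PARAMS)
        assert np.allclose(f, 0.0)

    def test_pure_adhesion_at_membrane_contact(self):
        f = pair_force(np.zeros(3), np.array([21.0, 0, 0]), 10.5, 10.5, PARAMS)
        expect = PARAMS.c_adh * (1.0 - 1.0 / PARAMS.adh_reach) ** 2
        # attractive: the cell at the origin is pulled toward its partner at +x
        assert f[0] == pytest.approx(expect)
        assert f[0] > 0

    def test_antisymmetry(self, rng):
        for _ in range(5):
            pi, pj = rng.uniform(-15, 15, (2, 3))
            fij = pair_force(pi, pj, 10.5, 10.5, PARAMS)
            fji = pair_force(pj, pi, 10.5, 10.5, PARAMS)
            assert np.allclose(fij, -fji, atol=1e-12)

    def test_equilibrium_separation_via_bisection_oracle(self):
        s = 21.0
        d_star = brentq(lambda d: scalar_force(d, s), 0.8 * s, s - 1e-9)
        # pair released from overlap relaxes to d* within 1%
        state = two_cell_state(0.85 * s)
        for _ in range(4000):
            step_positions(state, PARAMS)
        d_final = np.linalg.norm(state.positions[1] - state.positions[0])
        assert d_final == pytest.approx(d_star, rel=0.01)

    def test_net_forces_matches_pairwise_sum(self, rng):
        pos = rng.uniform(-20, 20, (5, 3))
        state = MechState(positions=pos, volumes=np.full(5, 4849.0), frozen=np.zeros(5, bool))
        F = net_forces(state, PARAMS)
        r = state.radii
        for i in range(5):
            acc = np.zeros(3)
            for j in range(5):
                if j != i:
                    acc += pair_force(pos[i], pos[j], r[i], r[j], PARAMS)
            assert np.allclose(F[i], acc, atol=1e-9)


class TestOverdampedStepping:
    def test_isolated_cell_does_not_move(self):
        state = MechState(positions=np.zeros((1, 3)), volumes=[4849.0], frozen=[False])
        step_positions(state, PARAMS)
        assert np.allclose(state.positions, 0.0)

    def test_pair_centroid_invariant(self):
        state = two_cell_state(18.0)
        c0 = state.positions.mean(axis=0).copy()
        for _ in range(200):
            step_positions(state, PARAMS)
        assert np.allclose(state.positions.mean(axis=0), c0, atol=1e-9)

    def test_momentum_conserved_per_step(self, rng):
        pos = rng.uniform(-25, 25, (6, 3))
        state = MechState(positions=pos, volumes=np.full(6, 4849.0), frozen=np.zeros(6, bool))
        F = net_forces(state, PARAMS)
        # net force (= momentum change per unit time) vanishes by antisymmetry
        assert np.linalg.norm(F.sum(axis=0)) < 1e-9

    def test_overlapped_pair_matches_ode_oracle(self):
        s = 21.0
        d0 = 0.8 * s

        def rhs(_t, y):
            # symmetric two-body: separation velocity = 2 F / drag
            return [2.0 * scalar_force(y[0], s) / PARAMS.drag]

        sol = solve_ivp(rhs, (0.0, 1.0), [d0], dense_output=True, rtol=1e-10, atol=1e-12)
        state = two_cell_state(d0)
        seps = []
        for step in range(1, 1001):
            step_positions(state, PARAMS)
            seps.append(np.linalg.norm(state.positions[1] - state.positions[0]))
        seps = np.asarray(seps)
        times = PARAMS.dt_mech * np.arange(1, 1001)
        assert np.all(np.diff(seps) > -1e-12)  # monotone separation
        assert np.allclose(seps, sol.sol(times)[0], atol=0.02)

    def test_force_magnitude_descends_in_quasi_static_relaxation(self):
        state = two_cell_state(0.84 * 21.0)
        mags = []
        for _ in range(500):
            F = net_forces(state, PARAMS)
            mags.append(np.linalg.norm(F[0]))
            step_positions(state, PARAMS)
        assert np.all(np.diff(mags) <= 1e-9)

    def test_instability_signalled(self):
        state = two_cell_state(1.0)  # extreme overlap -> huge repulsion
        with pytest.raises(StabilityError):
            step_positions(state, MechParams(dt_mech=1.0))

    def test_pinned_frozen_cells_mode(self):
        state = two_cell_state(18.0)
        state.frozen[0] = True
        step_positions(state, MechParams(frozen_mobile=False))
        assert np.allclose(state.positions[0], 0.0)
        assert not np.allclose(state.positions[1], [18.0, 0.0, 0.0])


class TestDetachment:
    def test_static_touching_pair_stays_attached(self):
        state = two_cell_state(21.0)
        state.attachments = {(0, 1)}
        report = detect_detachment(state, PARAMS)
        assert report.severed == ()
        assert report.components == ((0, 1),)

    def test_expansion_driven_severing(self):
        # constructed scenario: partner pushed beyond the adhesive reach
        state = two_cell_state(21.0)
        state.attachments = {(0, 1)}
        r = radius_of_volume(state.volumes[0])
        state.positions[1, 0] = PARAMS.adh_reach * 2 * r + 0.1
        report = detect_detachment(state, PARAMS)
        assert report.severed == ((0, 1),)
        assert report.lost_contacts == {0: 1, 1: 1}
        assert report.components == ((0,), (1,))

    def test_threshold_is_exact(self):
        state = two_cell_state(21.0)
        state.attachments = {(0, 1)}
        reach = PARAMS.adh_reach * 2 * radius_of_volume(state.volumes[0])
        state.positions[1, 0] = reach - 1e-9
        assert detect_detachment(state, PARAMS).severed == ()
        state.attachments = {(0, 1)}
        state.positions[1, 0] = reach + 1e-9
        assert detect_detachment(state, PARAMS).severed == ((0, 1),)

    def test_report_idempotent_without_motion(self):
        state = two_cell_state(21.0)
        state.attachments = {(0, 1)}
        state.positions[1, 0] = 40.0
        first = detect_detachment(state, PARAMS)
        second = detect_detachment(state, PARAMS)
        assert first.n_severed == 1
        assert second.n_severed == 0
        assert second.components == first.components


class TestStepConvergence:
    def test_halved_step_changes_disc_positions_below_tenth_micron(self):
        from iceprop.geometry import build_disc_monolayer

        disc = build_disc_monolayer(22)
        finals = []
        for dt in (1e-3, 5e-4):
            params = MechParams(dt_mech=dt)
            state = MechState(
                positions=disc.positions.copy(),
                volumes=np.full(22, 4849.048260815845),
                frozen=np.zeros(22, bool),
            )
            for _ in range(int(round(2.0 / dt))):
                step_positions(state, params)
            finals.append(state.positions.copy())
        assert np.abs(finals[0] - finals[1]).max() < 0.1
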