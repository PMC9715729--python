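"""Minimum-image unwrapping, phase partitioning, the per-step MSD
estimator, and the temperature fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_trajectory
from fibrilsorb.constants import KELVIN_OFFSET, R_GAS
from fibrilsorb.diffusion import (
    EmptyPhaseError,
    PHASES,
    PhaseSteps,
    arrhenius_fit,
    estimate_D,
    linear_fit_D_vs_T,
    partition_steps,
    two_interval_D,
    unwrap_step,
)
from fibrilsorb.geometry import SorptionLabels


def labels_for(traj, arrays):
    return [
        SorptionLabels(time=t, sorbed=np.asarray(a, bool))
        for t, a in zip(traj.times, arrays)
    ]


class TestUnwrapStep:
    def test_wrap_across_boundary(self):
        d = unwrap_step(np.array([0.1, 0, 0]), np.array([9.9, 0, 0]), np.array([10.0, 10, 10]))
        np.testing.assert_allclose(d, [-0.2, 0.0, 0.0], atol=1e-12)

    def test_no_wrap_is_plain_difference(self):
        d = unwrap_step(np.array([1.0, 2, 3]), np.array([1.5, 2.5, 2.0]), np.array([10.0, 10, 10]))
        np.testing.assert_allclose(d, [0.5, 0.5, -1.0])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0, 9.999), min_size=3, max_size=3),
        st.lists(st.floats(0, 9.999), min_size=3, max_size=3),
    )
    def test_matches_27_image_bruteforce(self, a, b):
        box = np.array([10.0, 10.0, 10.0])
        a, b = np.array(a), np.array(b)
        d = unwrap_step(a, b, box)
        images = np.array(
            [b + box * np.array([i, j, k]) - a for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        best = images[np.argmin((images**2).sum(axis=1))]
        assert (d**2).sum() == pytest.approx((best**2).sum(), abs=1e-9)


class TestPartitionSteps:
    def test_single_molecule_phase_sequence(self):
        traj = make_trajectory(n_frames=3, n_waters=1, seed=1)
        steps = partition_steps(traj, labels_for(traj, [[0], [0], [1]]))
        assert steps.phase.tolist() == ["WW", "WC"]

    def test_all_sorbed_gives_all_CC(self):
        traj = make_trajectory(n_frames=5, n_waters=3, seed=2)
        steps = partition_steps(traj, labels_for(traj, [[1, 1, 1]] * 5))
        assert steps.counts() == {"WW": 0, "CC": 12, "WC": 0, "CW": 0}

    def test_random_labels_match_pairwise_enumeration(self, rng):
        traj = make_trajectory(n_frames=8, n_waters=6, seed=3)
        arrays = rng.random((8, 6)) < 0.5
        steps = partition_steps(traj, labels_for(traj, arrays))
        expect = {p: 0 for p in PHASES}
        for f in range(7):
            for m in range(6):
                key = ("C" if arrays[f, m] else "W") + ("C" if arrays[f + 1, m] else "W")
                expect["WW" if key == "WW" else "CC" if key == "CC" else "WC" if key == "WC" else "CW"] += 1
        assert steps.counts() == expect

    def test_conservation_of_steps(self, rng):
        """n_WW + n_CC + n_WC + n_CW = (frames - 1) x molecules, exactly."""
        traj = make_trajectory(n_frames=11, n_waters=7, seed=4)
        arrays = rng.random((11, 7)) < 0.3
        steps = partition_steps(traj, labels_for(traj, arrays))
        assert sum(steps.counts().values()) == 10 * 7
        assert len(steps) == 10 * 7

    def test_label_misalignment_rejected(self):
        traj = make_trajectory(n_frames=3, n_waters=2)
        with pytest.raises(ValueError, match="label"):
            partition_steps(traj, labels_for(traj, [[0, 0], [0, 0]])[:2])


def brownian_steps(n_mol, n_steps, D, dt=10.0, seed=0, phase="WW"):
    """Independent Gaussian steps with per-axis variance 2 D dt."""
    r = np.random.default_rng(seed)
    disp = r.normal(0.0, np.sqrt(2 * D * dt), size=(n_steps, n_mol, 3))
    sq = (disp**2).sum(axis=2)
    f_idx = np.repeat(np.arange(n_steps), n_mol)
    return PhaseSteps(
        molecule=np.tile(np.arange(n_mol), n_steps),
        t_start=f_idx * dt,
        phase=np.full(n_steps * n_mol, phase),
        sq_disp=sq.reshape(-1),
        dt=dt,
    )


class TestEstimateD:
    def test_single_step_arithmetic(self):
        steps = PhaseSteps(
            molecule=np.array([0]),
            t_start=np.array([0.0]),
            phase=np.array(["WW"]),
            sq_disp=np.array([0.6]),
            dt=10.0,
        )
        e = estimate_D(steps, "WW")
        assert e.D_nm2_ps == pytest.approx(0.01)
        assert e.D == pytest.approx(10.0)  # in 1e-5 cm^2/s
        assert e.t_tot == 10.0 and e.n_steps == 1

    def test_stationary_molecules_give_zero(self):
        steps = brownian_steps(5, 20, 1e-3, seed=1)
        steps.sq_disp[:] = 0.0
        assert estimate_D(steps, "WW").D == 0.0

    def test_brownian_simulation_oracle(self):
        """10^4 particles x 100 steps at D = 3.7e-3 nm^2/ps: within 3 SE."""
        d_true = 3.7e-3
        steps = brownian_steps(10_000, 100, d_true, seed=42)
        e = estimate_D(steps, "WW")
        se = e.uncertainty / 1e3  # nm^2/ps
        assert abs(e.D_nm2_ps - d_true) < 3 * se
        assert se < 0.01 * d_true

    def test_empty_phase_names_phase(self):
        steps = brownian_steps(2, 2, 1e-3)
        with pytest.raises(EmptyPhaseError, match="CC"):
            estimate_D(steps, "CC")

    def test_pooled_estimator_equals_per_molecule_msd(self):
        """Eq-style pooled estimator == mean per-molecule lag-1 MSD / 6 dt."""
        steps = brownian_steps(50, 40, 2e-3, seed=7)
        e = estimate_D(steps, "WW")
        per_mol = [
            steps.sq_disp[steps.molecule == m].mean() for m in range(50)
        ]
        assert e.D_nm2_ps == pytest.approx(np.mean(per_mol) / (6 * steps.dt), rel=1e-12)

    def test_bias_decreases_with_step_count(self):
        """|D_hat - D| shrinks as steps x10 (mean over 20 seeds)."""
        d_true = 2.0e-3
        mean_abs_err = []
        for n_steps in (20, 200, 2000):
            errs = [
                abs(estimate_D(brownian_steps(10, n_steps, d_true, seed=s), "WW").D_nm2_ps - d_true)
                for s in range(20)
            ]
            mean_abs_err.append(np.mean(errs))
        assert mean_abs_err[0] > mean_abs_err[1] > mean_abs_err[2]


class TestMultiLagDiagnostic:
    def test_brownian_msd_grows_linearly_with_lag(self):
        """Free Brownian motion: MSD(lag) ~ 6 D lag dt for every lag."""
        from fibrilsorb.diffusion import multi_lag_msd
        from conftest import make_trajectory
        from fibrilsorb.trajio import Trajectory

        d_true, dt, n_frames, n_mol = 2.0e-3, 10.0, 400, 300
        r = np.random.default_rng(12)
        steps = r.normal(0, np.sqrt(2 * d_true * dt), size=(n_frames - 1, n_mol, 3))
        pos = np.concatenate([np.zeros((1, n_mol, 3)), np.cumsum(steps, axis=0)]) + 50.0
        traj = Trajectory(
            times=np.arange(n_frames) * dt,
            box=np.array([1e4, 1e4, 1e4]),  # effectively unwrapped
            positions=pos,
            roles=np.array(["water-oxygen"] * n_mol),
            mol_index=np.arange(n_mol),
        )
        curve = multi_lag_msd(traj, max_lag=5)
        for lag_ps, msd in zip(curve["lag_ps"], curve["msd_nm2"]):
            assert msd == pytest.approx(6 * d_true * lag_ps, rel=0.05)


class TestTwoIntervalD:
    def test_equal_steps_give_identical_halves(self):
        steps = brownian_steps(1, 10, 1e-3, seed=0)
        steps.sq_disp[:] = 0.12
        tw = two_interval_D(steps, "WW")
        assert tw.first.D == tw.second.D
        assert tw.ratio == 1.0

    def test_doubled_second_half_displacements(self):
        steps = brownian_steps(1, 10, 1e-3, seed=0)
        steps.sq_disp[:] = np.where(np.arange(10) < 5, 0.1, 0.2)
        tw = two_interval_D(steps, "WW")
        assert tw.ratio == pytest.approx(2.0)

    def test_homogeneous_brownian_halves_agree(self):
        steps = brownian_steps(200, 200, 3.7e-3, seed=9)
        tw = two_interval_D(steps, "WW")
        se = np.hypot(tw.first.uncertainty, tw.second.uncertainty)
        assert abs(tw.first.D - tw.second.D) < 3 * se

    def test_needs_two_steps(self):
        steps = brownian_steps(1, 1, 1e-3)
        with pytest.raises(EmptyPhaseError):
            two_interval_D(steps, "WW")


class TestTemperatureFits:
    def test_exact_arrhenius_recovery(self):
        """Synthetic D(T) with E_A = 17.1 kJ/mol is recovered to machine precision."""
        e_true, d0 = 17.1, 50.0
        T = np.array([7.0, 17.0, 27.0, 37.0])
        D = d0 * np.exp(-e_true * 1000 / (R_GAS * (T + KELVIN_OFFSET)))
        e_a, ln_d0 = arrhenius_fit(T, D)
        assert e_a == pytest.approx(e_true, rel=1e-9)
        assert ln_d0 == pytest.approx(np.log(d0), rel=1e-9)

    def test_constant_D_gives_zero_activation_energy(self):
        e_a, _ = arrhenius_fit([25.0, 50.0, 75.0], [4.0, 4.0, 4.0])
        assert e_a == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        """(25 C, 3.7) and (100 C, 10.4): E_A = R ln(D2/D1)/(1/T1 - 1/T2)."""
        e_a, _ = arrhenius_fit([25.0, 100.0], [3.7, 10.4])
        t1, t2 = 25.0 + KELVIN_OFFSET, 100.0 + KELVIN_OFFSET
        closed = R_GAS * np.log(10.4 / 3.7) / (1 / t1 - 1 / t2) / 1000.0
        assert e_a == pytest.approx(closed, rel=1e-12)

    def test_arrhenius_input_validation(self):
        with pytest.raises(ValueError):
            arrhenius_fit([25.0], [3.7])
        with pytest.raises(ValueError):
            arrhenius_fit([25.0, 50.0], [3.7, -1.0])

    def test_linear_fit_noiseless_recovery(self):
        """Points on D = 1.3 + 0.09 T are fitted exactly."""
        T = np.array([25.0, 50.0, 90.0, 100.0])
        intercept, slope = linear_fit_D_vs_T(T, 1.3 + 0.09 * T)
        assert intercept == pytest.approx(1.3, rel=1e-10)
        assert slope == pytest.approx(0.09, rel=1e-10)

    def test_linear_fit_matches_normal_equations(self, rng):
        T = rng.random(12) * 80 + 10
        D = rng.random(12) * 5
        intercept, slope = linear_fit_D_vs_T(T, D)
        X = np.column_stack([np.ones_like(T), T])
        beta = np.linalg.solve(X.T @ X, X.T @ D)
        assert intercept == pytest.approx(beta[0], rel=1e-9)
        assert slope == pytest.approx(beta[1], rel=1e-9)

    def test_linear_fit_needs_two_temperatures(self):
        with pytest.raises(ValueError):
            linear_fit_D_vs_T([25.0, 25.0], [1.0, 2.0])
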