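"""Phase-resolved diffusion-coefficient estimation.

Every frame-to-frame displacement of every water molecule is one step.
A step is assigned a phase from the sorbed/bulk labels at its two
endpoints: WW bulk->bulk, CC sorbed->sorbed, WC bulk->sorbed, CW
sorbed->bulk.  Within a phase P the estimator is the per-step (lag-1)
accumulated squared displacement

    MSD_P = sum of |r(t+dt) - r(t)|^2 over the n_P steps in P
          = 6 D_P t_tot,P,      t_tot,P = n_P * dt,

so D_P = MSD_P / (6 n_P dt) in nm^2/ps, reported in 1e-5 cm^2/s.  Steps
are unwrapped with the minimum-image convention, which is valid while a
true per-step displacement stays below half a box edge per axis (the
synthetic trajectories are constructed to respect this).

Temperature dependence: an Arrhenius fit ln D = ln D0 - E_A/(R T_K) and a
plain linear fit D = b + m * T_C are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import KELVIN_OFFSET, NM2_PS_TO_1E5_CM2_S, R_GAS
from .geometry import SorptionLabels
from .trajio import ROLE_WATER_OXYGEN, Trajectory

__all__ = [
    "PHASES",
    "PhaseSteps",
    "DiffusionEstimate",
    "TwoIntervalResult",
    "TemperatureFit",
    "unwrap_step",
    "partition_steps",
    "estimate_D",
    "two_interval_D",
    "multi_lag_msd",
    "arrhenius_fit",
    "linear_fit_D_vs_T",
]

PHASES = ("WW", "CC", "WC", "CW")


def unwrap_step(pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement pos_b - pos_a, each component in (-L/2, L/2]."""
    box = np.asarray(box, dtype=float)
    if (box <= 0).any():
        raise ValueError(f"box lengths must be positive, got {box}")
    d = np.asarray(pos_b, dtype=float) - np.asarray(pos_a, dtype=float)
    return d + box * np.floor(0.5 - d / box)


@dataclass
class PhaseSteps:
    """All per-molecule frame-to-frame steps with phase tags (array-of-columns)."""

    molecule: np.ndarray  # (n_steps,) int
    t_start: np.ndarray  # (n_steps,) ps
    phase: np.ndarray  # (n_steps,) strings from PHASES
    sq_disp: np.ndarray  # (n_steps,) nm^2
    dt: float  # ps

    def __len__(self) -> int:
        return len(self.sq_disp)

    def for_phase(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}; valid: {PHASES}")
        return self.sq_disp[self.phase == phase]

    def counts(self) -> dict[str, int]:
        return {p: int((self.phase == p).sum()) for p in PHASES}


@dataclass
class DiffusionEstimate:
    phase: str
    msd: float  # summed squared displacement, nm^2
    n_steps: int
    t_tot: float  # ps, = n_steps * dt
    D: float  # 1e-5 cm^2/s
    uncertainty: float  # 1e-5 cm^2/s, naive SE of per-step squared displacements

    @property
    def D_nm2_ps(self) -> float:
        return self.D / NM2_PS_TO_1E5_CM2_S


@dataclass
class TwoIntervalResult:
    first: DiffusionEstimate
    second: DiffusionEstimate

    @property
    def ratio(self) -> float:
        return self.second.D / self.first.D


@dataclass
class TemperatureFit:
    temperatures: np.ndarray  # deg C
    D: np.ndarray  # 1e-5 cm^2/s
    slope: float  # linear fit D = intercept + slope * T_C
    intercept: float
    E_A: float  # kJ/mol, Arrhenius
    ln_D0: float


def partition_steps(traj: Trajectory, labels: list[SorptionLabels]) -> PhaseSteps:
    """One phase-tagged step per water molecule per consecutive frame pair."""
    if len(labels) != traj.n_frames:
        raise ValueError(f"{len(labels)} label frames for {traj.n_frames} trajectory frames")
    water = traj.roles == ROLE_WATER_OXYGEN
    n_mol = int(water.sum())
    for f, lab in enumerate(labels):
        if len(lab.sorbed) != n_mol:
            raise ValueError(
                f"labels at frame {f} cover {len(lab.sorbed)} molecules, trajectory has {n_mol}"
            )
    order = np.argsort(traj.mol_index[water], kind="stable")
    wpos = traj.positions[:, water, :][:, order, :]  # (F, M, 3) in molecule order
    mols = traj.mol_index[water][order]
    dt = traj.frame_interval
    if traj.n_frames < 2:
        empty = np.array([])
        return PhaseSteps(empty.astype(int), empty, empty.astype(str), empty, dt)

    lab = np.stack([l.sorbed for l in labels])  # (F, M) bool
    d = wpos[1:] - wpos[:-1]
    d += traj.box * np.floor(0.5 - d / traj.box)
    sq = (d**2).sum(axis=2)  # (F-1, M)
    start, end = lab[:-1], lab[1:]
    phase = np.where(
        start,
        np.where(end, "CC", "CW"),
        np.where(end, "WC", "WW"),
    )
    f_idx = np.repeat(np.arange(traj.n_frames - 1), n_mol)
    return PhaseSteps(
        molecule=np.tile(mols, traj.n_frames - 1),
        t_start=traj.times[0] + f_idx * dt,
        phase=phase.reshape(-1),
        sq_disp=sq.reshape(-1),
        dt=dt,
    )


class EmptyPhaseError(ValueError):
    pass


def _estimate(sq: np.ndarray, phase: str, dt: float) -> DiffusionEstimate:
    n = len(sq)
    if n < 1:
        raise EmptyPhaseError(f"no steps in phase {phase}: cannot estimate D")
    msd = float(sq.sum())
    t_tot = n * dt
    d_nm2_ps = msd / (6.0 * t_tot)
    se = float(sq.std(ddof=1) / np.sqrt(n)) / (6.0 * dt) if n > 1 else float("nan")
    return DiffusionEstimate(
        phase=phase,
        msd=msd,
        n_steps=n,
        t_tot=t_tot,
        D=d_nm2_ps * NM2_PS_TO_1E5_CM2_S,
        uncertainty=se * NM2_PS_TO_1E5_CM2_S if n > 1 else float("nan"),
    )


def estimate_D(steps: PhaseSteps, phase: str, dt: float | None = None) -> DiffusionEstimate:
    """Accumulated-squared-displacement estimator for one phase.

    The uncertainty is the naive standard error of the per-step squared
    displacements propagated through the estimator (steps treated as
    independent).
    """
    dt = steps.dt if dt is None else dt
    return _estimate(steps.for_phase(phase), phase, dt)


def two_interval_D(steps: PhaseSteps, phase: str, dt: float | None = None) -> TwoIntervalResult:
    """Consistency check: the estimator applied to each half of the phase time.

    Steps of the phase are ordered by accumulated phase time (i.e. by
    start time, then molecule, as they entered the accumulator); the
    first n/2 steps form interval (0, t_tot/2], the rest (t_tot/2, t_tot].
    """
    dt = steps.dt if dt is None else dt
    mask = steps.phase == phase
    order = np.lexsort((steps.molecule[mask], steps.t_start[mask]))
    sq = steps.sq_disp[mask][order]
    n = len(sq)
    if n < 2:
        raise EmptyPhaseError(f"phase {phase} has {n} step(s); two intervals need >= 2")
    half = n // 2
    return TwoIntervalResult(
        first=_estimate(sq[:half], phase, dt),
        second=_estimate(sq[half:], phase, dt),
    )


def multi_lag_msd(traj: Trajectory, max_lag: int = 10) -> dict[str, np.ndarray]:
    """Diagnostic multi-lag MSD curve over all waters (not phase-resolved).

    Not used for any reported D; provided to eyeball linearity of the MSD.
    """
    water = traj.roles == ROLE_WATER_OXYGEN
    wpos = traj.positions[:, water, :]
    # Unwrap the whole trajectory once via cumulative minimum-image steps.
    d = wpos[1:] - wpos[:-1]
    d += traj.box * np.floor(0.5 - d / traj.box)
    unwrapped = np.concatenate([wpos[:1], wpos[:1] + np.cumsum(d, axis=0)])
    lags = np.arange(1, min(max_lag, traj.n_frames - 1) + 1)
    msd = np.array(
        [float(((unwrapped[lag:] - unwrapped[:-lag]) ** 2).sum(axis=2).mean()) for lag in lags]
    )
    return {"lag_ps": lags * traj.frame_interval, "msd_nm2": msd}


def arrhenius_fit(temperatures_C, D_values) -> tuple[float, float]:
    """Fit ln D = ln D0 - E_A/(R T_K) by ordinary least squares.

    Returns (E_A in kJ/mol, ln D0).  D may be in any consistent unit;
    ln D0 is in the log of that unit.
    """
    T = np.asarray(temperatures_C, dtype=float)
    D = np.asarray(D_values, dtype=float)
    if len(np.unique(T)) < 2:
        raise ValueError("Arrhenius fit needs at least 2 distinct temperatures")
    if (D <= 0).any():
        raise ValueError("all D values must be positive for an Arrhenius fit")
    x = 1.0 / (R_GAS * (T + KELVIN_OFFSET))
    res = stats.linregress(x, np.log(D))
    return -res.slope / 1000.0, float(res.intercept)


def linear_fit_D_vs_T(temperatures_C, D_values) -> tuple[float, float]:
    """Ordinary least squares D = intercept + slope * T (T in deg C).

    Returns (intercept, slope) in the units of D and D per deg C.
    """
    T = np.asarray(temperatures_C, dtype=float)
    D = np.asarray(D_values, dtype=float)
    if len(np.unique(T)) < 2:
        raise ValueError("linear fit needs at least 2 distinct temperatures")
    res = stats.linregress(T, D)
    return float(res.intercept), float(res.slope)


def temperature_fit(temperatures_C, D_values) -> TemperatureFit:
    """Convenience bundle of the linear and Arrhenius fits."""
    intercept, slope = linear_fit_D_vs_T(temperatures_C, D_values)
    e_a, ln_d0 = arrhenius_fit(temperatures_C, D_values)
    return TemperatureFit(
        temperatures=np.asarray(temperatures_C, dtype=float),
        D=np.asarray(D_values, dtype=float),
        slope=slope,
        intercept=intercept,
        E_A=e_a,
        ln_D0=ln_d0,
    )
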