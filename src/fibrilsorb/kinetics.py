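"""Residence-time statistics of sorbed water and gravimetric swelling.

A residence run is an unbroken sequence of frames in which a molecule is
sorbed; runs are broken by a single desorbed frame unless a minimum-gap
smoothing is requested (off by default).  Swelling S relates sorbed-water
mass to dry fibril mass:

    S = (W_t / W_O) * 100 %

with W_t the sorbed-water mass and W_O the dry mass.  The experimental
form of the same relation, S = (W_t/W_O - 1) * 100 % with W_t the wet
weight, is exposed as ``swelling_from_weights``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import N_AVOGADRO

__all__ = [
    "ResidenceStats",
    "SwellingValue",
    "residence_stats",
    "swelling",
    "swelling_from_weights",
    "moving_average",
]


@dataclass
class ResidenceStats:
    dt: float  # ps per frame
    total_time: np.ndarray  # (M,) ps sorbed per molecule
    runs: list[np.ndarray]  # per molecule, continuous sorbed run lengths, ps
    mean_total: float  # ps
    sd_total: float  # ps
    duration: float  # ps covered by the label series

    @property
    def fraction_of_simulation(self) -> float:
        """Mean total sorbed time as a fraction of the simulated duration."""
        return self.mean_total / self.duration if self.duration > 0 else 0.0

    def run_length_histogram(self, bins=20):
        all_runs = np.concatenate([r for r in self.runs if len(r)] or [np.array([])])
        return np.histogram(all_runs, bins=bins) if len(all_runs) else (np.array([]), np.array([]))

    def all_runs(self) -> np.ndarray:
        return np.concatenate([r for r in self.runs if len(r)] or [np.array([])])


def _close_gaps(col: np.ndarray, min_gap: int) -> np.ndarray:
    """Treat desorbed gaps of <= min_gap frames between sorbed frames as sorbed."""
    col = col.copy()
    idx = np.flatnonzero(col)
    if len(idx) < 2:
        return col
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= min_gap + 1:
            col[a:b] = True
    return col


def residence_stats(labels: np.ndarray, dt: float, min_gap: int = 0) -> ResidenceStats:
    """Per-molecule sorbed totals and continuous run lengths.

    ``labels`` is (n_frames, n_molecules) boolean, True = sorbed.  Each
    sorbed frame contributes dt ps; a run of L consecutive sorbed frames
    is a residence of L*dt ps.  ``min_gap`` > 0 bridges desorbed gaps of
    up to that many frames (optional smoothing, default off).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.ndim != 2:
        raise ValueError(f"labels must be (frames, molecules), got shape {labels.shape}")
    n_frames, n_mol = labels.shape
    runs: list[np.ndarray] = []
    totals = np.empty(n_mol)
    for m in range(n_mol):
        col = labels[:, m]
        if min_gap > 0:
            col = _close_gaps(col, min_gap)
        padded = np.concatenate([[False], col, [False]]).astype(int)
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        lengths = (ends - starts) * dt
        runs.append(lengths)
        totals[m] = lengths.sum()
    return ResidenceStats(
        dt=dt,
        total_time=totals,
        runs=runs,
        mean_total=float(totals.mean()),
        sd_total=float(totals.std()),
        duration=n_frames * dt,
    )


@dataclass(frozen=True)
class SwellingValue:
    S: float  # percent
    W_t: float  # sorbed-water mass, g
    W_O: float  # dry fibril mass, g


def swelling(
    mean_sorbed_count: float, water_molar_mass: float, fibril_mass: float
) -> SwellingValue:
    """Gravimetric swelling from a mean sorbed-molecule count.

    W_t = count * molar_mass / N_A; S = W_t / W_O * 100 %.  This is the
    modelling convention: the sorbed water mass over the dry fibril mass.
    """
    if fibril_mass <= 0:
        raise ValueError(f"fibril mass must be > 0 g, got {fibril_mass}")
    if mean_sorbed_count < 0:
        raise ValueError("sorbed count cannot be negative")
    w_t = mean_sorbed_count * water_molar_mass / N_AVOGADRO
    return SwellingValue(S=w_t / fibril_mass * 100.0, W_t=w_t, W_O=fibril_mass)


def swelling_from_weights(weight_t: float, weight_dry: float) -> float:
    """Experimental swelling S = (W_t/W_O - 1) * 100 % from weighed masses."""
    if weight_dry <= 0:
        raise ValueError(f"dry weight must be > 0, got {weight_dry}")
    return (weight_t / weight_dry - 1.0) * 100.0


def moving_average(series, n: int) -> np.ndarray:
    """Centred moving average with the window truncated at the boundaries.

    Index i averages series[i - (n-1)//2 : i + n//2 + 1] clipped to the
    series; output length equals input length.  n = 1 is the identity.
    """
    if n < 1:
        raise ValueError(f"window must be >= 1, got {n}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if n == 1:
        return x.copy()
    half_lo = (n - 1) // 2
    half_hi = n // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(len(x))
    lo = np.maximum(i - half_lo, 0)
    hi = np.minimum(i + half_hi, len(x) - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
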