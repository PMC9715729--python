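"""Per-frame geometric analysis of water around the fibril.

The fibril is represented by its carbon atoms, water by its oxygen atoms.
Three analyses mirror the modelling workflow: k-nearest-neighbour
water-cellulose distances, convex-hull fibril volume, and sorbed/bulk
classification of water oxygens by Delaunay point location (a water is
"sorbed" iff it lies inside, or on the boundary of, the carbon cloud's
convex hull).

Geometry here is non-periodic: the fibril is assumed compact within the
box, and carbon clouds spanning more than half of any box edge are
rejected when a box is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree

__all__ = [
    "NNSummary",
    "SorptionLabels",
    "DegenerateGeometryError",
    "mean_nn_distance",
    "hull_volume",
    "classify_sorbed",
    "label_trajectory",
    "occupancy_series",
]

#: boundary tolerance for point location, nm
BOUNDARY_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Carbon cloud is collinear/coplanar and admits no 3D triangulation."""


@dataclass
class NNSummary:
    k: int
    mean_distance: float  # nm, over all carbons and all k neighbours
    per_carbon_distances: np.ndarray  # (n_carbons, k), ascending per row


@dataclass
class SorptionLabels:
    time: float  # ps
    sorbed: np.ndarray  # (n_waters,) bool, molecule-index order

    @property
    def n_sorbed(self) -> int:
        return int(self.sorbed.sum())


def _check_cloud(points: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError(f"{name}: empty point set")
    return pts


def mean_nn_distance(carbons: np.ndarray, oxygens: np.ndarray, k: int = 50) -> NNSummary:
    """Mean distance from each carbon to its k nearest water oxygens.

    The mean pools all carbons and all k neighbours.  k defaults to 50,
    the neighbour count used to track hydration during swelling.
    """
    carbons = _check_cloud(carbons, "carbons")
    oxygens = _check_cloud(oxygens, "oxygens")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(oxygens):
        raise ValueError(f"k={k} exceeds the {len(oxygens)} available oxygens")
    dist, _ = cKDTree(oxygens).query(carbons, k=k)
    dist = np.atleast_2d(dist.reshape(len(carbons), k))
    return NNSummary(k=k, mean_distance=float(dist.mean()), per_carbon_distances=dist)


def hull_volume(carbons: np.ndarray) -> float:
    """Convex-hull volume of the carbon point cloud, nm^3."""
    carbons = _check_cloud(carbons, "carbons")
    try:
        return float(ConvexHull(carbons).volume)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"carbon cloud of {len(carbons)} points is degenerate (coplanar/collinear?)"
        ) from exc


def _triangulate(carbons: np.ndarray) -> Delaunay:
    try:
        return Delaunay(carbons)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"carbon cloud of {len(carbons)} points admits no 3D triangulation"
        ) from exc


def _check_span(carbons: np.ndarray, box: np.ndarray) -> None:
    span = carbons.max(axis=0) - carbons.min(axis=0)
    box = np.asarray(box, dtype=float)
    if (span > 0.5 * box * (1.0 + 1e-9)).any():
        raise ValueError(
            f"carbon cloud spans {span} nm, more than half the box {box} nm; "
            "non-periodic geometry operations are invalid for such a cloud"
        )


def classify_sorbed(
    carbons: np.ndarray,
    oxygens: np.ndarray,
    time: float = 0.0,
    box: np.ndarray | None = None,
    triangulation: Delaunay | None = None,
    shell_cutoff: float = 0.0,
) -> SorptionLabels:
    """Label each water oxygen sorbed/bulk by Delaunay point location.

    A water is sorbed iff it falls in some simplex of the triangulation of
    the carbon cloud, i.e. inside the carbon convex hull; points within
    BOUNDARY_TOL of a facet count as sorbed.  ``shell_cutoff`` > 0 nm adds
    an optional distance-shell criterion (water within that distance of
    any carbon also counts as sorbed) for sensitivity analysis; it is off
    by default and not part of the headline classification.

    Passing a prebuilt ``triangulation`` skips retriangulating a static
    fibril every frame.
    """
    oxygens = _check_cloud(oxygens, "oxygens")
    if triangulation is None:
        carbons = _check_cloud(carbons, "carbons")
        if box is not None:
            _check_span(carbons, box)
        triangulation = _triangulate(carbons)
    sorbed = triangulation.find_simplex(oxygens, tol=BOUNDARY_TOL) >= 0
    if shell_cutoff > 0.0:
        d, _ = cKDTree(triangulation.points).query(oxygens, k=1)
        sorbed = sorbed | (d <= shell_cutoff)
    return SorptionLabels(time=time, sorbed=sorbed)


def label_trajectory(traj, shell_cutoff: float = 0.0) -> list[SorptionLabels]:
    """Classify every frame of a trajectory (static-fibril fast path).

    If the carbon positions are identical in all frames the triangulation
    is built once.
    """
    from .trajio import ROLE_FIBRIL_CARBON, ROLE_WATER_OXYGEN, select

    first = traj.frame(0)
    carbons0 = select(first, ROLE_FIBRIL_CARBON)
    if len(carbons0) == 0:
        raise ValueError("trajectory has no fibril carbons to triangulate")
    _check_span(carbons0, first.box)
    static = all(
        np.array_equal(select(traj.frame(f), ROLE_FIBRIL_CARBON), carbons0)
        for f in range(traj.n_frames)
    )
    tri = _triangulate(carbons0) if static else None
    labels = []
    for frame in traj:
        carbons = carbons0 if static else select(frame, ROLE_FIBRIL_CARBON)
        labels.append(
            classify_sorbed(
                carbons,
                select(frame, ROLE_WATER_OXYGEN),
                time=frame.time,
                box=frame.box,
                triangulation=tri,
                shell_cutoff=shell_cutoff,
            )
        )
    return labels


def occupancy_series(labels: list[SorptionLabels]):
    """Per-frame sorbed counts with running mean and standard deviation.

    Returns a dict of arrays: time, count, running_mean, running_sd (the
    running statistics are over frames up to and including each frame;
    sd is the population sd, 0 for a single frame).
    """
    times = np.array([lab.time for lab in labels])
    counts = np.array([lab.n_sorbed for lab in labels], dtype=float)
    csum = np.cumsum(counts)
    n = np.arange(1, len(counts) + 1)
    running_mean = csum / n
    csq = np.cumsum(counts**2)
    var = np.maximum(csq / n - running_mean**2, 0.0)
    return {
        "time": times,
        "count": counts.astype(int),
        "running_mean": running_mean,
        "running_sd": np.sqrt(var),
    }
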