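"""Convex trap regions for the Brownian trapping simulator.

A region answers three geometric questions, vectorized over points:
membership, facet-plane distance (negative inside), and mirror
reflection across the nearest facet plane (inward or outward).  Two
concrete regions are provided: an axis-aligned block and the convex hull
of a point cloud (the fibril carbons).

The capture shell of width ``s`` is the plane-offset dilation: every
facet half-space is pushed outward by s.  For a block this is the block
expanded by s on every side; for a hull it is the offset polytope, whose
volume is computed exactly from the half-space intersection.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection

__all__ = ["BlockRegion", "HullRegion", "make_region"]


class _ConvexRegion:
    """Shared facet-plane machinery; subclasses provide normals/offsets.

    Facets are half-spaces n.x <= b with outward unit normals n; a point
    is inside iff all constraints hold.
    """

    normals: np.ndarray  # (F, 3) outward unit normals
    offsets: np.ndarray  # (F,)
    centroid: np.ndarray  # (3,) an interior point

    def plane_excess(self, points: np.ndarray) -> np.ndarray:
        """max_i (n_i.x - b_i): negative inside, ~distance outside."""
        pts = np.atleast_2d(points)
        return (pts @ self.normals.T - self.offsets).max(axis=1)

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.plane_excess(points) <= tol

    def in_shell(self, points: np.ndarray, shell: float) -> np.ndarray:
        """Outside the region but inside its plane-offset dilation."""
        e = self.plane_excess(points)
        return (e > 0.0) & (e <= shell)

    def reflect_out(self, points: np.ndarray) -> np.ndarray:
        """Mirror interior points across their nearest facet plane (always exits)."""
        pts = np.atleast_2d(points).copy()
        excess = pts @ self.normals.T - self.offsets  # (N, F), negative rows inside
        nearest = excess.argmax(axis=1)
        depth = excess[np.arange(len(pts)), nearest]  # negative
        pts -= 2.0 * depth[:, None] * self.normals[nearest]
        return pts

    def reflect_in(self, points: np.ndarray, max_iter: int = 4) -> np.ndarray:
        """Mirror exterior points across their most-violated facet plane.

        Iterates a few times for corner cases; points still outside fall
        back to a bisection pull toward the centroid.
        """
        pts = np.atleast_2d(points).copy()
        for _ in range(max_iter):
            excess = pts @ self.normals.T - self.offsets
            worst = excess.argmax(axis=1)
            depth = excess[np.arange(len(pts)), worst]
            out = depth > 0.0
            if not out.any():
                return pts
            pts[out] -= 2.0 * depth[out, None] * self.normals[worst[out]]
        still = ~self.contains(pts)
        if still.any():
            pts[still] = self._pull_inside(pts[still])
        return pts

    def fold_inward(self, start: np.ndarray, proposed: np.ndarray, max_iter: int = 6) -> np.ndarray:
        """Billiard reflection of a step that exits the region.

        For each (start inside, proposed outside) pair the segment is
        traced to its first facet crossing and the remainder mirrored
        across that facet, iterating for multiple bounces.  Points still
        outside after ``max_iter`` bounces fall back to a centroid pull.
        """
        start = np.atleast_2d(start)
        pts = np.atleast_2d(proposed).copy()
        cur = start.copy()
        active = ~self.contains(pts)
        for _ in range(max_iter):
            if not active.any():
                break
            a, p = cur[active], pts[active]
            d = p - a
            num = self.offsets - a @ self.normals.T  # (n, F) slack at start, >= ~0
            den = d @ self.normals.T
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(den > 1e-300, num / den, np.inf)
            t = np.where(t >= -1e-12, t, np.inf)
            facet = t.argmin(axis=1)
            rows = np.arange(len(a))
            t_star = np.clip(t[rows, facet], 0.0, 1.0)
            hit = a + t_star[:, None] * d
            n_hat = self.normals[facet]
            excess = ((p - hit) * n_hat).sum(axis=1)
            folded = p - 2.0 * excess[:, None] * n_hat
            pts[active] = folded
            cur[active] = hit
            nxt = active.copy()
            nxt[active] = ~self.contains(folded)
            active = nxt
        if active.any():
            pts[active] = self._pull_inside(pts[active])
        return pts

    def _pull_inside(self, points: np.ndarray) -> np.ndarray:
        lo = np.zeros(len(points))
        hi = np.ones(len(points))
        c = self.centroid
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            cand = c + mid[:, None] * (points - c)
            inside = self.contains(cand)
            lo = np.where(inside, mid, lo)
            hi = np.where(inside, hi, mid)
        return c + (0.95 * lo)[:, None] * (points - c)

    def bounding_box(self, margin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    @property
    def volume(self) -> float:
        raise NotImplementedError

    def shell_volume(self, shell: float) -> float:
        raise NotImplementedError


class BlockRegion(_ConvexRegion):
    """Axis-aligned block [lo, hi] per axis."""

    def __init__(self, lo, hi):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        if (self.hi <= self.lo).any():
            raise ValueError(f"block upper bounds must exceed lower: {lo} .. {hi}")
        eye = np.eye(3)
        self.normals = np.vstack([eye, -eye])
        self.offsets = np.concatenate([self.hi, -self.lo])
        self.centroid = 0.5 * (self.lo + self.hi)

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    def shell_volume(self, shell: float) -> float:
        return float(np.prod(self.hi - self.lo + 2.0 * shell)) - self.volume

    def bounding_box(self, margin: float = 0.0):
        return self.lo - margin, self.hi + margin


class HullRegion(_ConvexRegion):
    """Convex hull of a point cloud (e.g. the fibril carbons)."""

    def __init__(self, points):
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        self.hull = ConvexHull(pts)
        eq = self.hull.equations  # n.x + d <= 0 inside, |n| = 1
        self.normals = eq[:, :3]
        self.offsets = -eq[:, 3]
        self.centroid = pts[self.hull.vertices].mean(axis=0)
        self._points = pts

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    def shell_volume(self, shell: float) -> float:
        half = np.hstack([self.normals, -(self.offsets + shell)[:, None]])
        inter = HalfspaceIntersection(half, self.centroid)
        return float(ConvexHull(inter.intersections).volume) - self.volume

    def bounding_box(self, margin: float = 0.0):
        v = self._points[self.hull.vertices]
        return v.min(axis=0) - margin, v.max(axis=0) + margin


def make_region(kind: str, **kwargs):
    if kind == "block":
        return BlockRegion(kwargs["lo"], kwargs["hi"])
    if kind == "hull":
        return HullRegion(kwargs["points"])
    raise ValueError(f"unknown region kind {kind!r}; use 'block' or 'hull'")
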