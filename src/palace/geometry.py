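"""Searchlight construction on surface-like meshes, and coordinate ROI splits.

Searchlights are local vertex neighborhoods used as the unit of every
map-level statistic. Starting from one candidate searchlight per vertex
(all vertices within a hop radius), redundant units are removed greedily
until no unit can be removed without dropping some vertex below the
required coverage floor (every vertex must stay inside at least
``min_coverage`` searchlights; 10 in the design this package emulates).
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Mesh", "SearchlightSet", "build_searchlights", "split_roi_by_axis"]


@dataclass
class Mesh:
    """Vertex adjacency structure with optional 3-D coordinates (mm)."""

    neighbors: list
    coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(sorted(set(int(j) for j in nb)), dtype=int)
                          for nb in self.neighbors]
        n = len(self.neighbors)
        for i, nb in enumerate(self.neighbors):
            if np.any(nb == i):
                raise ValueError(f"vertex {i} lists itself as a neighbor")
            if np.any((nb < 0) | (nb >= n)):
                raise ValueError(f"vertex {i} has out-of-range neighbors")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError(f"adjacency not symmetric: {i}->{j}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError("coords must be (n_vertices, 3)")

    @property
    def n_vertices(self) -> int:
        return len(self.neighbors)

    @classmethod
    def from_edges(cls, n_vertices: int, edges: Sequence[tuple],
                   coords: Optional[np.ndarray] = None) -> "Mesh":
        nb = [set() for _ in range(n_vertices)]
        for a, b in edges:
            if a == b:
                continue
            nb[int(a)].add(int(b))
            nb[int(b)].add(int(a))
        return cls(neighbors=[sorted(s) for s in nb], coords=coords)


@dataclass
class SearchlightSet:
    """Surviving searchlights: (center, members) plus per-vertex coverage."""

    units: list  # list of (center: int, members: tuple[int, ...])
    coverage: np.ndarray
    min_coverage: int

    @property
    def n_units(self) -> int:
        return len(self.units)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"unit_id": u, "center": c, "member": m}
            for u, (c, members) in enumerate(self.units)
            for m in members
        ]
        return pd.DataFrame(rows, columns=["unit_id", "center", "member"])


def _ball(mesh: Mesh, center: int, radius_hops: int) -> tuple:
    """Vertices within ``radius_hops`` graph hops of ``center`` (inclusive)."""
    seen = {center}
    frontier = deque([(center, 0)])
    while frontier:
        v, d = frontier.popleft()
        if d == radius_hops:
            continue
        for w in mesh.neighbors[v]:
            if w not in seen:
                seen.add(int(w))
                frontier.append((w, d + 1))
    return tuple(sorted(seen))


def build_searchlights(mesh: Mesh, radius_hops: int = 2,
                       min_coverage: int = 10) -> SearchlightSet:
    """Greedy redundancy removal down to the coverage floor.

    One unit is seeded per vertex (members = vertices within ``radius_hops``
    hops). Repeatedly, among units whose removal leaves every member's
    coverage at or above ``min_coverage``, the unit with the largest summed
    member coverage is removed (ties broken by lowest center index), until
    no unit is removable. Deterministic for a given mesh.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    n = mesh.n_vertices
    members = [_ball(mesh, v, radius_hops) for v in range(n)]
    coverage = np.zeros(n, dtype=int)
    for ms in members:
        for m in ms:
            coverage[m] += 1
    if coverage.min() < min_coverage:
        worst = int(np.argmin(coverage))
        raise ValueError(
            f"mesh too sparse: vertex {worst} has initial coverage "
            f"{coverage[worst]} < min_coverage={min_coverage}"
        )
    alive = np.ones(n, dtype=bool)

    def removable(c: int) -> bool:
        return all(coverage[m] > min_coverage for m in members[c])

    def redundancy(c: int) -> int:
        return int(sum(coverage[m] for m in members[c]))

    # Lazy max-heap keyed by (summed member coverage, -center); stale entries
    # are re-validated on pop since coverage only decreases.
    heap = [(-redundancy(c), c) for c in range(n)]
    heapq.heapify(heap)
    while heap:
        neg_red, c = heapq.heappop(heap)
        if not alive[c]:
            continue
        cur = redundancy(c)
        if -neg_red != cur:
            heapq.heappush(heap, (-cur, c))
            continue
        if not removable(c):
            continue  # may become removable only if coverage rose; it never does
        alive[c] = False
        for m in members[c]:
            coverage[m] -= 1
        assert coverage[list(members[c])].min() >= min_coverage
    # Units that were skipped as non-removable can never become removable
    # (coverage is non-increasing), so the fixed point is reached.
    units = [(c, members[c]) for c in range(n) if alive[c]]
    return SearchlightSet(units=units, coverage=coverage,
                          min_coverage=min_coverage)


def split_roi_by_axis(
    roi_vertices: Sequence[int],
    coords: np.ndarray,
    axis: str,
    threshold: float,
) -> tuple:
    """Partition an ROI by a coordinate threshold (e.g. anterior/posterior
    hippocampus at y = -20 mm).

    Returns ``(above, at_or_below)``: vertices with coordinate strictly
    greater than ``threshold``, and those at or below it.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise ValueError(f"axis must be 'x', 'y' or 'z', got {axis!r}")
    roi = np.asarray(sorted(int(v) for v in roi_vertices), dtype=int)
    coords = np.asarray(coords, dtype=float)
    if roi.size and (roi.max() >= len(coords) or np.isnan(coords[roi, ax]).any()):
        raise ValueError("missing coordinates for some ROI vertices")
    if roi.size == 0:
        return roi, roi
    vals = coords[roi, ax]
    return roi[vals > threshold], roi[vals <= threshold]
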