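"""Lattice, tree and repulsive-field primitives.

The model world is a 2-D grid of cells. Epithelial tubule trees occupy
cells (each cell holds at most one tree element, either a ``tip`` or a
``stalk``) and every occupied cell is a point source of a secreted
repulsive factor.  The factor is assumed to diffuse fast relative to
tree growth and to undergo first-order loss, so its steady-state
contribution from a single source decays exponentially with distance:

    c(d) = s * exp(-d / lambda)

with ``s`` the per-cell source strength and ``lambda`` the decay length
in cell units.  The total concentration anywhere is the sum of the
contributions of every occupied cell, optionally with one zero-mean
Gaussian noise draw added and the result clamped at zero.  Because the
field is memoryless it is recomputed from current anatomy whenever it
is needed; no diffusion history is stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "GridDomain",
    "Element",
    "TubuleTree",
    "Tip",
    "point_source_contribution",
    "field_at",
    "field_at_points",
    "field_grid",
    "NEIGHBOR_OFFSETS",
]

#: The 8 lattice neighbour offsets (Chebyshev distance 1), fixed order.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (0, -1), (1, -1),
    (-1, 0), (1, 0),
    (-1, 1), (0, 1), (1, 1),
)


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the self-avoidance model.

    Distances are in lattice cell units and concentrations in the
    arbitrary units set by ``source_strength``.  Defaults were
    calibrated so that a single bud reproduces the emergent wide-first
    (~150 deg) then narrower (~95 deg) divergence angles; see
    docs/methods.md for the calibration rationale.

    Attributes
    ----------
    source_strength : float
        Concentration contributed by an occupied cell at distance 0 (s).
    decay_length : float
        Exponential decay length of a point-source contribution (lambda),
        in cells.
    noise_sd : float
        Standard deviation of the zero-mean Gaussian noise added to each
        field evaluation (eta).
    branch_threshold : float
        A tip may bifurcate only while the concentration it senses is
        below this value (theta).
    speed_half_saturation : float
        Concentration at which a tip's per-step move probability
        1/(1 + C/K) drops to one half (K).
    refractory_length : float
        Minimum arc length (cells) a tip must travel after a bifurcation
        before it may bifurcate again.
    contact_chebyshev : int
        Chebyshev distance at or below which two occupied cells count as
        touching, the lattice analogue of "no discernible gap".
    domain_width, domain_height : int
        Grid dimensions in cells.
    arc_length_L : float
        Lever arm (cells) used when measuring divergence angles.
    cells_per_micron : float or None
        Optional scale factor for converting morphometric output to
        microns; unset by default.
    """

    source_strength: float = 1.0
    decay_length: float = 8.0
    noise_sd: float = 0.2
    branch_threshold: float = 8.6
    speed_half_saturation: float = 7.5
    refractory_length: float = 14.0
    contact_chebyshev: int = 1
    domain_width: int = 200
    domain_height: int = 200
    arc_length_L: float = 10.0
    cells_per_micron: Optional[float] = None

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.source_strength < 0:
            raise ValueError("source_strength must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.branch_threshold < 0:
            raise ValueError("branch_threshold must be non-negative")
        if self.speed_half_saturation <= 0:
            raise ValueError("speed_half_saturation must be positive")
        if self.refractory_length < 0:
            raise ValueError("refractory_length must be non-negative")
        if self.domain_width < 16 or self.domain_height < 16:
            raise ValueError("domain dimensions must be at least 16 cells")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class Element:
    """One occupied cell of a tree: a tip or a stalk segment."""

    cell: tuple[int, int]
    kind: str  # "tip" or "stalk"
    parent: Optional[int]  # index into TubuleTree.elements, None for root
    generation: int
    birth_step: int


@dataclass
class TubuleTree:
    """A connected tubule tree on the lattice.

    Elements form a rooted tree: exactly one element has no parent, and
    every child cell lies within Chebyshev distance 1 of its parent cell
    (8-connectivity).
    """

    tree_id: int
    elements: list[Element] = field(default_factory=list)

    def cells(self) -> list[tuple[int, int]]:
        return [e.cell for e in self.elements]

    def root_index(self) -> int:
        roots = [i for i, e in enumerate(self.elements) if e.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree {self.tree_id} has {len(roots)} roots")
        return roots[0]

    def children_map(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {i: [] for i in range(len(self.elements))}
        for i, e in enumerate(self.elements):
            if e.parent is not None:
                kids[e.parent].append(i)
        return kids

    def branch_points(self) -> list[int]:
        """Indices of elements with exactly two children."""
        kids = self.children_map()
        return [i for i, ch in kids.items() if len(ch) == 2]

    def validate(self) -> None:
        self.root_index()
        for i, e in enumerate(self.elements):
            if e.kind not in ("tip", "stalk"):
                raise ValueError(f"element {i}: bad kind {e.kind!r}")
            if e.parent is not None:
                px, py = self.elements[e.parent].cell
                x, y = e.cell
                if max(abs(px - x), abs(py - y)) > 1:
                    raise ValueError(
                        f"element {i} at {e.cell} is not 8-adjacent to its parent"
                    )


class GridDomain:
    """Occupancy map of the simulation lattice.

    Tracks which cell is occupied by which (tree_id, kind) and mirrors
    the occupied coordinates in a NumPy array so field sums stay
    vectorised as trees grow.
    """

    def __init__(self, width: int, height: int):
        if width < 16 or height < 16:
            raise ValueError("domain dimensions must be at least 16 cells")
        self.width = int(width)
        self.height = int(height)
        self._occ: dict[tuple[int, int], tuple[int, str]] = {}
        self._coords = np.empty((0, 2), dtype=np.float64)
        self._row_of: dict[tuple[int, int], int] = {}

    def __contains__(self, cell: tuple[int, int]) -> bool:
        return cell in self._occ

    def __len__(self) -> int:
        return len(self._occ)

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height

    def occupant(self, cell: tuple[int, int]) -> Optional[tuple[int, str]]:
        return self._occ.get(cell)

    def occupy(self, cell: tuple[int, int], tree_id: int, kind: str) -> None:
        if not self.in_bounds(cell):
            raise ValueError(f"cell {cell} outside domain")
        if cell in self._occ:
            raise ValueError(f"cell {cell} already occupied")
        self._occ[cell] = (tree_id, kind)
        row = len(self._row_of)
        self._row_of[cell] = row
        if row >= self._coords.shape[0]:
            grown = np.empty((max(64, 2 * self._coords.shape[0]), 2))
            grown[: self._coords.shape[0]] = self._coords[: self._coords.shape[0]]
            self._coords = grown
        self._coords[row] = cell

    def set_kind(self, cell: tuple[int, int], kind: str) -> None:
        tree_id, _ = self._occ[cell]
        self._occ[cell] = (tree_id, kind)

    def coords_view(self) -> np.ndarray:
        """(n, 2) float array of occupied cell coordinates (insertion order)."""
        return self._coords[: len(self._row_of)]

    def row_index(self, cell: tuple[int, int]) -> Optional[int]:
        return self._row_of.get(cell)

    def free_neighbors(self, cell: tuple[int, int]) -> list[tuple[int, int]]:
        x, y = cell
        out = []
        for dx, dy in NEIGHBOR_OFFSETS:
            c = (x + dx, y + dy)
            if self.in_bounds(c) and c not in self._occ:
                out.append(c)
        return out

    @classmethod
    def from_trees(cls, width: int, height: int,
                   trees: Iterable[TubuleTree]) -> "GridDomain":
        dom = cls(width, height)
        for t in trees:
            for e in t.elements:
                dom.occupy(e.cell, t.tree_id, e.kind)
        return dom


@dataclass(eq=False)  # identity semantics: tips are mutable live objects
class Tip:
    """A growing tip: position, lineage depth and branch refractory state."""

    cell: tuple[int, int]
    tree_id: int
    generation: int
    distance_since_branch: float = 0.0
    stalled: bool = False
    elem_index: int = -1
    tip_id: int = -1

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be non-negative")
        if self.distance_since_branch < 0:
            raise ValueError("distance_since_branch must be non-negative")


def point_source_contribution(d: float, params: ModelParams) -> float:
    """Concentration contributed by one occupied cell at distance ``d``.

    Equals ``s * exp(-d / lambda)``: the steady state of a rapidly
    diffusing factor with first-order loss.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    return params.source_strength * math.exp(-d / params.decay_length)


def _gather_coords(trees: Sequence[TubuleTree]) -> np.ndarray:
    cells = [e.cell for t in trees for e in t.elements]
    if not cells:
        return np.empty((0, 2))
    return np.asarray(cells, dtype=np.float64)


def field_at_points(
    points: np.ndarray,
    coords: np.ndarray,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    noise_on: bool = False,
    exclude_row: Optional[int] = None,
) -> np.ndarray:
    """Summed-source field at each of ``points`` (m, 2), vectorised.

    ``coords`` is the (n, 2) array of source cells; ``exclude_row``
    removes one source from the sum (used for a tip's self-exclusion).
    With ``noise_on``, one independent zero-mean Gaussian draw of sd
    ``noise_sd`` is added per point and the result is clamped at 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if coords.shape[0] == 0:
        total = np.zeros(pts.shape[0])
    else:
        d = np.sqrt(
            ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        )
        contrib = params.source_strength * np.exp(-d / params.decay_length)
        if exclude_row is not None:
            contrib[:, exclude_row] = 0.0
        total = contrib.sum(axis=1)
    if noise_on:
        if rng is None:
            raise ValueError("noise_on requires an rng")
        total = total + rng.normal(0.0, params.noise_sd, size=total.shape)
        total = np.maximum(total, 0.0)
    return total


def field_at(
    point: tuple[float, float],
    trees: Sequence[TubuleTree],
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    noise_on: bool = False,
    exclude: Optional[tuple[int, int]] = None,
) -> float:
    """Total repulsive-factor concentration at ``point``.

    Sums ``point_source_contribution`` over every occupied cell of every
    tree (omitting ``exclude`` if given), then optionally adds one noise
    draw and clamps at zero.  Deterministic for a given rng state.
    """
    x, y = point
    if not (0 <= x < params.domain_width and 0 <= y < params.domain_height):
        raise ValueError(f"point {point} outside domain")
    coords = _gather_coords(trees)
    exclude_row = None
    if exclude is not None and coords.shape[0]:
        match = np.flatnonzero(
            (coords[:, 0] == exclude[0]) & (coords[:, 1] == exclude[1])
        )
        if match.size:
            exclude_row = int(match[0])
    return float(
        field_at_points(
            np.array([[x, y]]), coords, params, rng, noise_on, exclude_row
        )[0]
    )


def field_grid(
    trees: Sequence[TubuleTree],
    params: ModelParams,
    noise_on: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Field sampled at every cell; returned as array[y, x] (row y=0 first)."""
    w, h = params.domain_width, params.domain_height
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    coords = _gather_coords(trees)
    vals = field_at_points(pts, coords, params, rng, noise_on)
    return vals.reshape(h, w)
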