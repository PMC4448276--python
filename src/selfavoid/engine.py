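"""Simulation engine: threshold-gated bifurcation, field-guided tip
advance, stalk deposition and the preset starting anatomies.

Each step every tip, in a freshly shuffled order, gets one chance to
bifurcate and one chance to move:

* bifurcation — the tip senses the field at its own cell (own cell
  excluded, noise on).  If the concentration is below the branch
  threshold, the tip has travelled at least the refractory length since
  its last branch, and two mutually non-adjacent free neighbour cells
  exist, the tip cell becomes a stalk (the branch point) and two
  daughter tips of the next generation occupy the admissible free-cell
  pair with the lowest summed field;

* advance — with probability 1/(1 + C/K), where C is the sensed
  concentration, the tip moves to the free neighbour cell with the
  lowest (noisily evaluated) field, leaving a stalk behind.  High
  local concentration therefore slows a tip, even to a stop, and steers
  it down the local gradient — both behaviours come from the same field.

No angle rule, spacing rule or tropism is coded anywhere: wide first
branches, narrower later branches and collision avoidance between
neighbouring trees all emerge from mutual repulsion alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    NEIGHBOR_OFFSETS,
    Element,
    GridDomain,
    ModelParams,
    Tip,
    TubuleTree,
    field_at_points,
)

__all__ = [
    "SimulationState",
    "Scenario",
    "SimulationResult",
    "BifurcationEvent",
    "maybe_bifurcate",
    "advance_tip",
    "step",
    "run_scenario",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("single_bud", "head_on_pair", "offset_pair", "triple")


@dataclass(frozen=True)
class Scenario:
    """A named starting anatomy: unbranched trunks entering from the
    domain edges.

    ``head_on_pair`` aims two trunks directly at one another from
    opposite edges; ``offset_pair`` shifts one of them sideways by
    ``lateral_offset``; ``triple`` starts three parallel buds from the
    bottom edge.  ``trunk_length`` defaults to 4 cells for single/triple
    buds (a bud branches soon after entering the field) and to 85 cells
    for the paired scenarios, which leaves the two opposing tips ~30
    cells apart on the default 200-cell domain — the closely-spaced,
    collision-course geometry.
    """

    name: str
    trunk_length: Optional[int] = None
    lateral_offset: int = 20

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}"
            )

    def resolved_trunk_length(self) -> int:
        if self.trunk_length is not None:
            return self.trunk_length
        return 85 if self.name in ("head_on_pair", "offset_pair") else 4


@dataclass(frozen=True)
class BifurcationEvent:
    step: int
    cell: tuple[int, int]
    parent_generation: int
    tree_id: int


@dataclass
class SimulationState:
    """Complete mutable state of one simulation run."""

    step: int
    domain: GridDomain
    trees: list[TubuleTree]
    tips: list[Tip]
    seed: int
    params: ModelParams
    next_tip_id: int = 0

    def tree_by_id(self, tree_id: int) -> TubuleTree:
        for t in self.trees:
            if t.tree_id == tree_id:
                return t
        raise KeyError(tree_id)

    def check_invariants(self) -> None:
        n_elements = sum(len(t.elements) for t in self.trees)
        if n_elements != len(self.domain):
            raise AssertionError("element count != occupied cell count")
        tip_cells = {tip.cell for tip in self.tips}
        grid_tips = {
            e.cell for t in self.trees for e in t.elements if e.kind == "tip"
        }
        if tip_cells != grid_tips:
            raise AssertionError("tip list inconsistent with grid occupancy")
        for t in self.trees:
            t.validate()


@dataclass
class SimulationResult:
    """Final state plus the recorded history of a run."""

    state: SimulationState
    tracks: pd.DataFrame  # columns time_h, tip_id, x, y
    bifurcations: list[BifurcationEvent]
    contacts: list[tuple[int, tuple[int, int], tuple[int, int]]] = dc_field(
        default_factory=list
    )  # (step, cell moved into, other tree's cell)

    @property
    def trees(self) -> list[TubuleTree]:
        return self.state.trees


def _sense(state: SimulationState, tip: Tip,
           rng: np.random.Generator) -> float:
    """Noisy field at the tip's own cell, excluding the tip itself."""
    coords = state.domain.coords_view()
    row = state.domain.row_index(tip.cell)
    val = field_at_points(
        np.array([tip.cell], dtype=float), coords, state.params,
        rng=rng, noise_on=True, exclude_row=row,
    )
    return float(val[0])


def _candidate_fields(
    state: SimulationState, tip: Tip, cells: list[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One noisy field evaluation per candidate direction (tip self-excluded).

    Each candidate cell is scored by sampling the field at unit radius
    from the tip along the direction of that cell, not at the cell
    centre: diagonal neighbours sit sqrt(2) away, so scoring at cell
    centres would hand every diagonal a systematic head start (it is
    farther from all nearby sources) and lock growth onto the lattice
    diagonals.  Equal-radius sampling keeps direction choice isotropic.
    """
    coords = state.domain.coords_view()
    row = state.domain.row_index(tip.cell)
    tip_xy = np.asarray(tip.cell, dtype=float)
    offs = np.asarray(cells, dtype=float) - tip_xy
    offs /= np.linalg.norm(offs, axis=1, keepdims=True)
    return field_at_points(
        tip_xy + offs, coords, state.params,
        rng=rng, noise_on=True, exclude_row=row,
    )


def _heading(tree: TubuleTree, tip: Tip) -> Optional[tuple[int, int]]:
    """Unit lattice offset of the tip's last growth direction."""
    par = tree.elements[tip.elem_index].parent
    if par is None:
        return None
    px, py = tree.elements[par].cell
    return tip.cell[0] - px, tip.cell[1] - py


def _spawn_daughter(
    state: SimulationState, tree: TubuleTree, parent_idx: int,
    cells: list[tuple[int, int]], generation: int,
) -> None:
    """Append a daughter branch (stalk chain + terminal tip) to a tree."""
    arc = 0.0
    prev = tree.elements[parent_idx].cell
    for i, cell in enumerate(cells):
        last = i == len(cells) - 1
        kind = "tip" if last else "stalk"
        tree.elements.append(
            Element(cell, kind, parent_idx, generation, state.step)
        )
        state.domain.occupy(cell, tree.tree_id, kind)
        arc += math.hypot(cell[0] - prev[0], cell[1] - prev[1])
        prev = cell
        parent_idx = len(tree.elements) - 1
    state.tips.append(
        Tip(
            cell=cells[-1],
            tree_id=tree.tree_id,
            generation=generation,
            distance_since_branch=arc,
            elem_index=parent_idx,
            tip_id=state.next_tip_id,
        )
    )
    state.next_tip_id += 1


def maybe_bifurcate(
    tip: Tip, state: SimulationState, rng: np.random.Generator
) -> bool:
    """Bifurcate ``tip`` if the branch gate passes; returns True on branch.

    Gate: sensed concentration below the branch threshold AND at least
    the refractory length travelled since the last branch.  The tip cell
    becomes a stalk (the branch point) and two daughter branches sprout
    sideways, one stalk plus one tip each, flanking the parent's heading
    at +-90 degrees — the lattice rendering of an ampulla splitting into
    two short branches pointing in distinct directions.  Each daughter
    is a source from the moment it appears.  If either flank is blocked
    (crowded neighbourhood, domain edge), the daughters fall back to the
    two lowest-field free neighbour cells that are not 8-adjacent to
    each other; with fewer than two admissible cells the bifurcation is
    a no-op, never an error.
    """
    params = state.params
    c = _sense(state, tip, rng)
    if c >= params.branch_threshold:
        return False
    if tip.distance_since_branch < params.refractory_length:
        return False
    tree = state.tree_by_id(tip.tree_id)
    heading = _heading(tree, tip)

    daughters: Optional[list[list[tuple[int, int]]]] = None
    if heading is not None:
        hx, hy = heading
        flanks = []
        for dx, dy in ((-hy, hx), (hy, -hx)):
            chain = [
                (tip.cell[0] + dx, tip.cell[1] + dy),
                (tip.cell[0] + 2 * dx, tip.cell[1] + 2 * dy),
            ]
            if all(
                state.domain.in_bounds(cl) and cl not in state.domain
                for cl in chain
            ):
                flanks.append(chain)
        if len(flanks) == 2:
            daughters = flanks

    if daughters is None:
        free = state.domain.free_neighbors(tip.cell)
        if len(free) < 2:
            return False
        fields = _candidate_fields(state, tip, free, rng)
        best_pair = None
        best_sum = math.inf
        for i in range(len(free)):
            for j in range(i + 1, len(free)):
                a, b = free[i], free[j]
                if max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1:
                    continue  # daughters must take distinct directions
                s = fields[i] + fields[j]
                if s < best_sum:
                    best_sum = s
                    best_pair = (i, j)
        if best_pair is None:
            return False
        daughters = [[free[best_pair[0]]], [free[best_pair[1]]]]

    state.domain.set_kind(tip.cell, "stalk")
    tree.elements[tip.elem_index].kind = "stalk"
    state.tips.remove(tip)
    for chain in daughters:
        _spawn_daughter(state, tree, tip.elem_index, chain,
                        tip.generation + 1)
    return True


def advance_tip(
    tip: Tip, state: SimulationState, rng: np.random.Generator
) -> bool:
    """Move ``tip`` one cell down the field gradient; returns True on move.

    The move happens with probability 1/(1 + C/K): a tip in a crowded
    neighbourhood slows and ultimately stops.  The destination is the
    free 8-neighbour with the lowest noisily-evaluated field (exact ties
    broken uniformly); the vacated cell becomes a stalk.
    """
    params = state.params
    free = state.domain.free_neighbors(tip.cell)
    if not free:
        tip.stalled = True
        return False
    tip.stalled = False
    c = _sense(state, tip, rng)
    p_move = 1.0 / (1.0 + c / params.speed_half_saturation)
    if rng.random() >= p_move:
        return False
    fields = _candidate_fields(state, tip, free, rng)
    lowest = np.flatnonzero(fields == fields.min())
    choice = int(lowest[0] if lowest.size == 1 else rng.choice(lowest))
    dest = free[choice]

    tree = state.tree_by_id(tip.tree_id)
    state.domain.set_kind(tip.cell, "stalk")
    tree.elements[tip.elem_index].kind = "stalk"
    tree.elements.append(
        Element(dest, "tip", tip.elem_index, tip.generation, state.step)
    )
    state.domain.occupy(dest, tip.tree_id, "tip")
    step_len = math.hypot(dest[0] - tip.cell[0], dest[1] - tip.cell[1])
    tip.cell = dest
    tip.elem_index = len(tree.elements) - 1
    tip.distance_since_branch += step_len
    return True


def step(state: SimulationState, rng: np.random.Generator) -> SimulationState:
    """Advance the whole simulation by one step (in place).

    Tips act in a freshly shuffled order; each surviving tip first gets
    a bifurcation chance, then (if it did not branch) a movement chance.
    Daughters born this step start acting next step, though their field
    contribution is immediate.
    """
    order = list(rng.permutation(len(state.tips)))
    todo = [state.tips[i] for i in order]
    for tip in todo:
        if tip not in state.tips:  # replaced by daughters earlier this step
            continue
        if not maybe_bifurcate(tip, state, rng):
            advance_tip(tip, state, rng)
    state.step += 1
    return state


def build_scenario_state(
    scenario: Scenario, params: ModelParams, seed: int
) -> SimulationState:
    """Initial state for a named starting anatomy."""
    w, h = params.domain_width, params.domain_height
    L = scenario.resolved_trunk_length()
    if L < 2 or L > min(w, h) // 2:
        raise ValueError("trunk_length must fit inside half the domain")

    def trunk(cells: list[tuple[int, int]], tree_id: int) -> TubuleTree:
        tree = TubuleTree(tree_id=tree_id)
        for i, cell in enumerate(cells):
            kind = "tip" if i == len(cells) - 1 else "stalk"
            tree.elements.append(
                Element(cell, kind, None if i == 0 else i - 1, 0, 0)
            )
        return tree

    if scenario.name == "single_bud":
        trunks = [trunk([(w // 2, y) for y in range(L)], 0)]
    elif scenario.name == "head_on_pair":
        y = h // 2
        trunks = [
            trunk([(x, y) for x in range(L)], 0),
            trunk([(w - 1 - x, y) for x in range(L)], 1),
        ]
    elif scenario.name == "offset_pair":
        y = h // 2
        off = scenario.lateral_offset
        if not 0 <= y + off < h:
            raise ValueError("lateral_offset puts a trunk outside the domain")
        trunks = [
            trunk([(x, y) for x in range(L)], 0),
            trunk([(w - 1 - x, y + off) for x in range(L)], 1),
        ]
    else:  # triple
        xs = [w // 4, w // 2, 3 * w // 4]
        trunks = [
            trunk([(x, y) for y in range(L)], i) for i, x in enumerate(xs)
        ]

    domain = GridDomain.from_trees(w, h, trunks)
    tips = []
    for t in trunks:
        i = len(t.elements) - 1
        tips.append(
            Tip(
                cell=t.elements[i].cell,
                tree_id=t.tree_id,
                generation=0,
                # an entering trunk is branch-mature: the refractory gate
                # must not force it to elongate before its first split
                distance_since_branch=float(max(L, params.refractory_length)),
                elem_index=i,
                tip_id=t.tree_id,
            )
        )
    return SimulationState(
        step=0, domain=domain, trees=trunks, tips=tips, seed=seed,
        params=params, next_tip_id=len(tips),
    )


def _contact_check(state: SimulationState, out: list) -> None:
    """Append the first inter-tree contact found at the current tips.

    Cheap per-step check (tips are the only cells that can create new
    contacts); the full event list comes from
    ``morphometrics.detect_collisions`` on the final anatomy.
    """
    cd = state.params.contact_chebyshev
    for tip in state.tips:
        x, y = tip.cell
        for dx in range(-cd, cd + 1):
            for dy in range(-cd, cd + 1):
                if dx == 0 and dy == 0:
                    continue
                occ = state.domain.occupant((x + dx, y + dy))
                if occ is not None and occ[0] != tip.tree_id:
                    out.append((state.step, tip.cell, (x + dx, y + dy)))
                    return


def run_scenario(
    scenario: Scenario,
    params: ModelParams,
    seed: int,
    n_steps: int,
    recording_stride: int = 5,
    stop_on_contact: bool = False,
) -> SimulationResult:
    """Run a named scenario for ``n_steps`` (or until every tip stalls).

    Tip positions are recorded every ``recording_stride`` steps (plus
    the final step); one simulation step is one time unit in the track
    table.  Fully reproducible for a given (params, seed).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    state = build_scenario_state(scenario, params, seed)
    track_rows: list[tuple] = []
    bifs: list[BifurcationEvent] = []
    contacts: list[tuple] = []

    def record() -> None:
        for tip in state.tips:
            track_rows.append(
                (float(state.step), tip.tip_id, float(tip.cell[0]),
                 float(tip.cell[1]))
            )

    record()
    for _ in range(n_steps):
        tips_before = list(state.tips)
        step(state, rng)
        # a tip that vanished from the list bifurcated this step
        gone = [t for t in tips_before if t not in state.tips]
        for t in gone:
            tree = state.tree_by_id(t.tree_id)
            bifs.append(
                BifurcationEvent(state.step - 1, t.cell, t.generation,
                                 t.tree_id)
            )
        _contact_check(state, contacts)
        if state.step % recording_stride == 0:
            record()
        if all(tip.stalled for tip in state.tips) and state.tips:
            break
        if stop_on_contact and contacts:
            break
    if state.step % recording_stride != 0:
        record()
    tracks = pd.DataFrame(
        track_rows, columns=["time_h", "tip_id", "x", "y"]
    )
    return SimulationResult(state=state, tracks=tracks, bifurcations=bifs,
                            contacts=contacts)
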