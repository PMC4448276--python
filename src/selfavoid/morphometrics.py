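"""Tree and track morphometrics: divergence angles, collision scoring,
bead closest approach, tip speeds and pairwise closing speeds.

Divergence angle follows the skeleton-line protocol: at a bifurcation,
walk a fixed arc length L along each daughter's skeleton, form the unit
vector from the branch point to the point reached, and report the angle
between the two vectors.  Angles are therefore a property of the
elongated branches, not of the tip shape at the moment of splitting.

Collisions are scored the way cultures are scored under the microscope:
categorically.  Two trees collide if any of their cells approach within
a Chebyshev contact distance (default 1 cell, the lattice analogue of
"no discernible gap"); a single tree self-loops if two of its cells
touch while being far apart along the tree itself.

Kinematics mirror frame-pair measurements on time-lapse movies: speed
is Euclidean displacement over elapsed time between consecutive frames
sampled at a stride, and the closing speed of a tip pair is the decrease
in their Pythagorean separation per unit time (positive while the tips
approach; the raw frame-difference velocity, negative on approach, is
emitted alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ModelParams, TubuleTree

__all__ = [
    "AngleRecord",
    "CollisionEvent",
    "divergence_angle",
    "angles_by_generation",
    "detect_collisions",
    "closest_approach_to_disc",
    "tip_speeds",
    "closing_speed_table",
    "validate_track_table",
]

#: Expected columns of a track table (the time-lapse spreadsheet layout).
TRACK_COLUMNS = ["time_h", "tip_id", "x", "y"]


@dataclass(frozen=True)
class AngleRecord:
    """Divergence angle at one bifurcation, labelled by branch generation."""

    branch_point: tuple[int, int]
    generation: int
    angle: float  # degrees in [0, 180]

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= 180.0:
            raise ValueError("angle must lie in [0, 180] degrees")
        if self.generation < 1:
            raise ValueError("generation must be >= 1")


@dataclass(frozen=True)
class CollisionEvent:
    """A contact between tree cells: between trees, or a self-loop."""

    step: Optional[int]
    cells: tuple[tuple[int, int], tuple[int, int]]
    tree_ids: tuple[int, ...]
    type: str  # "inter_tree" or "self_loop"

    def __post_init__(self) -> None:
        if self.type == "inter_tree" and len(set(self.tree_ids)) != 2:
            raise ValueError("inter_tree event needs two distinct tree ids")
        if self.type == "self_loop" and len(set(self.tree_ids)) != 1:
            raise ValueError("self_loop event involves one tree")


def _walk_daughter(
    tree: TubuleTree,
    kids: dict[int, list[int]],
    start: int,
    origin: tuple[int, int],
    L: float,
) -> tuple[float, float]:
    """Skeleton point at arc length L along the branch starting at element
    ``start``, walking away from ``origin``.

    The walk follows the unique child chain and stops early at the
    branch's own next bifurcation or at its tip if the branch is shorter
    than L.  Returns the (x, y) of the first cell whose cumulative arc
    reaches L.
    """
    arc = 0.0
    prev = origin
    idx = start
    while True:
        cell = tree.elements[idx].cell
        arc += math.hypot(cell[0] - prev[0], cell[1] - prev[1])
        ch = kids[idx]
        if arc >= L or len(ch) != 1:
            return cell
        prev = cell
        idx = ch[0]


def divergence_angle(
    tree: TubuleTree,
    branch_point: tuple[int, int],
    L: float,
) -> float:
    """Divergence angle (degrees) at a two-daughter branch point.

    For each daughter, the direction is taken as the unit vector from the
    branch point to the skeleton point at arc length ``L`` along that
    daughter (or closer, if the daughter bifurcates again or ends first).
    """
    idx = next(
        (i for i, e in enumerate(tree.elements) if e.cell == branch_point), None
    )
    if idx is None:
        raise ValueError(f"no element at {branch_point}")
    kids = tree.children_map()
    daughters = kids[idx]
    if len(daughters) != 2:
        raise ValueError(
            f"branch point {branch_point} has {len(daughters)} daughters, need 2"
        )
    vecs = []
    for d in daughters:
        px, py = _walk_daughter(tree, kids, d, branch_point, L)
        v = np.array([px - branch_point[0], py - branch_point[1]], dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0.0:
            raise ValueError("degenerate daughter direction")
        vecs.append(v / norm)
    cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def angles_by_generation(
    source: Union[TubuleTree, Sequence[TubuleTree], "object"],
    L: Optional[float] = None,
    params: Optional[ModelParams] = None,
) -> tuple[dict[int, list[float]], list[AngleRecord]]:
    """Divergence angles of every bifurcation, grouped by generation.

    Generation 1 is the first bifurcation from the trunk (the daughters'
    lineage depth).  Accepts a tree, a list of trees, or any object with
    a ``trees`` attribute (e.g. a simulation result).  Returns the
    mapping generation -> angles plus the flat list of records.
    """
    if L is None:
        L = (params or ModelParams()).arc_length_L
    if hasattr(source, "trees"):
        trees = source.trees
    elif isinstance(source, TubuleTree):
        trees = [source]
    else:
        trees = list(source)
    records: list[AngleRecord] = []
    for tree in trees:
        kids = tree.children_map()
        for i in tree.branch_points():
            gen = tree.elements[kids[i][0]].generation
            angle = divergence_angle(tree, tree.elements[i].cell, L)
            records.append(AngleRecord(tree.elements[i].cell, gen, angle))
    table: dict[int, list[float]] = {}
    for rec in records:
        table.setdefault(rec.generation, []).append(rec.angle)
    return table, records


def _tree_depths(tree: TubuleTree) -> list[int]:
    """Edge depth of every element from the root (for path distances)."""
    # elements are appended parent-first by construction
    depth = [0] * len(tree.elements)
    for i, e in enumerate(tree.elements):
        if e.parent is not None:
            depth[i] = depth[e.parent] + 1
    return depth


def _path_distance(tree: TubuleTree, depths: list[int], a: int, b: int) -> int:
    """Number of tree edges between elements a and b (LCA walk)."""
    da, db = depths[a], depths[b]
    steps = 0
    while da > db:
        a = tree.elements[a].parent
        da -= 1
        steps += 1
    while db > da:
        b = tree.elements[b].parent
        db -= 1
        steps += 1
    while a != b:
        a = tree.elements[a].parent
        b = tree.elements[b].parent
        steps += 2
    return steps


def detect_collisions(
    trees: Sequence[TubuleTree],
    contact_chebyshev: int = 1,
    self_loop_path_cutoff: int = 10,
) -> tuple[list[CollisionEvent], bool]:
    """Score contacts between and within trees.

    An ``inter_tree`` event is any pair of cells from different trees
    within Chebyshev distance ``contact_chebyshev``.  A ``self_loop``
    event is a pair of cells of one tree that are that close in space
    but more than ``self_loop_path_cutoff`` cells apart along the tree —
    parent/daughter and sibling adjacency is not a loop.  Returns the
    events and the categorical verdict (any collision at all).
    """
    cell_owner: dict[tuple[int, int], tuple[int, int]] = {}
    for t in trees:
        for i, e in enumerate(t.elements):
            cell_owner[e.cell] = (t.tree_id, i)
    by_id = {t.tree_id: t for t in trees}
    depths = {t.tree_id: _tree_depths(t) for t in trees}
    events: list[CollisionEvent] = []
    seen: set[frozenset] = set()
    cd = int(contact_chebyshev)
    for cell, (tid, ei) in cell_owner.items():
        x, y = cell
        for dx in range(-cd, cd + 1):
            for dy in range(-cd, cd + 1):
                if dx == 0 and dy == 0:
                    continue
                other = (x + dx, y + dy)
                hit = cell_owner.get(other)
                if hit is None:
                    continue
                key = frozenset((cell, other))
                if key in seen:
                    continue
                otid, oei = hit
                if otid != tid:
                    seen.add(key)
                    events.append(
                        CollisionEvent(None, (cell, other), (tid, otid),
                                       "inter_tree")
                    )
                else:
                    dist = _path_distance(by_id[tid], depths[tid], ei, oei)
                    if dist > self_loop_path_cutoff:
                        seen.add(key)
                        events.append(
                            CollisionEvent(None, (cell, other), (tid,),
                                           "self_loop")
                        )
    return events, bool(events)


def closest_approach_to_disc(
    tree: TubuleTree, center: tuple[float, float], radius: float
) -> float:
    """Shortest edge-to-edge distance between the tree and a disc.

    Models the bead closest-approach measurement: distance from the
    nearest tree cell to the disc edge, clamped at 0 for cells inside.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cx, cy = center
    best = math.inf
    for x, y in tree.cells():
        d = math.hypot(x - cx, y - cy) - radius
        best = min(best, max(0.0, d))
    if not math.isfinite(best):
        raise ValueError("tree has no cells")
    return best


def validate_track_table(track: pd.DataFrame) -> pd.DataFrame:
    """Check track-table structure; returns the frame sorted per tip by time."""
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if not np.isfinite(track[["time_h", "x", "y"]].to_numpy(float)).all():
        raise ValueError("track table contains non-finite values")
    out = track.sort_values(["tip_id", "time_h"], kind="stable").reset_index(
        drop=True
    )
    for tid, grp in out.groupby("tip_id", sort=False):
        if grp["time_h"].diff().dropna().le(0).any():
            raise ValueError(f"tip {tid!r}: times not strictly increasing")
    return out


def tip_speeds(
    track: pd.DataFrame, stride: int = 5, tip_id=None
) -> pd.DataFrame:
    """Frame-pair tip speeds, sampled every ``stride`` frames.

    For frames n = 0, stride, 2*stride, ... the speed between frame n
    and n+1 is sqrt((x_{n+1}-x_n)^2 + (y_{n+1}-y_n)^2) / (t_{n+1}-t_n).
    Returns a frame with columns time_h (at frame n), tip_id, speed.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    track = validate_track_table(track)
    if tip_id is not None:
        track = track[track["tip_id"] == tip_id]
    rows = []
    for tid, grp in track.groupby("tip_id", sort=False):
        t = grp["time_h"].to_numpy(float)
        xy = grp[["x", "y"]].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"tip {tid!r}: need at least 2 frames")
        for n in range(0, len(t) - 1, stride):
            dt = t[n + 1] - t[n]
            disp = math.hypot(*(xy[n + 1] - xy[n]))
            rows.append({"time_h": t[n], "tip_id": tid, "speed": disp / dt})
    return pd.DataFrame(rows, columns=["time_h", "tip_id", "speed"])


def closing_speed_table(
    track_a: pd.DataFrame, track_b: pd.DataFrame
) -> pd.DataFrame:
    """Separation and closing speed for a pair of tip tracks.

    Both tracks must be sampled at identical frame times.  For each
    consecutive frame pair, the raw frame-difference velocity is
    (d_{n+1} - d_n) / dt — negative while the tips approach, exactly as
    a spreadsheet difference would give it — and the closing speed is
    its negation, positive on approach.  Columns: time_h, separation
    (at frame n), raw_velocity, closing_speed.
    """
    a = validate_track_table(track_a)
    b = validate_track_table(track_b)
    if a["tip_id"].nunique() > 1 or b["tip_id"].nunique() > 1:
        raise ValueError("closing_speed_table expects one tip per track")
    ta = a["time_h"].to_numpy(float)
    tb = b["time_h"].to_numpy(float)
    if len(ta) != len(tb) or not np.allclose(ta, tb):
        raise ValueError("tracks must share identical frame times")
    pa = a[["x", "y"]].to_numpy(float)
    pb = b[["x", "y"]].to_numpy(float)
    sep = np.hypot(*(pa - pb).T)
    dt = np.diff(ta)
    raw = np.diff(sep) / dt
    return pd.DataFrame(
        {
            "time_h": ta[:-1],
            "separation": sep[:-1],
            "raw_velocity": raw,
            "closing_speed": -raw,
        }
    )
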