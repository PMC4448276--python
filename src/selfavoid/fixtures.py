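"""Synthetic inputs with known ground truth.

Two generators make every analysis operation testable without any
external data:

* ``gen_pair_tracks`` — pairs of tip tracks approaching head-on under a
  known closing-speed law, v(d) = max(0, c * ln(d / d0)) plus Gaussian
  observation noise.  The logarithmic form mirrors the observed
  log-linear relation between closing speed and separation in cultured
  kidneys, with a complete stop at separation d0 (default 30 µm, the
  observed stopping distance).  The law is a test scaffold for the
  analysis pipeline, not a biological claim.

* ``gen_toy_tree`` — lattice trees with prescribed branch angles and
  lengths, rasterized with Bresenham lines, for checking the angle
  measurement against stored truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Element, TubuleTree

__all__ = ["TrackLaw", "ToyTreeSpec", "gen_pair_tracks", "gen_toy_tree"]


@dataclass(frozen=True)
class TrackLaw:
    """Closing-speed law for synthetic approaching tip pairs.

    ``closing speed = max(0, c * ln(d / stop_distance)) + noise`` —
    above the stop distance the pair closes at a rate proportional to
    the log of separation; at or below it the deterministic law is a
    dead stop.  The Gaussian term is observation noise on the recorded
    positions, so measured frame-to-frame speeds scatter around the law
    (and may be slightly negative), as tracking data do.

    Units are microns and hours by convention; nothing depends on that.
    """

    coefficient: float = 10.0          # µm/h per ln-unit of separation
    stop_distance: float = 30.0        # µm; the observed stopping separation
    noise_sd: float = 2.0              # µm/h
    initial_separation: float = 120.0  # µm
    frame_interval: float = 1.0        # h

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise ValueError("coefficient must be non-negative")
        if self.stop_distance <= 0:
            raise ValueError("stop_distance must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.initial_separation <= self.stop_distance:
            raise ValueError("initial separation must exceed stop_distance")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def speed(self, separation: float) -> float:
        """Deterministic closing speed at a given separation."""
        return max(0.0, self.coefficient *
                   math.log(separation / self.stop_distance))


def gen_pair_tracks(
    law: TrackLaw,
    n_pairs: int = 6,
    n_frames: int = 15,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate head-on approaching tip pairs under a known law.

    Each pair starts ``initial_separation`` apart on a horizontal line
    (pairs stacked 100 units apart in y) and both tips move toward each
    other, splitting the closing speed equally.  Per frame the closing
    speed is the law's deterministic value plus one Gaussian noise draw;
    separation never goes negative.  Returns the track table (columns
    time_h, tip_id, x, y) and the stored ground truth.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if n_pairs < 1:
        raise ValueError("need at least 1 pair")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_pairs):
        y = 100.0 * k
        d = law.initial_separation
        xa, xb = -d / 2.0, d / 2.0
        for frame in range(n_frames):
            t = frame * law.frame_interval
            rows.append((t, f"p{k}a", xa, y))
            rows.append((t, f"p{k}b", xb, y))
            v = law.speed(xb - xa) + rng.normal(0.0, law.noise_sd)
            shrink = v * law.frame_interval
            shrink = min(shrink, (xb - xa) - 1e-9)  # tips never cross
            xa += shrink / 2.0
            xb -= shrink / 2.0
    table = pd.DataFrame(rows, columns=["time_h", "tip_id", "x", "y"])
    truth = {
        "coefficient": law.coefficient,
        "stop_distance": law.stop_distance,
        "noise_sd": law.noise_sd,
        "n_pairs": n_pairs,
        "n_frames": n_frames,
        "seed": seed,
    }
    return table, truth


@dataclass(frozen=True)
class ToyTreeSpec:
    """Prescribed branch angles for a rasterized toy tree.

    ``branches`` lists one (generation, divergence angle in degrees,
    branch length in cells) triple per generation, applied at every
    branch point of that generation.  The trunk grows straight up for
    ``trunk_length`` cells before the first bifurcation.
    """

    branches: tuple = ()
    trunk_length: int = 12

    def __post_init__(self) -> None:
        gens = [g for g, _, _ in self.branches]
        if gens != sorted(gens) or len(set(gens)) != len(gens):
            raise ValueError("branch generations must be strictly increasing")
        if gens and (gens[0] != 1 or gens != list(range(1, len(gens) + 1))):
            raise ValueError("branch generations must be 1, 2, ...")
        for g, angle, length in self.branches:
            if not 0.0 < angle < 180.0:
                raise ValueError(f"generation {g}: angle must be in (0, 180)")
            if length < 2:
                raise ValueError(f"generation {g}: length must be >= 2")
        if self.trunk_length < 2:
            raise ValueError("trunk_length must be >= 2")


def _raster_segment(start: tuple[float, float], direction_deg: float,
                    length: float) -> list[tuple[int, int]]:
    """8-connected lattice cells of a straight segment (start excluded)."""
    x0, y0 = start
    x1 = x0 + length * math.cos(math.radians(direction_deg))
    y1 = y0 + length * math.sin(math.radians(direction_deg))
    n = int(math.ceil(2 * length)) + 1
    cells: list[tuple[int, int]] = []
    prev = (int(round(x0)), int(round(y0)))
    for i in range(1, n + 1):
        t = i / n
        c = (int(round(x0 + t * (x1 - x0))), int(round(y0 + t * (y1 - y0))))
        if c != prev and c not in cells:
            cells.append(c)
            prev = c
    return cells


def gen_toy_tree(spec: ToyTreeSpec, seed: int = 0,
                 origin: tuple[int, int] = (100, 10)) -> tuple[TubuleTree, dict]:
    """Rasterize a tree with prescribed divergence angles onto the lattice.

    At each branch point of generation g, two straight daughters leave
    symmetrically about the parent's direction, separated by the
    prescribed angle.  Stored truth maps generation -> intended angle.
    Overlapping branches raise ``ValueError``.
    """
    tree = TubuleTree(tree_id=0)
    occupied: set[tuple[int, int]] = set()

    def add_chain(cells, parent_idx, generation, tip_at_end):
        for i, cell in enumerate(cells):
            if cell in occupied:
                raise ValueError(f"branch overlap at {cell}")
            occupied.add(cell)
            kind = "tip" if (tip_at_end and i == len(cells) - 1) else "stalk"
            tree.elements.append(Element(cell, kind, parent_idx, generation, 0))
            parent_idx = len(tree.elements) - 1
        return parent_idx

    x0, y0 = origin
    trunk = [(x0, y0 + i) for i in range(spec.trunk_length)]
    occupied.add(trunk[0])
    tree.elements.append(Element(trunk[0], "stalk", None, 0, 0))
    end = add_chain(trunk[1:], 0, 0, tip_at_end=not spec.branches)

    # (element index of branch point, direction of the parent branch)
    frontier = [(end, 90.0)]
    for g, angle, length in spec.branches:
        new_frontier = []
        last_gen = g == len(spec.branches)
        for idx, direction in frontier:
            for sign in (+1.0, -1.0):
                d = direction + sign * angle / 2.0
                cells = _raster_segment(tree.elements[idx].cell, d, length)
                e = add_chain(cells, idx, g, tip_at_end=last_gen)
                new_frontier.append((e, d))
        frontier = new_frontier
    truth = {g: angle for g, angle, _ in spec.branches}
    return tree, truth
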