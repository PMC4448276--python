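"""File formats: tree JSON, SWC dialect, track CSV, flat config, PGM.

The JSON form is the canonical tree serialization (lossless, including
generation and birth step); the SWC dialect is the interoperable
export — one element per line, ``id type x y z radius parent`` with z
fixed at 0 and radius 1, type codes 1 = root, 3 = stalk, 4 = tip.
Track tables are plain CSV with header ``time_h,tip_id,x,y`` and an
optional ``# cells_per_micron=...`` comment carrying the unit scale.
Configs are flat ``key=value`` text, one parameter per line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import Element, ModelParams, TubuleTree, field_grid

__all__ = [
    "save_tree_json", "load_tree_json",
    "save_tree_swc", "load_tree_swc",
    "save_tracks_csv", "load_tracks_csv",
    "load_config", "save_config",
    "save_field_pgm", "save_field_png",
]

log = logging.getLogger("selfavoid")

_SWC_CODE = {"root": 1, "stalk": 3, "tip": 4}
_SWC_KIND = {1: "stalk", 3: "stalk", 4: "tip"}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def save_tree_json(tree: TubuleTree, path) -> None:
    """Write the canonical JSON form (stable key order, lossless)."""
    doc = {
        "tree_id": tree.tree_id,
        "elements": [
            {
                "id": i,
                "x": e.cell[0],
                "y": e.cell[1],
                "kind": e.kind,
                "parent": -1 if e.parent is None else e.parent,
                "generation": e.generation,
                "birth_step": e.birth_step,
            }
            for i, e in enumerate(tree.elements)
        ],
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_tree_json(path) -> TubuleTree:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    tree = TubuleTree(tree_id=doc["tree_id"])
    elements = sorted(doc["elements"], key=lambda r: r["id"])
    for i, r in enumerate(elements):
        if r["id"] != i:
            raise ValueError(f"{path}: element ids not contiguous at {r['id']}")
        parent = None if r["parent"] == -1 else r["parent"]
        if parent is not None and parent >= i:
            raise ValueError(f"{path}: parent {parent} does not precede {i}")
        tree.elements.append(
            Element((r["x"], r["y"]), r["kind"], parent, r["generation"],
                    r["birth_step"])
        )
    tree.validate()
    return tree


def save_tree_swc(tree: TubuleTree, path) -> None:
    """Write the SWC dialect (1-based ids, z=0, radius=1)."""
    lines = ["# id type x y z radius parent"]
    for i, e in enumerate(tree.elements):
        code = _SWC_CODE["root" if e.parent is None else e.kind]
        parent = -1 if e.parent is None else e.parent + 1
        lines.append(f"{i + 1} {code} {e.cell[0]} {e.cell[1]} 0 1 {parent}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_tree_swc(path, tree_id: int = 0) -> TubuleTree:
    """Read the SWC dialect; generations are recomputed from topology."""
    tree = TubuleTree(tree_id=tree_id)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(path, lineno, f"expected 7 fields, got {len(parts)}")
            try:
                ident, code = int(parts[0]), int(parts[1])
                x, y = int(float(parts[2])), int(float(parts[3]))
                parent = int(parts[6])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if ident != len(tree.elements) + 1:
                raise ParseError(path, lineno, f"ids must be contiguous, got {ident}")
            if code not in _SWC_KIND and code != 1:
                raise ParseError(path, lineno, f"unknown type code {code}")
            kind = "stalk" if parent == -1 else _SWC_KIND[code]
            tree.elements.append(
                Element((x, y), kind, None if parent == -1 else parent - 1,
                        0, 0)
            )
    # recompute generations: +1 across every 2-child branch point
    kids = tree.children_map()
    root = tree.root_index()
    stack = [(root, 0)]
    while stack:
        idx, gen = stack.pop()
        tree.elements[idx].generation = gen
        ch = kids[idx]
        nxt = gen + 1 if len(ch) == 2 else gen
        for c in ch:
            stack.append((c, nxt))
    tree.validate()
    return tree


def save_tracks_csv(table: pd.DataFrame, path,
                    cells_per_micron: Optional[float] = None) -> None:
    """Write a track table; the unit scale rides in a # comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if cells_per_micron is not None:
            fh.write(f"# cells_per_micron={cells_per_micron!r}\n")
        fh.write("time_h,tip_id,x,y\n")
        for row in table.itertuples(index=False):
            fh.write(f"{row.time_h:.6g},{row.tip_id},{row.x:.6g},{row.y:.6g}\n")


def load_tracks_csv(path) -> tuple[pd.DataFrame, Optional[float]]:
    """Read a track table; rows are re-sorted per tip by time if needed."""
    scale = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "cells_per_micron=" in first:
                scale = float(first.split("=", 1)[1])
            header_line = fh.readline()
        else:
            header_line = first
        cols = [c.strip() for c in header_line.strip().split(",")]
        missing = [c for c in ("time_h", "tip_id", "x", "y") if c not in cols]
        if missing:
            raise ParseError(path, 1 if first == header_line else 2,
                             f"missing columns {missing}")
        table = pd.read_csv(fh, names=cols, comment="#")
    table["tip_id"] = table["tip_id"].astype(str)
    sorted_tbl = table.sort_values(["tip_id", "time_h"],
                                   kind="stable").reset_index(drop=True)
    if not sorted_tbl[["time_h", "tip_id"]].equals(
        table[["time_h", "tip_id"]].reset_index(drop=True)
    ):
        log.warning("track file %s had out-of-order rows; sorted per tip", path)
    return sorted_tbl, scale


_PARAM_FIELDS = {f.name: f.type for f in dataclasses.fields(ModelParams)}


def save_config(params: ModelParams, path, extra: Optional[dict] = None) -> None:
    lines = ["# selfavoid run configuration"]
    for f in dataclasses.fields(ModelParams):
        val = getattr(params, f.name)
        if val is not None:
            lines.append(f"{f.name}={val}")
    for k, v in (extra or {}).items():
        lines.append(f"{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_config(path) -> tuple[ModelParams, dict]:
    """Parse flat key=value config; unknown keys are returned separately."""
    kwargs: dict = {}
    extra: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(path, lineno, "expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in _PARAM_FIELDS:
                if key in ("domain_width", "domain_height", "contact_chebyshev"):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
            else:
                extra[key] = val
    return ModelParams(**kwargs), extra


def save_field_pgm(grid: np.ndarray, path) -> None:
    """Write a field snapshot as plain (P2) PGM, scaled to 0-255.

    Row 0 of the image is the top of the domain (max y), as an image
    viewer expects.
    """
    lo, hi = float(grid.min()), float(grid.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((grid - lo) / span * 255).astype(int)
    flipped = scaled[::-1]  # y axis points up; PGM rows go top-down
    h, w = flipped.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"P2\n{w} {h}\n255\n")
        for row in flipped:
            fh.write(" ".join(str(v) for v in row) + "\n")


def save_field_png(grid: np.ndarray, path) -> None:
    """Optional PNG snapshot (requires Pillow)."""
    from PIL import Image

    lo, hi = float(grid.min()), float(grid.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((grid - lo) / span * 255).astype(np.uint8)
    Image.fromarray(scaled[::-1], mode="L").save(path)


def save_run(result, params: ModelParams, out_dir,
             scenario=None, seed: Optional[int] = None,
             snapshots: bool = False) -> None:
    """Write a full simulation run into a directory.

    Contents: one JSON + SWC per tree, tracks.csv, bifurcations.csv,
    the resolved config echo, and optionally a PGM field snapshot of
    the final state.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tree in result.trees:
        save_tree_json(tree, out / f"tree_{tree.tree_id}.json")
        save_tree_swc(tree, out / f"tree_{tree.tree_id}.swc")
    save_tracks_csv(result.tracks, out / "tracks.csv",
                    cells_per_micron=params.cells_per_micron)
    with open(out / "bifurcations.csv", "w", encoding="utf-8") as fh:
        fh.write("step,x,y,parent_generation,tree_id\n")
        for b in result.bifurcations:
            fh.write(f"{b.step},{b.cell[0]},{b.cell[1]},"
                     f"{b.parent_generation},{b.tree_id}\n")
    extra = {}
    if scenario is not None:
        extra["scenario"] = scenario.name
        extra["trunk_length"] = scenario.resolved_trunk_length()
        if scenario.name == "offset_pair":
            extra["lateral_offset"] = scenario.lateral_offset
    if seed is not None:
        extra["seed"] = seed
    extra["steps_run"] = result.state.step
    save_config(params, out / "config.txt", extra=extra)
    if snapshots:
        grid = field_grid(result.trees, params)
        save_field_pgm(grid, out / "field_final.pgm")
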