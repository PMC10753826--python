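"""Layered core-community delineation over a prevalence x detection grid.

A taxon belongs to the core community at thresholds (p, d) when its relative
abundance exceeds the detection threshold d in at least a fraction p of the
samples.  Because no single (p, d) pair is canonical, the core is computed
over a whole grid of threshold combinations; the grid cells are then
linearised into nested "core layers" — an inclusive Venn construct whose
innermost layer holds the most ubiquitous taxa (highest prevalence and
detection thresholds survive) and whose outer layers admit increasingly
marginal taxa.

Thresholds are fractions in [0, 1] internally; the percent-facing helpers
convert at exactly value / 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import RelAbundanceTable

__all__ = [
    "DEFAULT_PREVALENCE_GRID",
    "DEFAULT_DETECTION_GRID",
    "CoreThresholds",
    "CoreSet",
    "CoreGrid",
    "CoreLayers",
    "core_membership",
    "compute_core_grid",
    "build_core_layers",
    "innermost_core",
    "export_core_sets",
    "load_core_sets",
]

#: Prevalence thresholds 30% .. 100% in steps of 5% (as fractions).
DEFAULT_PREVALENCE_GRID: tuple[float, ...] = tuple(
    round(p, 10) for p in np.arange(0.30, 1.0000001, 0.05)
)

#: Detection (relative-abundance) thresholds, in fractions of total abundance:
#: 0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50, 0.75, 1.00, 2.00, 5.00, 10.00 percent.
DEFAULT_DETECTION_GRID: tuple[float, ...] = (
    0.0005, 0.001, 0.0015, 0.002, 0.003, 0.004, 0.005, 0.0075, 0.01, 0.02, 0.05, 0.10,
)


def percent(values: Sequence[float]) -> tuple[float, ...]:
    """Convert percent-scale thresholds to fractions (exactly value / 100)."""
    return tuple(v / 100 for v in values)


@dataclass(frozen=True)
class CoreThresholds:
    """A (prevalence, detection) threshold pair, both fractions in [0, 1]."""

    p: float
    d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"prevalence threshold p={self.p} outside [0, 1]")
        if not (0.0 <= self.d <= 1.0):
            raise ValueError(f"detection threshold d={self.d} outside [0, 1]")


@dataclass
class CoreSet:
    """Core members at one threshold pair, with each member's occupancy.

    ``occupancy[t]`` is the fraction of samples in which taxon ``t`` exceeds
    the detection threshold; every member's occupancy is >= p by construction.
    """

    thresholds: CoreThresholds
    members: frozenset[str]
    occupancy: Mapping[str, float]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def max_occupancy(self) -> float:
        if not self.members:
            return 0.0
        return max(self.occupancy[m] for m in self.members)


Comparison = Literal["strict", "inclusive"]


def core_membership(
    rel: RelAbundanceTable,
    thresholds: CoreThresholds,
    *,
    detection_cmp: Comparison = "strict",
    prevalence_cmp: Comparison = "inclusive",
    exclude: Sequence[str] = (),
) -> CoreSet:
    """Core members at one (p, d) pair.

    A taxon is present in a sample when its abundance is above the detection
    threshold (strict ``>`` by default — d is the threshold *above which* a
    taxon counts as present); it is a core member when its occupancy — the
    fraction of samples where it is present — reaches the prevalence
    threshold (inclusive ``>=`` by default).  Both comparisons are
    configurable because core definitions differ between toolkits.

    Taxa named in ``exclude`` (typically the pooled ``unassigned`` bucket,
    which is a bookkeeping row rather than a taxon) are never candidates;
    abundances are not renormalised.
    """
    values = rel.values.to_numpy(dtype=float)
    n_samples = values.shape[1]
    if n_samples == 0 or values.shape[0] == 0:
        return CoreSet(thresholds, frozenset(), {})
    present = values > thresholds.d if detection_cmp == "strict" else values >= thresholds.d
    occ = present.sum(axis=1) / n_samples
    if prevalence_cmp == "inclusive":
        member_mask = occ >= thresholds.p
    else:
        member_mask = occ > thresholds.p
    ids = np.asarray(rel.feature_ids, dtype=object)
    if exclude:
        member_mask &= ~np.isin(ids, list(exclude))
    members = frozenset(ids[member_mask])
    occupancy = {t: float(o) for t, o in zip(ids, occ) if t in members}
    return CoreSet(thresholds, members, occupancy)


@dataclass
class CoreGrid:
    """Core sets for every combination of the two threshold grids."""

    p_grid: tuple[float, ...]
    d_grid: tuple[float, ...]
    cells: dict[tuple[float, float], CoreSet]

    def cell(self, p: float, d: float) -> CoreSet:
        return self.cells[(p, d)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (p, d, taxon, occupancy)."""
        rows = []
        for (p, d), cs in self.cells.items():
            for taxon in sorted(cs.members):
                rows.append((p, d, taxon, cs.occupancy[taxon]))
        return pd.DataFrame(rows, columns=["prevalence", "detection", "taxon", "occupancy"])


def _check_grid(grid: Sequence[float], name: str) -> tuple[float, ...]:
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError(f"{name} grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError(f"{name} grid must be strictly increasing: {grid}")
    if any(not (0.0 <= g <= 1.0) for g in grid):
        raise ValueError(f"{name} grid values must be fractions in [0, 1]: {grid}")
    return grid


def compute_core_grid(
    rel: RelAbundanceTable,
    p_grid: Sequence[float] = DEFAULT_PREVALENCE_GRID,
    d_grid: Sequence[float] = DEFAULT_DETECTION_GRID,
    **cmp_kwargs,
) -> CoreGrid:
    """Evaluate :func:`core_membership` for every grid combination."""
    p_grid = _check_grid(p_grid, "prevalence")
    d_grid = _check_grid(d_grid, "detection")
    cells = {
        (p, d): core_membership(rel, CoreThresholds(p, d), **cmp_kwargs)
        for p in p_grid
        for d in d_grid
    }
    return CoreGrid(p_grid, d_grid, cells)


@dataclass
class CoreLayers:
    """Nested chain of core sets, innermost (most stringent non-empty) first."""

    layers: list[CoreSet]
    mode: str

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)


LayerMode = Literal["diagonal", "union-rank"]


def _diagonal_chain(grid: CoreGrid) -> list[CoreSet]:
    # Walk from the strictest corner outward, pairing the k-th largest
    # prevalence with the k-th largest detection value; the shorter grid is
    # index-mapped proportionally onto the longer so both end at their minima.
    ps = sorted(grid.p_grid, reverse=True)
    ds = sorted(grid.d_grid, reverse=True)
    n = max(len(ps), len(ds))

    def pick(seq: list[float], k: int) -> float:
        if n == 1:
            return seq[0]
        idx = round(k * (len(seq) - 1) / (n - 1))
        return seq[idx]

    return [grid.cell(pick(ps, k), pick(ds, k)) for k in range(n)]


def _union_rank_chain(grid: CoreGrid) -> list[CoreSet]:
    # Strictness rank of a cell = number of grid cells it dominates (both
    # thresholds <= the cell's, itself included); high rank = strict cell.
    ps, ds = grid.p_grid, grid.d_grid
    ranked: dict[int, list[CoreSet]] = {}
    for i, p in enumerate(ps):
        for j, d in enumerate(ds):
            rank = (i + 1) * (j + 1)
            ranked.setdefault(rank, []).append(grid.cell(p, d))
    max_rank = len(ps) * len(ds)
    layers: list[CoreSet] = []
    for k in sorted(set(ranked), reverse=True):
        cells = [c for r, cs in ranked.items() if r >= k for c in cs]
        union: set[str] = set()
        occupancy: dict[str, float] = {}
        p_min = min(c.thresholds.p for c in cells)
        d_min = min(c.thresholds.d for c in cells)
        for c in cells:
            union |= c.members
            for t in c.members:
                occupancy[t] = max(occupancy.get(t, 0.0), c.occupancy[t])
        layers.append(CoreSet(CoreThresholds(p_min, d_min), frozenset(union), occupancy))
    return layers


def build_core_layers(grid: CoreGrid, mode: LayerMode = "diagonal") -> CoreLayers:
    """Linearise the 2-D grid into nested layers, innermost first.

    ``diagonal`` (default) walks the grid's main diagonal from the strictest
    corner outward — nested by the monotonicity of core membership in both
    thresholds.  ``union-rank`` unions all cells of at least a given
    strictness rank.  Consecutive identical member sets are collapsed either
    way.
    """
    if mode == "diagonal":
        chain = _diagonal_chain(grid)
    elif mode == "union-rank":
        chain = _union_rank_chain(grid)
    else:
        raise ValueError(f"unknown layer mode: {mode!r}")
    collapsed: list[CoreSet] = []
    for cs in chain:
        if collapsed and cs.members == collapsed[-1].members:
            continue
        collapsed.append(cs)
    return CoreLayers(collapsed, mode)


def innermost_core(grid: CoreGrid) -> tuple[CoreSet, float]:
    """The non-empty cell at the lexicographically highest (p, d).

    Prevalence is the leading parameter: among non-empty cells the one with
    the highest prevalence threshold wins, detection breaking ties.  Returns
    the cell and the maximum per-taxon occupancy among its members (0.0 when
    every cell is empty, together with the strictest — empty — cell).
    """
    best: tuple[float, float] | None = None
    for p in grid.p_grid:
        for d in grid.d_grid:
            if grid.cell(p, d).members and (best is None or (p, d) > best):
                best = (p, d)
    if best is None:
        strictest = (grid.p_grid[-1], grid.d_grid[-1])
        return grid.cell(*strictest), 0.0
    cell = grid.cell(*best)
    return cell, cell.max_occupancy


def export_core_sets(layers: CoreLayers, path: str | Path) -> None:
    """Write the nested layers as JSON (thresholds, members, occupancies).

    The listing is the set-family input an external Venn renderer needs; no
    layout geometry is computed here.
    """
    payload = {
        "mode": layers.mode,
        "layers": [
            {
                "rank": k,
                "prevalence": cs.thresholds.p,
                "detection": cs.thresholds.d,
                "members": sorted(cs.members),
                "occupancy": {t: cs.occupancy[t] for t in sorted(cs.members)},
            }
            for k, cs in enumerate(layers)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_core_sets(path: str | Path) -> CoreLayers:
    """Read layers written by :func:`export_core_sets` (round-trip inverse)."""
    payload = json.loads(Path(path).read_text())
    layers = [
        CoreSet(
            CoreThresholds(entry["prevalence"], entry["detection"]),
            frozenset(entry["members"]),
            dict(entry["occupancy"]),
        )
        for entry in payload["layers"]
    ]
    return CoreLayers(layers, payload["mode"])
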