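"""Cell-state catalog: top-N marker combinations plus singleton states.

A *cell state* is a set of markers (e.g. CD3+CD8). The catalog contains the
``top_n`` most frequent exact positivity patterns pooled across all slides,
plus a singleton state for every panel marker not already represented as a
singleton, plus the stromal sentinel (all markers negative). State
*membership* is by superset matching: a cell belongs to a state if it is
positive for all the state's markers, whatever else it expresses — so a
CD3+CD8+ cell is a member of CD3, CD8 and CD3+CD8 alike. Stromal membership
is exact (no positive marker).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cells import CellTable
from .panel import MarkerPanel, PANELS

STROMAL_LABEL = "Stromal"
DEFAULT_TOP_N = 20


@dataclass(frozen=True)
class CellState:
    """A marker combination; the stromal sentinel has an empty marker set."""

    label: str
    marker_set: frozenset[str]
    rank: int
    count: int = 0  # pooled exact-pattern count at catalog build time

    @property
    def is_stromal(self) -> bool:
        return len(self.marker_set) == 0


@dataclass
class CellStateCatalog:
    panel: MarkerPanel
    states: list[CellState]
    top_n: int = DEFAULT_TOP_N

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("catalog labels must be unique")
        if sum(s.is_stromal for s in self.states) != 1:
            raise ValueError("catalog must contain exactly one stromal state")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, label: str) -> CellState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "panel": self.panel.name,
            "top_n": self.top_n,
            "states": [
                {
                    "label": s.label,
                    "markers": _panel_order(self.panel, s.marker_set),
                    "rank": s.rank,
                    "count": s.count,
                }
                for s in self.states
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CellStateCatalog":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        panel = PANELS[payload["panel"]]
        states = [
            CellState(
                label=s["label"],
                marker_set=frozenset(s["markers"]),
                rank=s["rank"],
                count=s.get("count", 0),
            )
            for s in payload["states"]
        ]
        return cls(panel=panel, states=states, top_n=payload["top_n"])


def _panel_order(panel: MarkerPanel, markers: frozenset[str]) -> list[str]:
    return [m for m in panel.markers if m in markers]


def state_label(panel: MarkerPanel, markers: frozenset[str]) -> str:
    """Human-readable label, markers in panel order: ``CD3+CD8``."""
    if not markers:
        return STROMAL_LABEL
    return "+".join(_panel_order(panel, markers))


def enumerate_states(
    tables: list[CellTable],
    top_n: int = DEFAULT_TOP_N,
    prune_below: float | None = None,
) -> CellStateCatalog:
    """Build the cell-state catalog from exact positivity patterns.

    Patterns are counted pooled across all slides; the ``top_n`` non-empty
    patterns by count are taken (ties broken lexicographically by sorted
    marker names, then by smaller set), then a singleton state is appended
    for every marker without a singleton among them, then the stromal
    sentinel. With ``prune_below`` (a prevalence fraction, e.g. ``0.001``),
    top-N states rarer than that fraction of all cells are dropped after
    ranking; default keeps everything.
    """
    if not tables:
        raise ValueError("need at least one cell table")
    panel = tables[0].panel
    for t in tables:
        if t.panel.markers != panel.markers:
            raise ValueError("all tables must share one marker panel")

    counts: dict[frozenset[str], int] = {}
    total_cells = 0
    marker_arr = np.array(panel.markers)
    for t in tables:
        pos = t.positivity()
        total_cells += len(pos)
        patterns, n = np.unique(pos, axis=0, return_counts=True)
        for row, c in zip(patterns, n):
            key = frozenset(marker_arr[row])
            counts[key] = counts.get(key, 0) + int(c)

    nonempty = {k: v for k, v in counts.items() if k}
    if not nonempty:
        warnings.warn("all cells are marker-negative; catalog is stromal-only")
        return CellStateCatalog(
            panel=panel,
            states=[CellState(STROMAL_LABEL, frozenset(), rank=1, count=counts.get(frozenset(), 0))],
            top_n=top_n,
        )

    ordered = sorted(
        nonempty.items(),
        key=lambda kv: (-kv[1], tuple(sorted(kv[0])), len(kv[0])),
    )
    top = ordered[:top_n]
    if prune_below is not None:
        floor = prune_below * total_cells
        top = [(k, v) for k, v in top if v >= floor]

    states: list[CellState] = []
    for rank, (markers, count) in enumerate(top, start=1):
        states.append(
            CellState(state_label(panel, markers), markers, rank=rank, count=count)
        )

    singleton_sets = {s.marker_set for s in states if len(s.marker_set) == 1}
    rank = len(states)
    for marker in panel.markers:
        single = frozenset([marker])
        if single not in singleton_sets:
            rank += 1
            states.append(
                CellState(
                    state_label(panel, single),
                    single,
                    rank=rank,
                    count=nonempty.get(single, 0),
                )
            )
    states.append(
        CellState(STROMAL_LABEL, frozenset(), rank=rank + 1, count=counts.get(frozenset(), 0))
    )
    return CellStateCatalog(panel=panel, states=states, top_n=top_n)


def membership_matrix(
    positivity: np.ndarray, catalog: CellStateCatalog
) -> np.ndarray:
    """(n_cells, n_states) boolean superset-membership matrix.

    Column order follows ``catalog.states``. A cell is a member of state S
    iff it is positive for every marker of S; of the stromal state iff it is
    positive for none.
    """
    positivity = np.asarray(positivity, dtype=bool)
    n = positivity.shape[0]
    out = np.empty((n, catalog.n_states), dtype=bool)
    marker_index = {m: i for i, m in enumerate(catalog.panel.markers)}
    any_pos = positivity.any(axis=1)
    for j, state in enumerate(catalog.states):
        if state.is_stromal:
            out[:, j] = ~any_pos
        else:
            idx = [marker_index[m] for m in state.marker_set]
            out[:, j] = positivity[:, idx].all(axis=1)
    return out


def state_membership(
    positivity_row: np.ndarray | list[bool], catalog: CellStateCatalog
) -> np.ndarray:
    """Membership vector over catalog states for a single cell."""
    row = np.asarray(positivity_row, dtype=bool).reshape(1, -1)
    if row.shape[1] != len(catalog.panel.markers):
        raise ValueError("positivity length must equal panel size")
    return membership_matrix(row, catalog)[0]
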