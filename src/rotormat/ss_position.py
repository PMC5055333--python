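"""Dihedral-window secondary-structure assignment and flank labeling.

Residues are classified into three groups — helix (H), sheet (S) and
other (O) — purely from their main-chain (phi, psi) pair falling inside
configurable Ramachandran windows; no hydrogen-bond geometry is used.
Around every maximal helix or sheet element the three residues on either
side are labeled with flank offsets -3..-1 (entering) and +1..+3
(leaving), the X-3 .. X+3 positions used when pooling dihedral
statistics by position relative to an element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .structure_io import RotorRecord

__all__ = [
    "SSConfig",
    "DEFAULT_CONFIG",
    "Element",
    "PositionLabel",
    "FLANK_REACH",
    "assign_secondary_structure",
    "segment_elements",
    "label_flanks",
    "write_position_labels",
]

#: Flank labels extend exactly three residues on either side of an element.
FLANK_REACH = 3


@dataclass(frozen=True)
class SSConfig:
    """Dihedral windows (degrees, open intervals except noted) and minimum run lengths.

    Defaults are conventional Ramachandran regions: the alpha-helical
    basin and the broad beta region; the sheet psi window is closed at
    +180 so the wrap point belongs to it.  Minimum lengths of 4 (one
    helical turn) and 3 (a short strand) demote isolated hits to O.
    """

    helix_phi: tuple[float, float] = (-100.0, -30.0)
    helix_psi: tuple[float, float] = (-80.0, -5.0)
    sheet_phi: tuple[float, float] = (-170.0, -50.0)
    sheet_psi: tuple[float, float] = (90.0, 180.0)
    min_helix_length: int = 4
    min_sheet_length: int = 3


DEFAULT_CONFIG = SSConfig()


class Element(NamedTuple):
    """A maximal helix or sheet run, inclusive residue index range."""

    kind: str  # 'H' or 'S'
    start_index: int
    end_index: int


class PositionLabel(NamedTuple):
    """Element kind plus flank offset; offset 0 means inside the element."""

    kind: str
    offset: int


def _in_window(value: float, window: tuple[float, float], closed_upper: bool) -> bool:
    lo, hi = window
    return lo < value <= hi if closed_upper else lo < value < hi


def _raw_label(rec: RotorRecord, cfg: SSConfig) -> str:
    if rec.phi is None or rec.psi is None:
        return "O"
    if _in_window(rec.phi, cfg.helix_phi, False) and _in_window(rec.psi, cfg.helix_psi, False):
        return "H"
    if _in_window(rec.phi, cfg.sheet_phi, False) and _in_window(
        rec.psi, cfg.sheet_psi, closed_upper=cfg.sheet_psi[1] >= 180.0
    ):
        return "S"
    return "O"


def assign_secondary_structure(
    records: Sequence[RotorRecord], config: SSConfig = DEFAULT_CONFIG
) -> list[str]:
    """Label each residue H, S or O from its (phi, psi) pair.

    Residues with an undefined phi or psi are O.  Runs of H shorter than
    ``min_helix_length`` and runs of S shorter than ``min_sheet_length``
    are demoted to O, so every surviving labeled run is a bona fide
    element.  The assignment is a pure function of (records, config).
    """
    labels = [_raw_label(r, config) for r in records]
    minimum = {"H": config.min_helix_length, "S": config.min_sheet_length}
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in minimum and (j - i) < minimum[labels[i]]:
            labels[i:j] = ["O"] * (j - i)
        i = j
    return labels


def segment_elements(labels: Sequence[str]) -> list[Element]:
    """Maximal H and S runs as inclusive-range elements, ordered by start."""
    elements: list[Element] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in ("H", "S"):
            elements.append(Element(labels[i], i, j - 1))
        i = j
    return elements


def label_flanks(
    elements: Iterable[Element], n_residues: int
) -> dict[int, set[PositionLabel]]:
    """Map residue index -> set of position labels contributed by *elements*.

    Each element labels its interior residues with offset 0, the three
    residues upstream with -3..-1 and the three downstream with +1..+3,
    truncated at the chain ends.  A residue between two nearby elements
    keeps the labels from both (multi-labeling, no precedence).
    """
    out: dict[int, set[PositionLabel]] = {}

    def add(idx: int, label: PositionLabel):
        if 0 <= idx < n_residues:
            out.setdefault(idx, set()).add(label)

    for el in elements:
        for idx in range(el.start_index, el.end_index + 1):
            add(idx, PositionLabel(el.kind, 0))
        for k in range(1, FLANK_REACH + 1):
            add(el.start_index - k, PositionLabel(el.kind, -k))
            add(el.end_index + k, PositionLabel(el.kind, +k))
    return out


def write_position_labels(
    records: Sequence[RotorRecord],
    labels: Mapping[int, set[PositionLabel]],
    path: str | Path,
) -> None:
    """Write one TSV row per (residue, position label)."""
    rows = []
    by_index = {r.sequence_index: r for r in records}
    for idx in sorted(labels):
        rec = by_index.get(idx)
        for kind, offset in sorted(labels[idx]):
            rows.append(
                {
                    "chain": rec.chain_id if rec else "",
                    "index": idx,
                    "aa": rec.residue_name if rec else "X",
                    "kind": kind,
                    "offset": offset,
                }
            )
    pd.DataFrame(rows, columns=["chain", "index", "aa", "kind", "offset"]).to_csv(
        path, sep="\t", index=False
    )
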