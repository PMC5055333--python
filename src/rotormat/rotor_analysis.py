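"""Rotor rotation directions across secondary-structure transitions.

During formation of an element the modal (most populated) angle of each
rotor shifts between the flank position three residues out (offset -3)
and the element interior (offset 0); during breaking, between offset 0
and offset +3.  The sign of the minimal arc between the two modal
angles gives the rotor's rotation direction: '+' is right-handed
(clockwise, increasing dihedral), '-' left-handed, '0' no net rotation
within a tolerance of half a grid bin.

The reference direction patterns are:

=====  ==========  ====  ====  =====  =====
kind   transition  phi   psi   chi1   chi2
=====  ==========  ====  ====  =====  =====
H      formation    +     +     -      +
H      breaking     -     +     +      -
S      formation    -     +     +      -
S      breaking     +     -     -      +
=====  ==========  ====  ====  =====  =====

Built into the table is the counter-rotation of the two side-chain
rotors (chi1 and chi2 always move in opposite directions) and of chi1
against phi.  The table is overridable: the narrative source material
for these patterns is internally inconsistent about psi (described both
as always left-handed outside sheet breaking and as right-handed
throughout helix formation and breaking); the defaults follow the
per-transition figure annotations.  Note also that helix breaking and
sheet formation share a sign row — the patterns alone do not
distinguish them.  A net arc cannot represent a full-circle rotation,
so the per-offset modal trajectory is kept in the report to expose
multi-step paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import RotormatError
from .geometry import signed_arc
from .structure_io import ROTOR_NAMES, RotorRecord
from .basin_stats import grid_center

__all__ = [
    "SignVector",
    "TransitionReport",
    "MatchResult",
    "DEFAULT_ZERO_TOLERANCE",
    "modal_angle",
    "transition_signs",
    "expected_sign_table",
    "match_pattern",
    "write_transition_report",
]

#: Displacements smaller than half a 10-degree bin count as no rotation.
DEFAULT_ZERO_TOLERANCE = 5.0

_FORMATION_OFFSETS = (-3, -2, -1, 0)
_BREAKING_OFFSETS = (0, 1, 2, 3)

_EXPECTED_SIGNS = {
    ("H", "formation"): {"phi": "+", "psi": "+", "chi1": "-", "chi2": "+"},
    ("H", "breaking"): {"phi": "-", "psi": "+", "chi1": "+", "chi2": "-"},
    ("S", "formation"): {"phi": "-", "psi": "+", "chi1": "+", "chi2": "-"},
    ("S", "breaking"): {"phi": "+", "psi": "-", "chi1": "-", "chi2": "+"},
}


class SignVector(NamedTuple):
    """Per-rotor rotation direction, each '+', '-' or '0'."""

    phi: str
    psi: str
    chi1: str
    chi2: str

    def rotor(self, name: str) -> str:
        return getattr(self, name)


@dataclass
class TransitionReport:
    """Modal trajectory, net displacement and direction per rotor.

    ``modes[rotor][offset]`` is the 10-degree modal center at that flank
    offset (None when the rotor has no defined angles there);
    ``displacements[rotor]`` is the minimal signed arc from the start to
    the end offset of the transition, in (-180, +180].
    """

    kind: str
    transition: str
    offsets: tuple[int, ...]
    modes: dict[str, dict[int, float | None]]
    displacements: dict[str, float | None]
    signs: SignVector


@dataclass(frozen=True)
class MatchResult:
    """Per-rotor agreement with the reference sign pattern."""

    rotor_match: dict[str, bool]
    all_match: bool
    counter_rotation_ok: bool


def modal_angle(records: Sequence[RotorRecord], rotor: str) -> float | None:
    """Most populated 10-degree grid center of a rotor's marginal.

    Ties are broken toward the center nearest 0, and between +/-c toward
    the negative one.  Returns None when no record has the rotor defined.
    """
    counts: dict[int, int] = {}
    for rec in records:
        a = rec.rotor(rotor)
        if a is None:
            continue
        c = grid_center(a)
        counts[c] = counts.get(c, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    candidates = sorted((c for c, k in counts.items() if k == best), key=lambda c: (abs(c), c))
    return float(candidates[0])


def _sign(displacement: float | None, tol: float) -> str:
    if displacement is None:
        return "0"
    if displacement > tol:
        return "+"
    if displacement < -tol:
        return "-"
    return "0"


def transition_signs(
    records_by_offset: Mapping[int, Sequence[RotorRecord]],
    kind: str,
    transition: str,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
) -> TransitionReport:
    """Direction of each rotor's modal shift across a transition.

    Formation runs from offset -3 to 0, breaking from 0 to +3; all four
    offsets must be present.  The displacement is the minimal signed arc
    between the modal angles at the two end offsets; intermediate modes
    are reported so multi-step trajectories remain visible.  The result
    does not depend on record order within an offset.
    """
    if kind not in ("H", "S"):
        raise RotormatError(f"unknown element kind {kind!r}; expected 'H' or 'S'")
    if transition == "formation":
        offsets = _FORMATION_OFFSETS
    elif transition == "breaking":
        offsets = _BREAKING_OFFSETS
    else:
        raise RotormatError(
            f"unknown transition {transition!r}; expected 'formation' or 'breaking'"
        )
    for off in offsets:
        if off not in records_by_offset or not records_by_offset[off]:
            raise RotormatError(f"transition {kind}/{transition}: missing offset {off:+d}")

    modes: dict[str, dict[int, float | None]] = {}
    displacements: dict[str, float | None] = {}
    signs = {}
    for rotor in ROTOR_NAMES:
        modes[rotor] = {off: modal_angle(records_by_offset[off], rotor) for off in offsets}
        start, end = modes[rotor][offsets[0]], modes[rotor][offsets[-1]]
        disp = None if start is None or end is None else signed_arc(start, end)
        displacements[rotor] = disp
        signs[rotor] = _sign(disp, zero_tolerance)
    return TransitionReport(
        kind=kind,
        transition=transition,
        offsets=offsets,
        modes=modes,
        displacements=displacements,
        signs=SignVector(**signs),
    )


def expected_sign_table(
    kind: str,
    transition: str,
    overrides: Mapping[tuple[str, str], Mapping[str, str]] | None = None,
) -> SignVector:
    """Reference rotation-direction pattern for a transition (overridable)."""
    table = dict(_EXPECTED_SIGNS)
    if overrides:
        for key, row in overrides.items():
            table[key] = {**table.get(key, {}), **row}
    key = (kind, transition)
    if key not in table:
        raise RotormatError(f"no expected sign pattern for kind={kind!r}, transition={transition!r}")
    return SignVector(**table[key])


def match_pattern(
    report: TransitionReport, expected: SignVector | None = None
) -> MatchResult:
    """Compare a report's signs with the reference pattern.

    Also checks, independently of the pattern, the side-chain
    counter-rotation relation sign(chi1) = -sign(chi2) (with 0 matching
    only 0).
    """
    if expected is None:
        expected = expected_sign_table(report.kind, report.transition)
    rotor_match = {r: report.signs.rotor(r) == expected.rotor(r) for r in ROTOR_NAMES}
    flip = {"+": "-", "-": "+", "0": "0"}
    counter = report.signs.chi1 == flip[report.signs.chi2] and report.signs.chi1 != "0"
    if report.signs.chi1 == "0" and report.signs.chi2 == "0":
        counter = True  # vacuously counter-rotating: neither rotor moved
    return MatchResult(
        rotor_match=rotor_match,
        all_match=all(rotor_match.values()),
        counter_rotation_ok=counter,
    )


def write_transition_report(report: TransitionReport, path: str | Path) -> None:
    """Write per-rotor modes, displacement and sign as TSV."""
    rows = []
    for rotor in ROTOR_NAMES:
        row = {
            "kind": report.kind,
            "transition": report.transition,
            "rotor": rotor,
            "displacement": report.displacements[rotor],
            "sign": report.signs.rotor(rotor),
        }
        for off in report.offsets:
            row[f"mode_{off:+d}"] = report.modes[rotor][off]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
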