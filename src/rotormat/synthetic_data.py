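"""Synthetic fixtures: ideal chains, basin-weighted samples, transition cohorts.

Three generators cover the package's input space without any external
download:

* :func:`build_ideal_chain` places a backbone (N, CA, C, O, CB) by
  sequential internal-coordinate (NeRF) construction at prescribed
  phi/psi torsions with ideal bond lengths and angles and a fixed trans
  peptide (omega = 180).  It is the geometric oracle for the dihedral
  extractor: angles put in must come back out.
* :func:`sample_rotor_records` draws per-residue rotor angles by first
  choosing one of the four basins according to prescribed weights, then
  sampling uniformly within the basin (basin 1 on its wrapped interval
  through +/-180).  No claim is made about real rotamer statistics; the
  generator exercises exactly the basin abstraction.
* :func:`make_transition_cohort` produces flank-offset cohorts whose
  rotor angles follow a wrapped normal around prescribed per-offset
  modal angles, emulating the modal-basin shifts seen when residues
  enter or leave a secondary-structure element.

All generators are deterministic given (parameters, seed) and emit
angles in (-180, +180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import RotormatError
from .geometry import normalize_angle, place_atom, signed_arc
from .structure_io import (
    AtomRecord,
    ONE_TO_THREE,
    ROTOR_NAMES,
    RotorRecord,
    THREE_TO_ONE,
)
from .basin_stats import valid_rotors

__all__ = [
    "IDEAL_GEOMETRY",
    "BasinWeights",
    "CohortSpec",
    "BASIN_INTERVALS",
    "sample_rotor_records",
    "build_ideal_chain",
    "make_transition_cohort",
    "reference_cohort_spec",
]

#: Ideal backbone internal coordinates (lengths in Angstrom, angles in
#: degrees).  They need only be internally consistent: the round-trip
#: oracle compares torsions, which are independent of these constants.
IDEAL_GEOMETRY = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,
    "bond_C_O": 1.231,
    "bond_CA_CB": 1.521,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "angle_CA_C_O": 120.5,
    "angle_C_CA_CB": 110.1,
    "torsion_N_C_CA_CB": 122.6,
    "omega": 180.0,
}

#: Sampling interval per basin; basin 1 is sampled on [150, 210) and
#: wrapped, so it covers [+150, +180] u (-180, -150).
BASIN_INTERVALS = ((150.0, 210.0), (-150.0, -50.0), (-50.0, 50.0), (50.0, 150.0))


@dataclass(frozen=True)
class BasinWeights:
    """Per-rotor probabilities over the four basins (each row sums to 1)."""

    phi: tuple[float, float, float, float]
    psi: tuple[float, float, float, float]
    chi1: tuple[float, float, float, float]
    chi2: tuple[float, float, float, float]

    def __post_init__(self):
        for rotor in ROTOR_NAMES:
            w = np.asarray(getattr(self, rotor), dtype=float)
            if w.shape != (4,) or (w < 0).any():
                raise RotormatError(f"{rotor}: weights must be 4 non-negative reals")
            if abs(w.sum() - 1.0) > 1e-12:
                raise RotormatError(f"{rotor}: weights must sum to 1, got {w.sum()!r}")

    @classmethod
    def uniform(cls) -> "BasinWeights":
        q = (0.25, 0.25, 0.25, 0.25)
        return cls(q, q, q, q)

    @classmethod
    def same(cls, w: Sequence[float]) -> "BasinWeights":
        w = tuple(float(x) for x in w)
        return cls(w, w, w, w)

    def rotor(self, name: str) -> np.ndarray:
        return np.asarray(getattr(self, name), dtype=float)


def _sample_basin_angles(rng: np.random.Generator, weights: np.ndarray, n: int) -> np.ndarray:
    basins = rng.choice(4, size=n, p=weights)
    lo = np.array([BASIN_INTERVALS[b][0] for b in basins])
    hi = np.array([BASIN_INTERVALS[b][1] for b in basins])
    raw = rng.uniform(lo, hi)
    return np.array([normalize_angle(a) for a in raw])


def sample_rotor_records(
    aa: str, weights: BasinWeights, n: int, seed: int
) -> list[RotorRecord]:
    """Draw *n* rotor records for one amino acid from basin weights.

    Rotors the residue type does not possess (glycine side chain, chi2
    of SER/CYS/THR/VAL, ...) are emitted undefined regardless of the
    weights.  Deterministic given the seed.
    """
    if aa not in ONE_TO_THREE:
        raise RotormatError(f"unknown amino acid {aa!r}")
    rng = np.random.default_rng(seed)
    rotors = valid_rotors(aa)
    angles: dict[str, np.ndarray | None] = {}
    for rotor in ROTOR_NAMES:
        if rotor in rotors:
            angles[rotor] = _sample_basin_angles(rng, weights.rotor(rotor), n)
        else:
            angles[rotor] = None
    return [
        RotorRecord(
            residue_name=aa,
            chain_id="A",
            sequence_index=i,
            **{
                rotor: (None if angles[rotor] is None else float(angles[rotor][i]))
                for rotor in ROTOR_NAMES
            },
        )
        for i in range(n)
    ]


def build_ideal_chain(
    rotor_spec: Sequence[tuple[float | None, float | None]],
    residue_types: Sequence[str] | str = None,
) -> list[AtomRecord]:
    """Build a 3-D backbone with prescribed per-residue (phi, psi) torsions.

    ``rotor_spec[i] = (phi_i, psi_i)``; the first residue's phi and the
    last residue's psi are not geometrically realizable (no neighbour on
    that side) and may be None.  ``residue_types`` is a 1-letter string
    or a sequence of 1-/3-letter codes (default poly-alanine).  Side
    chains stop at CB (omitted for glycine); the peptide is trans.
    """
    n = len(rotor_spec)
    if n == 0:
        raise RotormatError("rotor_spec must contain at least one residue")
    if residue_types is None:
        residue_types = "A" * n
    if len(residue_types) != n:
        raise RotormatError("residue_types length must match rotor_spec")
    three_letter = []
    for rt in residue_types:
        code = ONE_TO_THREE.get(rt, rt if rt in THREE_TO_ONE else None)
        if code is None:
            raise RotormatError(f"unknown residue type {rt!r}")
        three_letter.append(code)

    g = IDEAL_GEOMETRY
    atoms: list[AtomRecord] = []
    backbone: list[dict[str, np.ndarray]] = []

    def emit(name: str, resname: str, resnum: int, xyz: np.ndarray):
        atoms.append(
            AtomRecord(
                name=name,
                residue_name=resname,
                chain_id="A",
                residue_number=resnum,
                coordinates=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
            )
        )

    for i, resname in enumerate(three_letter):
        phi = rotor_spec[i][0]
        psi = rotor_spec[i][1]
        if i == 0:
            n_at = np.zeros(3)
            ca = np.array([g["bond_N_CA"], 0.0, 0.0])
            c = place_atom(
                np.array([0.0, 1.0, 0.0]), n_at, ca,
                g["bond_CA_C"], g["angle_N_CA_C"], 0.0,
            )
        else:
            prev = backbone[i - 1]
            psi_prev = rotor_spec[i - 1][1]
            if psi_prev is None:
                raise RotormatError(f"residue {i - 1}: psi required to place residue {i}")
            n_at = place_atom(
                prev["N"], prev["CA"], prev["C"],
                g["bond_C_N"], g["angle_CA_C_N"], psi_prev,
            )
            ca = place_atom(
                prev["CA"], prev["C"], n_at,
                g["bond_N_CA"], g["angle_C_N_CA"], g["omega"],
            )
            if phi is None:
                raise RotormatError(f"residue {i}: phi required for interior residues")
            c = place_atom(
                prev["C"], n_at, ca,
                g["bond_CA_C"], g["angle_N_CA_C"], phi,
            )
        o = place_atom(
            n_at, ca, c,
            g["bond_C_O"], g["angle_CA_C_O"],
            normalize_angle((psi if psi is not None else 0.0) + 180.0),
        )
        backbone.append({"N": n_at, "CA": ca, "C": c})
        emit("N", resname, i + 1, n_at)
        emit("CA", resname, i + 1, ca)
        emit("C", resname, i + 1, c)
        emit("O", resname, i + 1, o)
        if resname != "GLY":
            cb = place_atom(
                n_at, c, ca,
                g["bond_CA_CB"], g["angle_C_CA_CB"], g["torsion_N_C_CA_CB"],
            )
            emit("CB", resname, i + 1, cb)
    return atoms


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a flank-offset cohort with prescribed modal angles.

    ``modes[rotor][offset]`` is the target modal angle (degrees); rotors
    absent from ``modes`` are emitted undefined.  ``sigma`` is the
    wrapped-normal angular noise, ``n`` the number of records per
    offset.
    """

    kind: str
    transition: str
    modes: Mapping[str, Mapping[int, float]]
    sigma: float = 5.0
    n: int = 500
    seed: int = 0
    amino_acid: str = "Q"

    def offsets(self) -> tuple[int, ...]:
        return (-3, -2, -1, 0) if self.transition == "formation" else (0, 1, 2, 3)

    def __post_init__(self):
        if self.kind not in ("H", "S"):
            raise RotormatError(f"unknown kind {self.kind!r}")
        if self.transition not in ("formation", "breaking"):
            raise RotormatError(f"unknown transition {self.transition!r}")
        if self.n < 1:
            raise RotormatError("n must be >= 1")
        if self.sigma < 0:
            raise RotormatError("sigma must be non-negative")
        required = set(self.offsets())
        for rotor, per_offset in self.modes.items():
            if rotor not in ROTOR_NAMES:
                raise RotormatError(f"unknown rotor {rotor!r} in modes")
            missing = required - set(per_offset)
            if missing:
                raise RotormatError(f"{rotor}: modes missing offsets {sorted(missing)}")


def make_transition_cohort(spec: CohortSpec) -> dict[int, list[RotorRecord]]:
    """Per-offset rotor records with wrapped-normal noise around the modes."""
    rng = np.random.default_rng(spec.seed)
    cohort: dict[int, list[RotorRecord]] = {}
    for offset in spec.offsets():
        draws: dict[str, np.ndarray | None] = {}
        for rotor in ROTOR_NAMES:
            per_offset = spec.modes.get(rotor)
            if per_offset is None:
                draws[rotor] = None
                continue
            mode = per_offset[offset]
            raw = mode + rng.normal(0.0, spec.sigma, size=spec.n)
            draws[rotor] = np.array([normalize_angle(a) for a in raw])
        cohort[offset] = [
            RotorRecord(
                residue_name=spec.amino_acid,
                chain_id=str(offset),
                sequence_index=i,
                **{
                    rotor: (None if draws[rotor] is None else float(draws[rotor][i]))
                    for rotor in ROTOR_NAMES
                },
            )
            for i in range(spec.n)
        ]
    return cohort


# Modal endpoints (start, end) per rotor for the four canonical
# transitions.  Helix formation carries the +80-degree right-handed phi
# shift (-140 -> -60); every row is consistent with the reference sign
# pattern of rotor_analysis.expected_sign_table.
_REFERENCE_ENDPOINTS = {
    ("H", "formation"): {"phi": (-140, -60), "psi": (150, -45), "chi1": (-60, 180), "chi2": (180, -90)},
    ("H", "breaking"): {"phi": (-60, -140), "psi": (-45, 100), "chi1": (180, -60), "chi2": (-90, 180)},
    ("S", "formation"): {"phi": (-60, -140), "psi": (60, 130), "chi1": (-60, 60), "chi2": (90, -30)},
    ("S", "breaking"): {"phi": (-140, -60), "psi": (130, 60), "chi1": (60, -60), "chi2": (-30, 90)},
}


def reference_cohort_spec(
    kind: str,
    transition: str,
    n: int = 500,
    sigma: float = 5.0,
    seed: int = 0,
) -> CohortSpec:
    """Canonical cohort spec whose modal shifts realize the reference signs.

    Intermediate offsets interpolate along the minimal arc between the
    start and end modal angles.
    """
    key = (kind, transition)
    if key not in _REFERENCE_ENDPOINTS:
        raise RotormatError(f"no reference endpoints for kind={kind!r}, transition={transition!r}")
    offsets = (-3, -2, -1, 0) if transition == "formation" else (0, 1, 2, 3)
    modes: dict[str, dict[int, float]] = {}
    for rotor, (start, end) in _REFERENCE_ENDPOINTS[key].items():
        arc = signed_arc(start, end)
        modes[rotor] = {
            off: normalize_angle(start + arc * k / 3.0) for k, off in enumerate(offsets)
        }
    return CohortSpec(kind=kind, transition=transition, modes=modes, sigma=sigma, n=n, seed=seed)
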