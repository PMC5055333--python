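"""Frequency grids, four-basin occupancy and basin free energies.

A rotor's angular distribution is coarse-grained two ways:

* a 37 x 37 grid over a pair of rotors, with 10-degree cells centered on
  -180, -170, ..., +180 (the wrap point deliberately occupies two
  distinct centers, +180 and -180, split at +/-175, giving 37 centers
  per axis rather than 36);
* four fixed angular basins partitioning (-180, +180]:

  ======  =============================  =========================
  basin   interval                       convention
  ======  =============================  =========================
  1       [+150, +180] u (-180, -150)    wraps through +/-180
  2       [-150, -50)                    half-open [lower, upper)
  3       [-50, +50)
  4       [+50, +150)
  ======  =============================  =========================

Basin occupancies are converted to free energies dG_i = -RT ln(N_i/B_i)
in kJ/mol, where N_i is the (pseudocounted) count in basin i and the
reference B_i is, depending on the variant: the sum of the remaining
basins (MIDMAT1), their average (MIDMAT2), or the average over all four
basins (MIDMAT3).  A low energy marks a preferred basin; the variants
differ only in how strongly the other basins' mass is aggregated into
the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RotormatError
from .geometry import normalize_angle
from .structure_io import (
    CHI1_GAMMA_ATOM,
    CHI2_DELTA_ATOM,
    ONE_TO_THREE,
    ROTOR_NAMES,
    RotorRecord,
)

__all__ = [
    "GRID_CENTERS",
    "N_BASINS",
    "VARIANTS",
    "Grid37",
    "BasinCounts",
    "EnergyParams",
    "BasinEnergyProfile",
    "grid_center",
    "basin_index",
    "build_frequency_grid",
    "basin_histogram",
    "basin_energies",
    "rotor_energy_profile",
    "valid_rotors",
    "write_grid",
    "write_energy_profiles",
    "read_energy_profiles",
]

GRID_CENTERS = np.arange(-180, 181, 10)
N_BASINS = 4
VARIANTS = ("MIDMAT1", "MIDMAT2", "MIDMAT3")

#: Lower edges of basins 2..4; basin 1 wraps through +/-180.
_BASIN2_LO, _BASIN3_LO, _BASIN4_LO, _BASIN1_LO = -150.0, -50.0, 50.0, 150.0


@dataclass
class Grid37:
    """37 x 37 cell counts for one rotor pair, with provenance metadata."""

    counts: np.ndarray
    rotor_pair: tuple[str, str]
    aa_filter: str | None = None
    position_filter: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (37, 37):
            raise RotormatError(f"grid must be 37x37, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise RotormatError("grid counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return GRID_CENTERS

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BasinCounts:
    """Occupancy of the four angular basins, in basin order 1..4."""

    b: tuple[int, int, int, int]

    @property
    def total(self) -> int:
        return sum(self.b)


@dataclass(frozen=True)
class EnergyParams:
    """Thermodynamic constants and smoothing for basin energies.

    R in J/mol/K, T in K (25 C unless overridden), and a Laplace
    pseudocount added to every basin before taking odds so that empty
    basins stay finite; set pseudocount=0 for exact small-count checks.
    """

    R: float = 8.314
    T: float = 298.15
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.R <= 0 or self.T <= 0:
            raise RotormatError("R and T must be positive")
        if self.pseudocount < 0:
            raise RotormatError("pseudocount must be non-negative")


@dataclass
class BasinEnergyProfile:
    """Basin energies (kJ/mol) for one amino acid: 4 rotors x 4 basins.

    Row order is phi, psi, chi1, chi2.  Rotors the residue type does not
    possess (e.g. chi1/chi2 of glycine) carry a row of zeros and are
    listed in ``missing_rotors``.
    """

    amino_acid: str
    variant: str
    energies: np.ndarray
    missing_rotors: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (4, 4):
            raise RotormatError(f"profile must be 4x4, got {self.energies.shape}")
        if self.variant not in VARIANTS:
            raise RotormatError(f"unknown variant {self.variant!r}")

    def rotor_row(self, rotor: str) -> np.ndarray:
        return self.energies[ROTOR_NAMES.index(rotor)]


def grid_center(angle: float) -> int:
    """Nearest 10-degree grid center for an angle in (-180, +180].

    Ties at a 5-degree midpoint round away from zero, which places
    (+175, +180] on center +180 and (-180, -175] on center -180.
    """
    a = normalize_angle(angle)
    return int(np.sign(a) * np.floor(abs(a) / 10.0 + 0.5)) * 10


def basin_index(angle: float) -> int:
    """0-based basin index (0..3 for basins 1..4) of an angle in degrees."""
    a = normalize_angle(angle)
    if a >= _BASIN1_LO or a < _BASIN2_LO:
        return 0
    if a < _BASIN3_LO:
        return 1
    if a < _BASIN4_LO:
        return 2
    return 3


def build_frequency_grid(
    records: Sequence[RotorRecord],
    rotor_pair: tuple[str, str],
    aa_filter: str | None = None,
    index_filter: set[int] | None = None,
    position_filter: str | None = None,
) -> Grid37:
    """Count records on the 37 x 37 grid of a rotor pair.

    A record contributes exactly one cell when both rotors are defined
    (and it passes the optional amino-acid / residue-index filters);
    otherwise it is skipped.  ``position_filter`` is a provenance string
    stored on the grid (e.g. ``"H-3"``); the actual index selection is
    supplied via ``index_filter``.
    """
    for name in rotor_pair:
        if name not in ROTOR_NAMES:
            raise RotormatError(f"unknown rotor {name!r}; expected one of {ROTOR_NAMES}")
    counts = np.zeros((37, 37), dtype=int)
    for rec in records:
        if aa_filter is not None and rec.residue_name != aa_filter:
            continue
        if index_filter is not None and rec.sequence_index not in index_filter:
            continue
        x = rec.rotor(rotor_pair[0])
        y = rec.rotor(rotor_pair[1])
        if x is None or y is None:
            continue
        counts[grid_center(x) // 10 + 18, grid_center(y) // 10 + 18] += 1
    return Grid37(counts, tuple(rotor_pair), aa_filter, position_filter)


def basin_histogram(angles: Iterable[float]) -> BasinCounts:
    """Count angles into the four basins; counts sum to the input length.

    Angles outside (-180, +180] are normalized into range first.
    """
    b = [0, 0, 0, 0]
    for a in angles:
        b[basin_index(a)] += 1
    return BasinCounts(tuple(b))


def basin_energies(
    counts: BasinCounts, variant: str, params: EnergyParams = EnergyParams()
) -> np.ndarray:
    """Free energy (kJ/mol) of each basin under the chosen reference variant.

    N_i = b_i + pseudocount; with total = sum(N):

    * MIDMAT1: B_i = total - N_i          (sum of remaining basins)
    * MIDMAT2: B_i = (total - N_i)/(n-1)  (average of remaining basins)
    * MIDMAT3: B_i = total/n              (average over all basins)

    dG_i = -R T ln(N_i / B_i) / 1000.
    """
    if variant not in VARIANTS:
        raise RotormatError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    n = np.asarray(counts.b, dtype=float) + params.pseudocount
    total = n.sum()
    if total == 0:
        raise RotormatError(
            "all basin counts are zero and pseudocount is 0; "
            "set a positive pseudocount to define the energies"
        )
    if variant == "MIDMAT1":
        ref = total - n
    elif variant == "MIDMAT2":
        ref = (total - n) / (N_BASINS - 1)
    else:
        ref = np.full(N_BASINS, total / N_BASINS)
    rt_kj = params.R * params.T / 1000.0
    with np.errstate(divide="ignore"):
        return -rt_kj * np.log(n / ref)


def valid_rotors(aa: str) -> tuple[str, ...]:
    """Rotors that exist for a residue type (1-letter code)."""
    three = ONE_TO_THREE.get(aa)
    rotors = ["phi", "psi"]
    if three in CHI1_GAMMA_ATOM or three is None:
        rotors.append("chi1")
    if three in CHI2_DELTA_ATOM or three is None:
        rotors.append("chi2")
    return tuple(rotors)


def rotor_energy_profile(
    records: Sequence[RotorRecord],
    aa: str,
    variant: str,
    params: EnergyParams = EnergyParams(),
) -> BasinEnergyProfile:
    """Basin-energy profile of one amino acid over all four rotors.

    Each rotor's histogram is taken over that rotor's defined angles in
    the records for *aa*.  Rotors with no defined angles (side-chain
    rotors the residue type lacks, or absent from the data) contribute a
    zero row and are flagged in ``missing_rotors``.
    """
    subset = [r for r in records if r.residue_name == aa]
    if not subset:
        raise RotormatError(f"no records for amino acid {aa!r}; cannot build a profile")
    energies = np.zeros((4, 4))
    missing = []
    for i, rotor in enumerate(ROTOR_NAMES):
        angles = [r.rotor(rotor) for r in subset]
        angles = [a for a in angles if a is not None]
        if not angles:
            missing.append(rotor)
            continue
        energies[i] = basin_energies(basin_histogram(angles), variant, params)
    return BasinEnergyProfile(aa, variant, energies, frozenset(missing))


def write_grid(grid: Grid37, path: str | Path) -> None:
    """Write a grid as TSV: header of centers, one labeled row per center."""
    df = pd.DataFrame(grid.counts, index=GRID_CENTERS, columns=GRID_CENTERS)
    df.index.name = f"{grid.rotor_pair[0]}\\{grid.rotor_pair[1]}"
    df.to_csv(path, sep="\t")


def write_energy_profiles(
    profiles: Mapping[str, BasinEnergyProfile] | Iterable[BasinEnergyProfile],
    path: str | Path,
) -> None:
    """Write profiles as a long TSV keyed by (aa, rotor, basin, variant)."""
    if isinstance(profiles, Mapping):
        profiles = profiles.values()
    rows = []
    for p in profiles:
        for i, rotor in enumerate(ROTOR_NAMES):
            for basin in range(N_BASINS):
                rows.append(
                    {
                        "aa": p.amino_acid,
                        "rotor": rotor,
                        "basin": basin + 1,
                        "variant": p.variant,
                        "energy_kj_mol": p.energies[i, basin],
                        "missing": rotor in p.missing_rotors,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_energy_profiles(path: str | Path) -> dict[str, BasinEnergyProfile]:
    """Read profiles written by :func:`write_energy_profiles`."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, BasinEnergyProfile] = {}
    for (aa, variant), sub in df.groupby(["aa", "variant"], sort=False):
        energies = np.zeros((4, 4))
        missing = set()
        for row in sub.itertuples(index=False):
            energies[ROTOR_NAMES.index(row.rotor), int(row.basin) - 1] = row.energy_kj_mol
            if bool(row.missing):
                missing.add(row.rotor)
        out[str(aa)] = BasinEnergyProfile(str(aa), str(variant), energies, frozenset(missing))
    return out
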