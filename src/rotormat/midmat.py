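"""MIDMAT substitution matrices from rotor basin-energy profiles.

The dissimilarity of two amino acids x, y is the Euclidean distance
between their basin-energy profiles,

    D_xy = sqrt( sum_i [ (phi_ix-phi_iy)^2 + (psi_ix-psi_iy)^2
                       + (chi1_ix-chi1_iy)^2 + (chi2_ix-chi2_iy)^2 ] ),

summed over the four basins i (16 squared terms in all).  Distances are
divided by a common denominator (default 1000), centered on the median
over the 190 unordered distinct pairs and scaled by 0.5:

    SV_xy = 0.5 * (median(D) - D_xy),

so similar pairs score positive and dissimilar ones negative.  The
self-score of x is the global maximum off-diagonal substitution value
plus the maximum in row x, applied on unrounded values; the whole
matrix is then rounded once to integers (halves away from zero).  The
three variants MIDMAT1/2/3 differ only in the basin-energy reference
used upstream (see :mod:`rotormat.basin_stats`).

Matrices are read and written in the ASCII scoring-matrix format
understood by BLAST ('#' comments, a header row of one-letter codes,
one labeled row per residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .basin_stats import BasinEnergyProfile, EnergyParams, rotor_energy_profile
from .errors import MatrixFormatError, RotormatError
from .structure_io import RotorRecord

__all__ = [
    "AA_ORDER",
    "MidmatParams",
    "DistanceMatrix",
    "SubstitutionMatrix",
    "distance_matrix",
    "substitution_values",
    "fill_diagonal",
    "round_matrix",
    "build_substitution_matrix",
    "profiles_from_records",
    "write_blast_matrix",
    "read_blast_matrix",
    "load_reference_matrix",
]

#: Canonical residue ordering of the MIDMAT tables.
AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

_EXTENDED = ("B", "Z", "X", "*")


@dataclass(frozen=True)
class MidmatParams:
    """Scaling constants of the distance-to-score conversion."""

    denominator: float = 1000.0
    sv_factor: float = 0.5

    def __post_init__(self):
        if self.denominator <= 0 or self.sv_factor <= 0:
            raise RotormatError("denominator and sv_factor must be positive")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative 20x20 rotor-preference distances, zero diagonal."""

    values: np.ndarray
    order: tuple[str, ...] = AA_ORDER

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.order)
        if self.values.shape != (n, n):
            raise RotormatError(f"distance matrix must be {n}x{n}")
        if not np.allclose(self.values, self.values.T):
            raise RotormatError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise RotormatError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0):
            raise RotormatError("self-distances must be zero")


@dataclass(eq=False)
class SubstitutionMatrix:
    """Integer score table over the 20 amino acids with ordering metadata."""

    scores: np.ndarray
    order: tuple[str, ...] = AA_ORDER
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if not np.issubdtype(self.scores.dtype, np.integer):
            raise RotormatError("substitution scores must be integers")
        n = len(self.order)
        if self.scores.shape != (n, n):
            raise RotormatError(f"score matrix must be {n}x{n}")
        self.order = tuple(self.order)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubstitutionMatrix)
            and self.order == other.order
            and np.array_equal(self.scores, other.scores)
        )

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.scores, self.scores.T))

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.order.index(a), self.order.index(b)])


def distance_matrix(profiles: Mapping[str, BasinEnergyProfile]) -> DistanceMatrix:
    """Pairwise Euclidean distances between the 20 basin-energy profiles.

    All 20 amino acids must be present and computed under the same
    variant; rotors a residue type lacks enter as zero rows, as emitted
    by :func:`rotormat.basin_stats.rotor_energy_profile`.
    """
    missing = [a for a in AA_ORDER if a not in profiles]
    if missing:
        raise RotormatError(f"profiles missing amino acids: {''.join(missing)}")
    extra = [a for a in profiles if a not in AA_ORDER]
    if extra:
        raise RotormatError(f"unexpected amino acids in profiles: {extra}")
    variants = {profiles[a].variant for a in AA_ORDER}
    if len(variants) != 1:
        raise RotormatError(f"profiles mix variants: {sorted(variants)}")
    stack = np.stack([profiles[a].energies.ravel() for a in AA_ORDER])
    diff = stack[:, None, :] - stack[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values)


def pair_median(normalized: np.ndarray) -> float:
    """Median over the unordered distinct pairs (upper triangle, no diagonal)."""
    iu = np.triu_indices(normalized.shape[0], k=1)
    return float(np.median(normalized[iu]))


def substitution_values(D: DistanceMatrix, params: MidmatParams = MidmatParams()) -> np.ndarray:
    """Real-valued off-diagonal scores; the diagonal is NaN until filled.

    Distances are normalized by ``params.denominator``, then each pair's
    score is ``sv_factor * (median - distance)`` with the median taken
    over the 190 unordered distinct pairs.
    """
    normalized = D.values / params.denominator
    m = pair_median(normalized)
    sv = params.sv_factor * (m - normalized)
    np.fill_diagonal(sv, np.nan)
    return sv


def fill_diagonal(sv: np.ndarray) -> np.ndarray:
    """Self-scores from off-diagonal scores, on unrounded values.

    SV_xx = max over all off-diagonal scores + max over row x's
    off-diagonal scores.
    """
    sv = np.array(sv, dtype=float)
    off = sv.copy()
    np.fill_diagonal(off, np.nan)
    global_max = np.nanmax(off)
    row_max = np.nanmax(off, axis=1)
    np.fill_diagonal(sv, global_max + row_max)
    return sv


def round_matrix(
    values: np.ndarray,
    order: Sequence[str] = AA_ORDER,
    provenance: dict | None = None,
) -> SubstitutionMatrix:
    """Round to nearest integer, halves away from zero."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise RotormatError("matrix contains non-finite entries; fill the diagonal first")
    rounded = (np.sign(values) * np.floor(np.abs(values) + 0.5)).astype(int)
    return SubstitutionMatrix(rounded, tuple(order), provenance or {})


def profiles_from_records(
    records: Sequence[RotorRecord],
    variant: str,
    params: EnergyParams = EnergyParams(),
) -> dict[str, BasinEnergyProfile]:
    """Basin-energy profiles for all 20 amino acids from a rotor table."""
    return {aa: rotor_energy_profile(records, aa, variant, params) for aa in AA_ORDER}


def build_substitution_matrix(
    profiles: Mapping[str, BasinEnergyProfile],
    params: MidmatParams = MidmatParams(),
) -> SubstitutionMatrix:
    """Full distance -> score -> diagonal -> rounding pipeline."""
    D = distance_matrix(profiles)
    sv = fill_diagonal(substitution_values(D, params))
    variant = profiles[AA_ORDER[0]].variant
    return round_matrix(
        sv,
        provenance={
            "variant": variant,
            "denominator": params.denominator,
            "sv_factor": params.sv_factor,
        },
    )


def write_blast_matrix(
    m: SubstitutionMatrix,
    path: str | Path,
    pad_blast: bool = False,
    comments: Sequence[str] = (),
) -> None:
    """Write an ASCII scoring matrix readable by BLAST.

    With ``pad_blast`` the ambiguity codes B, Z, X and the stop '*' are
    appended, filled with the matrix minimum, which some BLAST builds
    require.
    """
    order = list(m.order)
    scores = m.scores
    if pad_blast:
        fill = int(scores.min())
        n = len(order)
        padded = np.full((n + 4, n + 4), fill, dtype=int)
        padded[:n, :n] = scores
        scores = padded
        order = order + list(_EXTENDED)
    width = max(3, max(len(str(int(v))) for v in scores.ravel()) + 1)
    lines = [f"# {c}" for c in comments]
    lines.append(" " + "".join(f"{a:>{width}s}" for a in order))
    for i, a in enumerate(order):
        lines.append(a + "".join(f"{int(v):>{width}d}" for v in scores[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_blast_matrix(path: str | Path, strip_extended: bool = True) -> SubstitutionMatrix:
    """Read an ASCII scoring matrix; raises with a line number when malformed.

    ``strip_extended`` drops B/Z/X/* padding so that a padded write
    round-trips to the original 20x20 matrix.  Symmetry is *not*
    enforced on read (use :meth:`SubstitutionMatrix.is_symmetric`).
    """
    path = Path(path)
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    row_order: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if header is None:
            if not all(len(t) == 1 for t in toks):
                raise MatrixFormatError("header must be single-letter codes", lineno)
            header = toks
            continue
        label, *vals = toks
        if len(label) != 1:
            raise MatrixFormatError(f"bad row label {label!r}", lineno)
        if len(vals) != len(header):
            raise MatrixFormatError(
                f"row {label} has {len(vals)} values, expected {len(header)}", lineno
            )
        try:
            rows[label] = [int(v) for v in vals]
        except ValueError:
            raise MatrixFormatError(f"non-integer score in row {label}", lineno) from None
        row_order.append(label)
    if header is None:
        raise MatrixFormatError(f"{path}: no header row found")
    if row_order != header:
        raise MatrixFormatError(
            f"{path}: row labels {row_order} do not match header {header}"
        )
    scores = np.array([rows[a] for a in header], dtype=int)
    order = list(header)
    if strip_extended:
        keep = [i for i, a in enumerate(order) if a not in _EXTENDED]
        scores = scores[np.ix_(keep, keep)]
        order = [order[i] for i in keep]
    return SubstitutionMatrix(scores, tuple(order), {"source": str(path)})


def load_reference_matrix(variant: str) -> SubstitutionMatrix:
    """Load one of the shipped reference matrices MIDMAT1, MIDMAT2 or MIDMAT3.

    These are the published reference score tables, distributed verbatim
    for parsing, comparison and plausibility checks; they are not
    regenerated by this package (doing so would require the original
    structure snapshot they were derived from).
    """
    if variant not in ("MIDMAT1", "MIDMAT2", "MIDMAT3"):
        raise RotormatError(f"unknown reference matrix {variant!r}")
    ref = resources.files("rotormat.data").joinpath(f"{variant}.mat")
    with resources.as_file(ref) as p:
        m = read_blast_matrix(p)
    m.provenance = {"reference": variant}
    return m
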