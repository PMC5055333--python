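import numpy as np
import pytest

import rotormat as rm


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Hand-written minimal ALA-GLY PDB file (standard fixed columns)."""
    text = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00
ATOM      3  C   ALA A   1       2.009   1.421   0.000  1.00  0.00
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00
ATOM      7  CA  GLY A   2       3.988   2.839   0.071  1.00  0.00
ATOM      8  C   GLY A   2       5.454   2.711   0.420  1.00  0.00
ATOM      9  O   GLY A   2       5.933   1.601   0.672  1.00  0.00
TER
END
"""
    path = tmp_path / "dipeptide.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def helical_chain_records():
    """Rotor records of an ideal 10-residue alpha-helical chain."""
    atoms = rm.build_ideal_chain([(-57.0, -47.0)] * 10)
    return rm.extract_rotor_table(rm.group_atoms(atoms)[0])


def random_basin_table(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Random per-amino-acid 4x4 basin-count tables (rotors x basins)."""
    return {aa: rng.integers(1, 2000, size=(4, 4)) for aa in rm.AA_ORDER}


def profiles_from_count_table(table, variant, params=None):
    """Basin-energy profiles straight from count tables (bypasses records)."""
    params = params or rm.EnergyParams(pseudocount=0.0)
    profiles = {}
    for aa, counts in table.items():
        energies = np.stack(
            [
                rm.basin_energies(rm.BasinCounts(tuple(int(c) for c in counts[i])), variant, params)
                for i in range(4)
            ]
        )
        profiles[aa] = rm.BasinEnergyProfile(aa, variant, energies)
    return profiles
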