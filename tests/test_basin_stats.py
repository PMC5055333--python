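"""37x37 grids, four-basin histograms and basin free energies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rotormat as rm
from rotormat.basin_stats import basin_index, grid_center
from rotormat.errors import RotormatError

RT_KJ = 8.314 * 298.15 / 1000.0


def brute_force_energies(counts, variant, pseudocount=0.0):
    """Straight-line scalar evaluation of the three reference variants."""
    n = [c + pseudocount for c in counts]
    total = sum(n)
    out = []
    for i in range(4):
        if variant == "MIDMAT1":
            ref = total - n[i]
        elif variant == "MIDMAT2":
            ref = (total - n[i]) / 3
        else:
            ref = total / 4
        out.append(-8.314 * 298.15 * math.log(n[i] / ref) / 1000.0)
    return out


class TestGrid:
    def test_empty_input_gives_zero_grid(self):
        g = rm.build_frequency_grid([], ("phi", "psi"))
        assert g.counts.shape == (37, 37) and g.total == 0

    def test_wrap_convention_180_occupies_plus_180_cell(self):
        rec = rm.RotorRecord("Q", "A", 0, phi=180.0, chi1=180.0)
        g = rm.build_frequency_grid([rec], ("phi", "chi1"))
        assert g.counts[36, 36] == 1 and g.total == 1

    @pytest.mark.parametrize(
        "angle,center",
        [(180.0, 180), (176.0, 180), (-176.0, -180), (-174.9, -170), (0.0, 0), (63.0, 60), (-45.0, -50)],
    )
    def test_nearest_center_with_split_wrap_cell(self, angle, center):
        assert grid_center(angle) == center

    def test_total_counts_records_with_both_rotors_defined(self):
        recs = rm.sample_rotor_records("Q", rm.BasinWeights.uniform(), 500, seed=7)
        g = rm.build_frequency_grid(recs, ("phi", "chi2"))
        expected = sum(1 for r in recs if r.phi is not None and r.chi2 is not None)
        assert g.total == expected == 500

    def test_unknown_rotor_is_fatal(self):
        with pytest.raises(RotormatError):
            rm.build_frequency_grid([], ("phi", "omega"))

    @given(st.lists(st.floats(-180, 180, exclude_min=True), max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_grid_and_basin_totals_conserve_input_length(self, angles):
        recs = [rm.RotorRecord("Q", "A", i, phi=a, psi=a) for i, a in enumerate(angles)]
        assert rm.build_frequency_grid(recs, ("phi", "psi")).total == len(angles)
        assert rm.basin_histogram(angles).total == len(angles)


class TestBasinHistogram:
    @pytest.mark.parametrize(
        "angle,basin",
        [
            (0.0, 2),      # [-50, +50)
            (180.0, 0),    # wrap cell belongs to basin 1
            (150.0, 0),
            (-150.0, 1),   # lower edge owned by the basin it opens
            (-50.0, 2),
            (50.0, 3),
            (149.999, 3),
            (-150.001, 0),
        ],
    )
    def test_boundary_ownership(self, angle, basin):
        assert basin_index(angle) == basin

    def test_out_of_range_angles_normalized_first(self):
        counts = rm.basin_histogram([360.0, 540.0, -360.0])  # -> 0, 180, 0
        assert counts.b == (1, 0, 2, 0)
        assert basin_index(540.0) == basin_index(180.0)


class TestBasinEnergies:
    def test_uniform_counts_zero_for_variants_2_and_3(self):
        counts = rm.BasinCounts((10, 10, 10, 10))
        params = rm.EnergyParams(pseudocount=0.0)
        assert rm.basin_energies(counts, "MIDMAT3", params) == pytest.approx([0.0] * 4, abs=0)
        assert rm.basin_energies(counts, "MIDMAT2", params) == pytest.approx([0.0] * 4, abs=0)

    def test_uniform_counts_closed_form_for_variant_1(self):
        counts = rm.BasinCounts((10, 10, 10, 10))
        e = rm.basin_energies(counts, "MIDMAT1", rm.EnergyParams(pseudocount=0.0))
        assert e == pytest.approx([RT_KJ * math.log(3)] * 4, rel=1e-12)

    def test_reference_equals_own_count_gives_zero(self):
        e = rm.basin_energies(
            rm.BasinCounts((30, 10, 10, 10)), "MIDMAT1", rm.EnergyParams(pseudocount=0.0)
        )
        assert e[0] == pytest.approx(0.0, abs=0)

    def test_documented_scalar_value_variant_2(self):
        e = rm.basin_energies(
            rm.BasinCounts((30, 10, 10, 10)), "MIDMAT2", rm.EnergyParams(pseudocount=0.0)
        )
        assert e[0] == pytest.approx(-RT_KJ * math.log(3.0), rel=1e-12)

    def test_all_zero_counts_with_zero_pseudocount_fatal(self):
        with pytest.raises(RotormatError, match="pseudocount"):
            rm.basin_energies(
                rm.BasinCounts((0, 0, 0, 0)), "MIDMAT1", rm.EnergyParams(pseudocount=0.0)
            )

    @pytest.mark.parametrize("variant", ["MIDMAT1", "MIDMAT2", "MIDMAT3"])
    def test_brute_force_oracle_on_random_counts(self, variant):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            counts = tuple(int(c) for c in rng.integers(1, 5000, size=4))
            ours = rm.basin_energies(
                rm.BasinCounts(counts), variant, rm.EnergyParams(pseudocount=0.0)
            )
            ref = brute_force_energies(counts, variant)
            np.testing.assert_allclose(ours, ref, rtol=1e-12)

    @pytest.mark.parametrize("variant", ["MIDMAT1", "MIDMAT2", "MIDMAT3"])
    def test_increasing_a_basins_count_decreases_its_energy(self, variant):
        params = rm.EnergyParams(pseudocount=0.0)
        lo = rm.basin_energies(rm.BasinCounts((20, 30, 40, 50)), variant, params)[0]
        hi = rm.basin_energies(rm.BasinCounts((25, 30, 40, 50)), variant, params)[0]
        assert hi < lo


class TestRotorEnergyProfile:
    def test_glycine_side_chain_rows_zero_and_flagged(self):
        recs = rm.sample_rotor_records("G", rm.BasinWeights.uniform(), 50, seed=1)
        profile = rm.rotor_energy_profile(recs, "G", "MIDMAT2")
        assert profile.missing_rotors == {"chi1", "chi2"}
        assert np.all(profile.rotor_row("chi1") == 0.0)
        assert np.all(profile.rotor_row("chi2") == 0.0)

    def test_concentrated_basin_has_minimal_energy(self):
        w = rm.BasinWeights(
            phi=(0.0, 1.0, 0.0, 0.0),
            psi=(0.25, 0.25, 0.25, 0.25),
            chi1=(0.25, 0.25, 0.25, 0.25),
            chi2=(0.25, 0.25, 0.25, 0.25),
        )
        recs = rm.sample_rotor_records("Q", w, 400, seed=3)
        profile = rm.rotor_energy_profile(recs, "Q", "MIDMAT3")
        phi_row = profile.rotor_row("phi")
        assert np.argmin(phi_row) == 1

    def test_counts_sufficiency(self):
        # two disjoint record sets with identical basin counts -> identical profiles
        base = [10.0, -120.0, 0.0, 100.0]
        recs_a = [rm.RotorRecord("Q", "A", i, phi=a, psi=a, chi1=a, chi2=a) for i, a in enumerate(base)]
        shifted = [15.0, -100.0, 20.0, 120.0]  # same basins, different angles
        recs_b = [rm.RotorRecord("Q", "A", i, phi=a, psi=a, chi1=a, chi2=a) for i, a in enumerate(shifted)]
        pa = rm.rotor_energy_profile(recs_a, "Q", "MIDMAT1")
        pb = rm.rotor_energy_profile(recs_b, "Q", "MIDMAT1")
        np.testing.assert_array_equal(pa.energies, pb.energies)

    def test_no_records_is_fatal(self):
        with pytest.raises(RotormatError):
            rm.rotor_energy_profile([], "Q", "MIDMAT1")


class TestProfileIO:
    def test_energy_profile_tsv_round_trip(self, tmp_path):
        recs = rm.sample_rotor_records("G", rm.BasinWeights.uniform(), 30, seed=5)
        profiles = {"G": rm.rotor_energy_profile(recs, "G", "MIDMAT2")}
        path = tmp_path / "energies.tsv"
        rm.basin_stats.write_energy_profiles(profiles, path)
        back = rm.basin_stats.read_energy_profiles(path)
        np.testing.assert_allclose(back["G"].energies, profiles["G"].energies)
        assert back["G"].missing_rotors == {"chi1", "chi2"}
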