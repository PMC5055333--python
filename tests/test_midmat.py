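"""Distance -> substitution-value -> diagonal -> rounding pipeline and matrix I/O."""

import numpy as np
import pytest

import rotormat as rm
from rotormat.errors import MatrixFormatError, RotormatError
from rotormat.midmat import pair_median

from conftest import profiles_from_count_table, random_basin_table


def uniform_profiles(variant="MIDMAT3"):
    return {
        aa: rm.BasinEnergyProfile(aa, variant, np.zeros((4, 4))) for aa in rm.AA_ORDER
    }


def profile_with(aa, variant, **cells):
    e = np.zeros((4, 4))
    for key, value in cells.items():
        rotor, basin = key.rsplit("_", 1)
        e[("phi", "psi", "chi1", "chi2").index(rotor), int(basin) - 1] = value
    return rm.BasinEnergyProfile(aa, variant, e)


class TestDistanceMatrix:
    def test_identical_profiles_have_zero_distance(self):
        D = rm.distance_matrix(uniform_profiles())
        assert np.all(D.values == 0.0)

    def test_single_component_difference(self):
        profiles = uniform_profiles()
        profiles["R"] = profile_with("R", "MIDMAT3", phi_1=3.0)
        D = rm.distance_matrix(profiles)
        assert D.values[0, 1] == pytest.approx(3.0)  # A vs R

    def test_three_four_five(self):
        profiles = uniform_profiles()
        profiles["R"] = profile_with("R", "MIDMAT3", phi_1=3.0, chi2_4=4.0)
        D = rm.distance_matrix(profiles)
        assert D.values[0, 1] == pytest.approx(5.0)

    def test_missing_amino_acid_fatal(self):
        profiles = uniform_profiles()
        del profiles["W"]
        with pytest.raises(RotormatError, match="W"):
            rm.distance_matrix(profiles)

    def test_mixed_variants_fatal(self):
        profiles = uniform_profiles()
        profiles["A"] = rm.BasinEnergyProfile("A", "MIDMAT1", np.zeros((4, 4)))
        with pytest.raises(RotormatError):
            rm.distance_matrix(profiles)


class TestSubstitutionValues:
    def toy_distances(self):
        # 3-amino-acid toy embedded in the 20x20 frame: distances
        # {AB: 2, AC: 6, BC: 4} after normalization by 1.0; remaining
        # pairs use values keeping the median at 4 is impossible with 20
        # residues, so the toy is checked through the algebra directly.
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 2.0
        values[0, 2] = values[2, 0] = 6.0
        values[1, 2] = values[2, 1] = 4.0
        return values

    def test_toy_median_centering(self):
        values = self.toy_distances()
        m = float(np.median(values[np.triu_indices(3, k=1)]))
        assert m == 4.0
        sv = 0.5 * (m - values)
        assert sv[0, 1] == pytest.approx(1.0)
        assert sv[0, 2] == pytest.approx(-1.0)
        assert sv[1, 2] == pytest.approx(0.0)

    def test_pair_at_median_scores_zero(self):
        rng = np.random.default_rng(5)
        table = random_basin_table(rng)
        profiles = profiles_from_count_table(table, "MIDMAT2")
        D = rm.distance_matrix(profiles)
        params = rm.MidmatParams(denominator=1000.0)
        sv = rm.substitution_values(D, params)
        m = pair_median(D.values / 1000.0)
        iu = np.triu_indices(20, k=1)
        closest = np.argmin(np.abs(D.values[iu] / 1000.0 - m))
        # an exact-median pair scores exactly zero (190 pairs -> even
        # count -> median is the mean of the two middle values, which
        # coincides with one of them only by luck; check the identity)
        assert sv[iu][closest] == pytest.approx(
            0.5 * (m - (D.values[iu] / 1000.0)[closest]), abs=0
        )

    def test_zero_distance_pair_scores_half_median(self):
        profiles = uniform_profiles()
        profiles["R"] = profile_with("R", "MIDMAT3", phi_1=500.0)
        D = rm.distance_matrix(profiles)
        sv = rm.substitution_values(D, rm.MidmatParams(denominator=1000.0))
        m = pair_median(D.values / 1000.0)
        iu = np.triu_indices(20, k=1)
        # every pair not involving R has distance 0 -> maximal score 0.5*m
        assert np.nanmax(sv) == pytest.approx(0.5 * m)
        assert sv[2, 3] == pytest.approx(0.5 * m)  # N vs D

    def test_monotone_decreasing_in_distance(self):
        rng = np.random.default_rng(17)
        profiles = profiles_from_count_table(random_basin_table(rng), "MIDMAT1")
        D = rm.distance_matrix(profiles)
        sv = rm.substitution_values(D, rm.MidmatParams())
        iu = np.triu_indices(20, k=1)
        order = np.argsort(D.values[iu])
        assert np.all(np.diff(sv[iu][order]) <= 1e-15)


class TestFillDiagonalAndRounding:
    def test_toy_diagonal(self):
        sv = np.full((3, 3), np.nan)
        sv[0, 1] = sv[1, 0] = 2.0
        sv[0, 2] = sv[2, 0] = -1.0
        sv[1, 2] = sv[2, 1] = 0.0
        full = rm.fill_diagonal(sv)
        assert full[0, 0] == 4.0 and full[1, 1] == 4.0 and full[2, 2] == 2.0

    def test_constant_off_diagonal_doubles(self):
        sv = np.full((4, 4), 1.5)
        np.fill_diagonal(sv, np.nan)
        full = rm.fill_diagonal(sv)
        assert np.all(np.diag(full) == 3.0)

    def test_diagonal_identity_on_random_input(self):
        rng = np.random.default_rng(3)
        sv = rng.normal(size=(20, 20))
        sv = (sv + sv.T) / 2
        np.fill_diagonal(sv, np.nan)
        full = rm.fill_diagonal(sv)
        off = sv.copy()
        gmax = np.nanmax(off)
        for i in range(20):
            assert full[i, i] == pytest.approx(gmax + np.nanmax(off[i]))

    @pytest.mark.parametrize(
        "value,expected", [(2.5, 3), (-2.5, -3), (1.49, 1), (-1.49, -1), (0.5, 1), (7.0, 7)]
    )
    def test_rounding_halves_away_from_zero(self, value, expected):
        m = rm.round_matrix(np.full((20, 20), value))
        assert m.scores[0, 0] == expected

    def test_rounding_idempotent_on_integers(self):
        rng = np.random.default_rng(1)
        ints = rng.integers(-9, 10, size=(20, 20)).astype(float)
        assert np.array_equal(rm.round_matrix(ints).scores, ints.astype(int))

    def test_non_finite_entries_fatal(self):
        with pytest.raises(RotormatError):
            rm.round_matrix(np.full((20, 20), np.nan))


class TestEndToEnd:
    @pytest.mark.parametrize("variant", ["MIDMAT1", "MIDMAT2", "MIDMAT3"])
    def test_matrices_symmetric_integer_20x20(self, variant):
        rng = np.random.default_rng({"MIDMAT1": 101, "MIDMAT2": 202, "MIDMAT3": 303}[variant])
        profiles = profiles_from_count_table(random_basin_table(rng), variant)
        m = rm.build_substitution_matrix(profiles, rm.MidmatParams())
        assert m.scores.shape == (20, 20)
        assert m.is_symmetric()
        assert np.issubdtype(m.scores.dtype, np.integer)

    def test_identical_profiles_give_uniform_matrix(self):
        m = rm.build_substitution_matrix(uniform_profiles())
        assert np.all(m.scores == 0)  # median 0, all distances 0


class TestBlastMatrixIO:
    def roundtrip(self, tmp_path, pad):
        rng = np.random.default_rng(8)
        scores = rng.integers(-10, 16, size=(20, 20))
        scores = np.triu(scores) + np.triu(scores, 1).T
        m = rm.SubstitutionMatrix(scores, rm.AA_ORDER)
        path = tmp_path / "m.mat"
        rm.write_blast_matrix(m, path, pad_blast=pad, comments=["test matrix"])
        return m, rm.read_blast_matrix(path)

    def test_round_trip(self, tmp_path):
        m, back = self.roundtrip(tmp_path, pad=False)
        assert back == m

    def test_padded_round_trip_strips_extended_codes(self, tmp_path):
        m, back = self.roundtrip(tmp_path, pad=True)
        assert back == m

    def test_padded_file_contains_extended_rows(self, tmp_path):
        m, _ = self.roundtrip(tmp_path, pad=True)
        path = tmp_path / "p.mat"
        rm.write_blast_matrix(m, path, pad_blast=True)
        full = rm.read_blast_matrix(path, strip_extended=False)
        assert full.order[-4:] == ("B", "Z", "X", "*")
        assert full.scores[-1, -1] == m.scores.min()

    def test_malformed_file_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.mat"
        path.write_text("# comment\n A R\nA 1\n")
        with pytest.raises(MatrixFormatError, match="line 3"):
            rm.read_blast_matrix(path)

    def test_ncbi_header_recognized_by_makeblastdb_style_layout(self, tmp_path):
        m = rm.SubstitutionMatrix(np.eye(20, dtype=int), rm.AA_ORDER)
        path = tmp_path / "eye.mat"
        rm.write_blast_matrix(m, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert lines[0].split() == list(rm.AA_ORDER)
        assert lines[1].split()[0] == "A"


class TestReferenceMatrices:
    @pytest.mark.parametrize("variant", ["MIDMAT1", "MIDMAT2", "MIDMAT3"])
    def test_parse_as_20x20_integer_tables(self, variant):
        m = rm.load_reference_matrix(variant)
        assert m.scores.shape == (20, 20)
        assert m.order == rm.AA_ORDER

    def test_printed_anchor_entries(self):
        m1 = rm.load_reference_matrix("MIDMAT1")
        assert m1.score("A", "A") == 9
        assert m1.score("P", "P") == 3
        m3 = rm.load_reference_matrix("MIDMAT3")
        assert m3.score("G", "G") == 5

    def test_reference_midmat3_is_symmetric(self):
        assert rm.load_reference_matrix("MIDMAT3").is_symmetric()

    def test_diagonal_dominates_rows_in_references(self):
        for variant in ("MIDMAT1", "MIDMAT2", "MIDMAT3"):
            m = rm.load_reference_matrix(variant)
            assert np.all(np.diag(m.scores) >= m.scores.max(axis=1))
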