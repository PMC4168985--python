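"""Profile data model, file dialect, blank imputation and Ts scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nescan.profiles import (
    AA_INDEX,
    AMINO_ACIDS,
    ActivityProfile,
    NesClass,
    ProfileParseError,
    compute_ts,
    fill_blanks,
    read_profile,
    write_profile,
)
from nescan.simulate import make_toy_profile


def toy(st_score=8.0, seed=0, nes_class=NesClass.CLASS_1C):
    return make_toy_profile(nes_class, st=st_score, seed=seed)


class TestProfileIO:
    def test_round_trip_preserves_matrix(self, tmp_path, profile_1c):
        path = tmp_path / "p.tsv"
        write_profile(profile_1c, path)
        again = read_profile(path)
        assert again.template == profile_1c.template
        assert again.st == profile_1c.st
        assert again.conserved_positions == profile_1c.conserved_positions
        np.testing.assert_array_equal(again.matrix, profile_1c.matrix)

    def test_round_trip_is_bit_stable(self, tmp_path):
        profile = toy(seed=5)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_profile(profile, p1)
        write_profile(read_profile(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_na_cells_round_trip_as_blanks(self, tmp_path):
        profile = toy()
        profile.matrix[2, AA_INDEX["W"]] = np.nan
        path = tmp_path / "p.tsv"
        write_profile(profile, path)
        again = read_profile(path)
        assert np.isnan(again.matrix[2, AA_INDEX["W"]])

    def test_published_1c_template_loads_with_standard_score_8(self, profile_1c):
        assert profile_1c.template == "SELAEKLQAGLDLN"
        assert profile_1c.st == 8.0

    def test_template_matrix_length_mismatch_is_parse_error(self, tmp_path, profile_1c):
        path = tmp_path / "p.tsv"
        write_profile(profile_1c, path)
        text = path.read_text().replace("#template SELAEKLQAGLDLN", "#template SELAEKLQAGLDL")
        path.write_text(text)
        with pytest.raises(ProfileParseError, match="columns"):
            read_profile(path)

    def test_non_numeric_cell_names_offending_row(self, tmp_path, profile_1c):
        path = tmp_path / "p.tsv"
        write_profile(profile_1c, path)
        lines = path.read_text().splitlines()
        lines[5] = lines[5].rsplit("\t", 1)[0] + "\tbogus"
        path.write_text("\n".join(lines))
        with pytest.raises(ProfileParseError, match="non-numeric"):
            read_profile(path)

    def test_template_identity_violation_downgrades_to_warning(self, tmp_path, profile_1c):
        legacy = profile_1c.copy()
        legacy.matrix[0, AA_INDEX[legacy.template[0]]] = legacy.st + 2
        path = tmp_path / "legacy.tsv"
        write_profile(legacy, path)
        with pytest.warns(UserWarning, match="disagree"):
            again = read_profile(path)
        # cells are left as read
        assert again.matrix[0, AA_INDEX[legacy.template[0]]] == legacy.st + 2


class TestFillBlanks:
    def test_similarity_partner_fills_first(self):
        profile = toy()
        profile.matrix[4, AA_INDEX["I"]] = np.nan
        filled = fill_blanks(profile)
        assert filled.matrix[4, AA_INDEX["I"]] == profile.matrix[4, AA_INDEX["L"]]
        assert filled.filled_mask[4, AA_INDEX["I"]]

    def test_donor_cell_used_when_no_group_partner(self):
        profile = toy()
        # cysteine has no similarity partner
        profile.matrix[4, AA_INDEX["C"]] = np.nan
        donor = toy(seed=9, nes_class=NesClass.CLASS_1B)
        filled = fill_blanks(profile, donors=[donor])
        # class 1b's first Phi is at 5, class 1c's at 3: donor position shifts by +2
        assert filled.matrix[4, AA_INDEX["C"]] == donor.matrix[6, AA_INDEX["C"]]

    def test_position_mean_is_last_resort(self):
        profile = toy()
        profile.matrix[4, AA_INDEX["C"]] = np.nan
        row = profile.matrix[4]
        expected = np.nanmean(row)
        filled = fill_blanks(profile)
        assert filled.matrix[4, AA_INDEX["C"]] == pytest.approx(expected)

    def test_fully_specified_profile_unchanged(self, profile_1c):
        filled = fill_blanks(profile_1c)
        np.testing.assert_array_equal(filled.matrix, profile_1c.matrix)
        assert not filled.filled_mask.any()

    def test_position_with_no_determined_scores_errors(self):
        profile = toy()
        profile.matrix[4, :] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fill_blanks(profile)


class TestComputeTs:
    def test_template_scores_standard_score(self, bundled_profiles):
        for profile in bundled_profiles:
            assert compute_ts(profile.template, profile) == pytest.approx(profile.st)

    def test_published_1c_template_scores_8(self, profile_1c):
        assert compute_ts("SELAEKLQAGLDLN", profile_1c) == pytest.approx(8.0)

    def test_single_substitution_adds_one_delta(self, profile_1c):
        window = list(profile_1c.template)
        window[5] = "W"
        expected = profile_1c.st + (profile_1c.score(6, "W") - profile_1c.st)
        assert compute_ts("".join(window), profile_1c) == pytest.approx(expected)

    def test_double_substitutions_sum_deltas_exactly(self):
        """Brute force over every 2-substitution pair of a 3-position profile."""
        matrix = np.arange(60, dtype=float).reshape(3, 20) / 10
        template = "LDL"
        for i, aa in enumerate(template):
            matrix[i, AA_INDEX[aa]] = 5.0
        profile = ActivityProfile(
            nes_class=NesClass.CLASS_2,
            template=template,
            st=5.0,
            matrix=matrix,
            conserved_positions=(1, 3),
        )
        for (i, j) in itertools.combinations(range(3), 2):
            for a, b in itertools.product(AMINO_ACIDS, repeat=2):
                window = list(template)
                window[i], window[j] = a, b
                expected = (
                    5.0
                    + (matrix[i, AA_INDEX[a]] - 5.0)
                    + (matrix[j, AA_INDEX[b]] - 5.0)
                )
                assert compute_ts("".join(window), profile) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 13), st.sampled_from(AMINO_ACIDS)), max_size=6))
    def test_additivity_for_any_substitution_set(self, subs):
        profile = toy(seed=3)
        window = list(profile.template)
        applied = {}
        for pos, aa in subs:
            window[pos] = aa
            applied[pos] = aa
        expected = profile.st + sum(
            profile.score(pos + 1, aa) - profile.st for pos, aa in applied.items()
        )
        assert compute_ts("".join(window), profile) == pytest.approx(expected)

    def test_truncation_consistency(self, profile_1c):
        """p=2 on w[2..L] equals p=1 on template[0]+w[2..L]."""
        window = list(profile_1c.template)
        window[7] = "K"
        tail = "".join(window[1:])
        assert compute_ts(tail, profile_1c, p=2) == pytest.approx(
            compute_ts(profile_1c.template[0] + tail, profile_1c, p=1)
        )

    def test_unknown_residue_contributes_zero_delta(self, profile_1c):
        window = "X" + profile_1c.template[1:]
        assert compute_ts(window, profile_1c) == pytest.approx(profile_1c.st)

    def test_window_length_mismatch_errors(self, profile_1c):
        with pytest.raises(ValueError, match="length"):
            compute_ts("SELAEK", profile_1c)
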