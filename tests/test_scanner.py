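"""Window scanning, the spacer-hydrophobicity penalty, and call merging."""

import dataclasses

import pytest

import nescan as ns
from nescan.profiles import NesClass
from nescan.scanner import (
    CLASS_ORDER,
    NesPrediction,
    ScanConfig,
    apply_penalty,
    merge_predictions,
    scan_protein,
    spacer_hydrophobicity,
)


def _cfg(**overrides):
    return dataclasses.replace(ScanConfig(), **overrides)


class TestSpacerHydrophobicity:
    def test_all_polar_spacers_rate_zero(self, profile_1c):
        window = list(profile_1c.template)
        for i in profile_1c.spacer_positions:
            window[i - 1] = "E"
        assert spacer_hydrophobicity("".join(window), profile_1c) == 0.0

    def test_all_leucine_spacers_rate_one(self, profile_1c):
        window = list(profile_1c.template)
        for i in profile_1c.spacer_positions:
            window[i - 1] = "L"
        assert spacer_hydrophobicity("".join(window), profile_1c) == 1.0

    def test_partial_rate_is_count_ratio(self, profile_1c):
        window = list(profile_1c.template)
        for i in profile_1c.spacer_positions:
            window[i - 1] = "E"
        for i in list(profile_1c.spacer_positions)[:4]:
            window[i - 1] = "V"
        n_spacers = len(profile_1c.spacer_positions)
        assert spacer_hydrophobicity("".join(window), profile_1c) == pytest.approx(
            4 / n_spacers
        )

    def test_profile_without_spacers_errors(self):
        profile = ns.make_toy_profile(NesClass.CLASS_1C)
        no_spacer = dataclasses.replace(
            profile, conserved_positions=tuple(range(1, profile.length + 1))
        )
        with pytest.raises(ValueError, match="spacer"):
            spacer_hydrophobicity(profile.template, no_spacer)


class TestApplyPenalty:
    def test_hydrophobic_spacers_drop_score_8_to_1(self):
        # the penalty magnitude mirrors a measured activity collapse from 8 to 1
        assert apply_penalty(8.0, 0.5) == pytest.approx(1.0)

    def test_below_threshold_rate_leaves_score(self):
        assert apply_penalty(8.0, 0.39) == pytest.approx(8.0)

    def test_boundary_rate_is_inclusive(self):
        assert apply_penalty(5.0, 0.4) == pytest.approx(-2.0)

    def test_configurable_penalty(self):
        cfg = _cfg(penalty_value=-3.0, penalty_rate_threshold=0.6)
        assert apply_penalty(4.0, 0.5, cfg) == pytest.approx(4.0)
        assert apply_penalty(4.0, 0.6, cfg) == pytest.approx(1.0)


class TestScanProtein:
    def test_planted_template_recovered_at_its_coordinates(self, bundled_profiles, profile_1c):
        # class 1c template at 40-53 between neutral flanks (multiplier 1.0)
        seq = "G" * 14 + "A" * 14 + "S" * 11 + profile_1c.template + "G" * 47
        rec = ns.SequenceRecord(id="planted", residues=seq)
        cfg = _cfg(enabled_classes=frozenset({NesClass.CLASS_1C}))
        preds = scan_protein(rec, bundled_profiles, cfg)
        assert len(preds) == 1
        (pred,) = preds
        assert (pred.start, pred.end) == (40, 53)
        assert pred.raw_score == pytest.approx(profile_1c.st)
        assert pred.multiplier == pytest.approx(1.0)

    def test_higher_threshold_predictions_are_subset(self, small_proteome, bundled_profiles):
        _, records, _, _ = small_proteome
        lo = _cfg(threshold=2.0, merge_overlaps=False)
        hi = _cfg(threshold=6.0, merge_overlaps=False)
        for rec in records:
            low = {(p.nes_class, p.start, p.end) for p in scan_protein(rec, bundled_profiles, lo)}
            high = {(p.nes_class, p.start, p.end) for p in scan_protein(rec, bundled_profiles, hi)}
            assert high <= low

    def test_every_admissible_start_scored_once_per_class(self, bundled_profiles):
        """Shift-1 completeness against direct enumeration of window starts."""
        rec = ns.SequenceRecord(id="t", residues="GASLVDE" * 10)
        cfg = _cfg(threshold=-1e9, merge_overlaps=False, apply_flank_adjustment=False)
        preds = scan_protein(rec, bundled_profiles, cfg)
        for profile in bundled_profiles:
            if profile.nes_class not in cfg.active_classes():
                continue
            L = profile.length
            spans = [(p.start, p.end) for p in preds if p.nes_class is profile.nes_class]
            full = [(s, s + L - 1) for s in range(1, len(rec) - L + 2)]
            truncated = [(1, L - p + 1) for p in range(2, 5)]
            assert sorted(spans) == sorted(full + truncated)
            assert len(spans) == len(set(spans)) + 0  # each start scored exactly once

    def test_no_window_extends_past_the_c_terminus(self, small_proteome, bundled_profiles):
        _, records, _, _ = small_proteome
        cfg = _cfg(threshold=-1e9, merge_overlaps=False)
        for rec in records[:3]:
            for p in scan_protein(rec, bundled_profiles, cfg):
                assert 1 <= p.start <= p.end <= len(rec)

    def test_penalty_stage_applied_exactly_once(self, small_proteome, bundled_profiles):
        _, records, _, _ = small_proteome
        cfg = _cfg(threshold=-1e9, merge_overlaps=False, apply_flank_adjustment=False)
        for rec in records[:3]:
            for p in scan_protein(rec, bundled_profiles, cfg):
                expected_penalty = -7.0 if p.spacer_hydrophobicity_rate >= 0.4 else 0.0
                assert p.penalty == expected_penalty
                assert p.adjusted_score == pytest.approx(p.raw_score + p.penalty)

    def test_truncated_n_terminal_windows_scored(self, bundled_profiles, profile_1c):
        # first 11 residues = template tail: the p=4 truncated window scores St
        seq = profile_1c.template[3:] + "G" * 60
        rec = ns.SequenceRecord(id="nterm", residues=seq)
        cfg = _cfg(
            threshold=-1e9,
            merge_overlaps=False,
            enabled_classes=frozenset({NesClass.CLASS_1C}),
            apply_flank_adjustment=False,
        )
        preds = scan_protein(rec, bundled_profiles, cfg)
        truncated = [p for p in preds if (p.start, p.end) == (1, 11)]
        assert len(truncated) == 1
        assert truncated[0].raw_score == pytest.approx(profile_1c.st)

    def test_short_sequence_yields_empty_with_warning(self, bundled_profiles, caplog):
        rec = ns.SequenceRecord(id="short", residues="MKL")
        with caplog.at_level("WARNING"):
            assert scan_protein(rec, bundled_profiles) == []
        assert any("short" in m for m in caplog.messages)

    def test_flank_adjustment_flag_controls_multiplier(self, small_proteome, bundled_profiles):
        _, _, pos, _ = small_proteome
        cfg = _cfg(apply_flank_adjustment=False)
        for rec in pos.sequences:
            for p in scan_protein(rec, bundled_profiles, cfg):
                assert p.multiplier == 1.0


def _pred(start, end, score, cls=NesClass.CLASS_1C, seq_id="s"):
    return NesPrediction(
        sequence_id=seq_id,
        nes_class=cls,
        start=start,
        end=end,
        window="A" * (end - start + 1),
        raw_score=score,
        penalty=0.0,
        spacer_hydrophobicity_rate=0.0,
        flank=None,
        multiplier=1.0,
        adjusted_score=score,
    )


class TestMerging:
    def test_overlapping_same_class_calls_keep_best(self):
        preds = [_pred(10, 23, 5.0), _pred(12, 25, 9.0), _pred(14, 27, 3.0)]
        merged = merge_predictions(preds)
        assert len(merged) == 1
        assert merged[0].adjusted_score == 9.0

    def test_merging_never_increases_count_nor_drops_class_max(self):
        preds = [
            _pred(1, 14, 4.0),
            _pred(5, 18, 7.0),
            _pred(40, 53, 2.5),
            _pred(41, 54, 2.0, cls=NesClass.CLASS_2),
        ]
        merged = merge_predictions(preds)
        assert len(merged) <= len(preds)
        for cls in {p.nes_class for p in preds}:
            best_in = max(p.adjusted_score for p in preds if p.nes_class is cls)
            best_out = max(p.adjusted_score for p in merged if p.nes_class is cls)
            assert best_out == best_in

    def test_cross_class_overlaps_are_both_reported(self):
        preds = [_pred(10, 23, 5.0), _pred(10, 23, 5.0, cls=NesClass.CLASS_2)]
        merged = merge_predictions(preds)
        assert {p.nes_class for p in merged} == {NesClass.CLASS_1C, NesClass.CLASS_2}

    def test_score_tie_broken_by_smaller_start(self):
        preds = [_pred(12, 25, 5.0), _pred(10, 23, 5.0)]
        merged = merge_predictions(preds)
        assert merged[0].start == 10

    def test_non_overlapping_calls_untouched(self):
        preds = [_pred(1, 14, 4.0), _pred(40, 53, 4.0)]
        assert len(merge_predictions(preds)) == 2
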