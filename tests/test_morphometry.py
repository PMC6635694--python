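"""Measurement tables, reference normalization and donor selection."""

import numpy as np
import pandas as pd
import pytest

from boneframe import frame as bframe
from boneframe import morphometry as morph
from boneframe.errors import InputError


@pytest.fixture(scope="module")
def reference_table():
    return morph.load_measurements(morph.reference_measurements_path())


@pytest.fixture(scope="module")
def reference_ratios(reference_table):
    return morph.ratio_table(reference_table, "H. naledi")


@pytest.fixture(scope="module")
def published_ratios():
    wide = pd.read_csv(morph.reference_ratio_path())
    return wide.melt(
        id_vars=["subject", "bone"], var_name="measure", value_name="expected"
    )


class TestRatioTable:
    def test_reproduces_published_ratios(self, reference_ratios, published_ratios):
        """Recomputing every normalized cell from the raw measurements
        matches the published ratio table to 4 decimals (165 cells)."""
        merged = reference_ratios.rounded().merge(
            published_ratios, on=["subject", "bone", "measure"]
        )
        assert len(merged) == 165
        assert (merged["ratio"] - merged["expected"]).abs().max() == 0.0

    def test_reference_row_is_unity(self, reference_ratios):
        assert reference_ratios.row("H. naledi") == pytest.approx(1.0)

    def test_spot_cells(self, reference_ratios):
        cells = reference_ratios.rounded().set_index(["subject", "bone", "measure"])
        assert cells.loc[("Basketball player 1", "metatarsal", "width"), "ratio"] == 1.0888
        assert cells.loc[("Runner", "metatarsal", "volume"), "ratio"] == 1.2833

    def test_scaling_a_subject_scales_its_ratios(self, reference_table):
        scaled = reference_table.copy()
        mask = scaled["subject"] == "Runner"
        scaled.loc[mask, list(morph.MEASURES)] *= 3.0
        table = morph.ratio_table(scaled, "H. naledi")
        base = morph.ratio_table(reference_table, "H. naledi")
        assert table.row("Runner") == pytest.approx(3.0 * base.row("Runner"))

    def test_missing_bone_reported(self, reference_table):
        broken = reference_table[
            ~(
                (reference_table["subject"] == "Jumper")
                & (reference_table["bone"] == "distal_phalanx")
            )
        ]
        with pytest.raises(InputError, match="Jumper/distal_phalanx"):
            morph.ratio_table(broken, "H. naledi")

    def test_unknown_reference(self, reference_table):
        with pytest.raises(InputError, match="reference"):
            morph.ratio_table(reference_table, "Nobody")


class TestDonorSelection:
    def test_mean_ratio_selects_runner(self, reference_ratios):
        """The middle-distance runner has the smallest mean ratio
        (1.0127) and is the reconstruction donor."""
        assert morph.select_donor(reference_ratios) == "Runner"
        assert morph.donor_score(reference_ratios, "Runner") == pytest.approx(
            1.0127, abs=5e-5
        )

    def test_runner_has_smallest_mean_ratio(self, reference_ratios):
        runner = morph.donor_score(reference_ratios, "Runner")
        for subj in reference_ratios.subjects():
            if subj not in ("Runner", "H. naledi"):
                assert morph.donor_score(reference_ratios, subj) > runner

    def test_abs_dev_score_orders_differently(self, reference_ratios):
        """Mean absolute deviation ranks basketball player 2 closest on
        this dataset — over- and under-sized bones cancel in the plain
        mean but not in the deviation — so the mean-ratio score is the
        canonical selector."""
        assert (
            morph.select_donor(reference_ratios, method="mean_abs_dev")
            == "Basketball player 2"
        )

    def test_all_ones_row_scores(self, reference_ratios):
        assert morph.donor_score(reference_ratios, "H. naledi") == 1.0
        assert morph.donor_score(reference_ratios, "H. naledi", "mean_abs_dev") == 0.0

    def test_single_subject(self, reference_table):
        two = reference_table[
            reference_table["subject"].isin(["H. naledi", "Jumper"])
        ]
        assert morph.select_donor(morph.ratio_table(two, "H. naledi")) == "Jumper"

    def test_tie_keeps_input_order(self, reference_table):
        dup = reference_table[
            reference_table["subject"].isin(["H. naledi", "Runner"])
        ].copy()
        clone = dup[dup["subject"] == "Runner"].copy()
        clone["subject"] = "Runner clone"
        table = morph.ratio_table(pd.concat([dup, clone]), "H. naledi")
        with pytest.warns(UserWarning, match="tie"):
            assert morph.select_donor(table) == "Runner"

    def test_unknown_subject_and_method(self, reference_ratios):
        with pytest.raises(InputError):
            morph.donor_score(reference_ratios, "Nobody")
        with pytest.raises(InputError):
            morph.donor_score(reference_ratios, "Runner", method="median")


class TestMeasureSubject:
    def test_records_from_synthetic_subject(self, default_subject):
        std = bframe.standardize_subject(
            default_subject.metatarsal,
            default_subject.proximal,
            default_subject.distal,
        )
        records = morph.measure_subject(std, subject="synthetic")
        assert len(records) == 3
        assert {r.bone for r in records} == set(morph.BONES)
        mt = next(r for r in records if r.bone == "metatarsal")
        assert mt.length == pytest.approx(100.0, abs=1e-6)
        frame_df = morph.records_to_frame(records)
        assert set(frame_df.columns) == {"subject", "bone", *morph.MEASURES}

    def test_standardized_measures_are_size_invariant(self, default_subject):
        """Doubling the subject pre-standardization leaves records unchanged."""
        std1 = bframe.standardize_subject(
            default_subject.metatarsal,
            default_subject.proximal,
            default_subject.distal,
        )
        std2 = bframe.standardize_subject(
            default_subject.metatarsal.apply_scale(2.0),
            default_subject.proximal.apply_scale(2.0),
            default_subject.distal.apply_scale(2.0),
        )
        r1 = morph.records_to_frame(morph.measure_subject(std1))
        r2 = morph.records_to_frame(morph.measure_subject(std2))
        for measure in morph.MEASURES:
            assert r2[measure].to_numpy() == pytest.approx(
                r1[measure].to_numpy(), rel=1e-6
            )
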