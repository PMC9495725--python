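import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtpfluor.data import default_em_grid, default_ex_grid, Spectrum2D
from mtpfluor.errors import AlignmentError, ConfigError, GridError
from mtpfluor.preprocess import (
    FeatureMatrix,
    PreprocessConfig,
    SpectrumBlocks,
    mask_emission_window,
    preprocess_spectrum,
    reference_to_initial,
    run_preprocess,
    smooth_emission,
    unfold_and_downsample,
)


def blocks_from(ex, em, values, well="w", t=0.1):
    return SpectrumBlocks(well, t, np.asarray(ex, float), [np.asarray(em, float)] * len(ex),
                          [np.asarray(v, float) for v in values])


class TestMask:
    def test_ex280_on_canonical_grid_keeps_605_points(self):
        # emission points 278 + 0.45k <= 550 enumerate to 605
        em = default_em_grid(0.45)
        b = blocks_from([280.0], em, [np.zeros(em.size)])
        out = mask_emission_window(b)
        assert out.em[0].size == 605
        assert out.em[0][0] == 278.0
        assert out.em[0][-1] <= 550.0 + 1e-9

    def test_window_bounds_inclusive(self):
        em = np.array([269.9, 270.0, 400.0, 550.0, 550.1])
        b = blocks_from([280.0], em, [np.arange(5.0)])
        out = mask_emission_window(b)
        # [ex-10, ex+270] = [270, 550], inclusive at both ends
        assert list(out.em[0]) == [270.0, 400.0, 550.0]

    def test_ex700_clipped_at_grid_end(self):
        em = default_em_grid(0.45)
        b = blocks_from([700.0], em, [np.zeros(em.size)])
        out = mask_emission_window(b)
        assert out.em[0][0] >= 690.0 - 1e-9
        assert out.em[0][-1] <= 720.0

    def test_empty_window_drops_row(self):
        em = np.array([300.0, 310.0])
        b = blocks_from([700.0, 280.0], em, [np.zeros(2), np.zeros(2)])
        out = mask_emission_window(b)
        assert list(out.ex) == [280.0]


class TestSmoothing:
    def test_constant_row_unchanged(self):
        b = blocks_from([300.0], np.arange(40.0), [np.full(40, 7.0)])
        out = smooth_emission(b, 25)
        assert np.allclose(out.values[0], 7.0)

    def test_impulse_response_is_box(self):
        row = np.zeros(101)
        row[50] = 1.0
        b = blocks_from([300.0], np.arange(101.0), [row])
        out = smooth_emission(b, 25)
        assert np.allclose(out.values[0][38:63], 1 / 25)
        assert np.allclose(out.values[0][:38], 0.0)
        assert out.values[0].size == 101

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=300)
        out = smooth_emission(blocks_from([300.0], np.arange(300.0), [row]), 25).values[0]
        half = 12
        expected = np.array(
            [row[max(0, i - half) : min(300, i + half + 1)].mean() for i in range(300)]
        )
        assert np.max(np.abs(out - expected)) < 1e-12

    def test_short_row_raises(self):
        b = blocks_from([300.0], np.arange(10.0), [np.zeros(10)])
        with pytest.raises(GridError, match="shorter than window"):
            smooth_emission(b, 25)

    def test_even_window_rejected(self):
        b = blocks_from([300.0], np.arange(30.0), [np.zeros(30)])
        with pytest.raises(ConfigError, match="odd"):
            smooth_emission(b, 24)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(2)
        reduced = 0
        for _ in range(120):
            row = rng.normal(size=200)
            out = smooth_emission(blocks_from([300.0], np.arange(200.0), [row]), 25).values[0]
            reduced += out.var() < row.var()
        assert reduced == 120


class TestUnfold:
    def test_block_of_11_stride_5_keeps_3(self):
        b = blocks_from([300.0], np.arange(11.0), [np.arange(11.0)])
        row, meta = unfold_and_downsample(b, 5)
        assert list(row) == [0.0, 5.0, 10.0]
        assert list(meta["em_nm"]) == [0.0, 5.0, 10.0]

    def test_605_points_give_121_features(self):
        em = default_em_grid(0.45)
        b = mask_emission_window(blocks_from([280.0], em, [np.zeros(em.size)]))
        row, meta = unfold_and_downsample(b, 5)
        assert row.size == 121  # ceil(605/5)

    def test_stride_1_is_identity(self):
        vals = np.arange(20.0)
        b = blocks_from([300.0], np.arange(20.0), [vals])
        row, _ = unfold_and_downsample(b, 1)
        assert np.array_equal(row, vals)

    def test_blocks_concatenated_in_ascending_excitation_order(self):
        b = blocks_from([280.0, 290.0], np.arange(6.0), [np.zeros(6), np.ones(6)])
        row, meta = unfold_and_downsample(b, 5)
        assert list(meta["ex_nm"]) == [280.0, 280.0, 290.0, 290.0]
        assert list(row) == [0.0, 0.0, 1.0, 1.0]


def small_fm(values, wells, cycles, times=None):
    values = np.asarray(values, float)
    times = times if times is not None else [0.1 + 0.5 * c for c in cycles]
    return FeatureMatrix(
        values=values,
        feature_meta=pd.DataFrame(
            {"ex_nm": np.arange(values.shape[1]), "em_nm": np.arange(values.shape[1]) + 10}
        ),
        row_meta=pd.DataFrame(
            {"well_id": wells, "condition_id": "A", "replicate": 1, "cycle": cycles,
             "time_h": times}
        ),
    )


class TestReferencing:
    def test_first_cycle_row_is_zero(self):
        fm = small_fm([[1.0, 2.0], [3.0, 5.0]], ["w", "w"], [0, 1])
        out = reference_to_initial(fm)
        assert np.array_equal(out.values[0], [0.0, 0.0])
        assert np.array_equal(out.values[1], [2.0, 3.0])

    def test_constant_well_all_zero(self):
        fm = small_fm([[4.0, 4.0]] * 3, ["w"] * 3, [0, 1, 2])
        assert np.all(reference_to_initial(fm).values == 0.0)

    def test_manual_subtraction_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(2, 5))
        fm = small_fm(vals, ["w", "w"], [0, 1])
        out = reference_to_initial(fm)
        assert np.array_equal(out.values[1], vals[1] - vals[0])

    def test_missing_first_cycle_raises(self):
        fm = small_fm([[1.0, 2.0], [1.0, 2.0], [3.0, 5.0]], ["a", "b", "b"], [0, 1, 2])
        with pytest.raises(AlignmentError, match="first measurement cycle"):
            reference_to_initial(fm)

    @given(offset=st.floats(-1e3, 1e3, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_per_well_additive_offset(self, offset):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(3, 4))
        fm = small_fm(vals, ["w"] * 3, [0, 1, 2])
        shifted = small_fm(vals + offset, ["w"] * 3, [0, 1, 2])
        assert np.allclose(
            reference_to_initial(fm).values, reference_to_initial(shifted).values, atol=1e-9
        )


class TestComposition:
    def test_blank_constant_dataset_gives_zero_matrix(self, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        fm = run_preprocess(ds)
        # every first-cycle row is exactly zero by the referencing contract
        first = fm.row_meta["cycle"] == fm.row_meta["cycle"].min()
        assert np.all(fm.values[first.to_numpy()] == 0.0)

    def test_degenerate_settings_equal_raw_difference(self):
        ex = default_ex_grid()[:3]
        em = default_em_grid(10.0)[:5]
        rng = np.random.default_rng(5)
        from mtpfluor.data import MeasurementSchedule, SpectraDataset, WellCondition

        ds = SpectraDataset({"w": WellCondition("A", 9.0, 0.07)}, MeasurementSchedule())
        raw = [rng.uniform(0, 10, (3, 5)) for _ in range(2)]
        for c, inten in enumerate(raw):
            ds.add(Spectrum2D("w", 0.1 + 0.5 * c, ex, em, inten), c)
        cfg = PreprocessConfig(window=1, stride=1, apply_mask=False)
        fm = run_preprocess(ds, cfg)
        assert np.allclose(fm.values[1], (raw[1] - raw[0]).ravel())

    def test_pipeline_matches_scripted_step_oracle(self, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        cfg = PreprocessConfig()
        fm = run_preprocess(ds, cfg)
        # scripted oracle: apply the four steps by hand for one spectrum
        well = ds.wells()[0]
        cycles = ds.cycles(well)
        rows = {}
        for c in (cycles[0], cycles[2]):
            spec = ds.spectra[(well, c)]
            row, _ = preprocess_spectrum(spec, cfg)
            rows[c] = row
        expected = rows[cycles[2]] - rows[cycles[0]]
        got = fm.values[
            (
                (fm.row_meta["well_id"] == well) & (fm.row_meta["cycle"] == cycles[2])
            ).to_numpy()
        ][0]
        assert np.allclose(got, expected, atol=1e-12)

    def test_column_count_stable_and_rows_permute_with_wells(self, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        fm = run_preprocess(ds)
        n_rows = sum(len(ds.cycles(w)) for w in ds.wells())
        assert fm.values.shape == (n_rows, fm.n_features)
        assert (fm.feature_meta["em_nm"] >= fm.feature_meta["ex_nm"] - 10 - 1e-9).all()
        assert (fm.feature_meta["em_nm"] <= fm.feature_meta["ex_nm"] + 270 + 1e-9).all()

    def test_csv_round_trip(self, tmp_path, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        fm = run_preprocess(ds)
        path = tmp_path / "features.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert np.allclose(back.values, fm.values)
        assert np.allclose(back.feature_meta["ex_nm"], fm.feature_meta["ex_nm"])
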