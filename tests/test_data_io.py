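import json

import numpy as np
import pandas as pd
import pytest

from mtpfluor.data import (
    MeasurementSchedule,
    SpectraDataset,
    Spectrum2D,
    WellCondition,
    default_em_grid,
    default_ex_grid,
    extract_signal,
    mean_over_replicates,
    mean_spectra_over_replicates,
    read_spectra,
    validate_offline_table,
    write_spectra,
)
from mtpfluor.errors import AlignmentError, FormatError, GridError


def make_dataset(n_wells=2, n_cycles=3, seed=0):
    rng = np.random.default_rng(seed)
    ex = default_ex_grid()[:5]
    em = default_em_grid(10.0)[:7]
    conds = {
        f"W{i}": WellCondition("A", 9.0, 0.07, replicate_index=i + 1) for i in range(n_wells)
    }
    ds = SpectraDataset(conds, MeasurementSchedule())
    for i in range(n_wells):
        for c in range(n_cycles):
            ds.add(
                Spectrum2D(
                    f"W{i}", 0.1 + 0.5 * c, ex, em,
                    rng.uniform(0, 100, (ex.size, em.size)),
                    meta={"integration_time_ms": 30, "cycle": c},
                ),
                c,
            )
    return ds


class TestGrids:
    def test_default_ex_grid(self):
        ex = default_ex_grid()
        assert ex.size == 43 and ex[0] == 280.0 and ex[-1] == 700.0

    def test_canonical_em_grid(self):
        em = default_em_grid(0.45)
        assert em.size == 983 and em[0] == 278.0 and em[-1] <= 720.0


@pytest.mark.parametrize("suffix", [".csv", ".h5"])
class TestRoundTrip:
    def test_round_trip_identity(self, tmp_path, suffix):
        ds = make_dataset()
        path = tmp_path / f"spectra{suffix}"
        write_spectra(ds, path)
        back = read_spectra(path)
        assert back.wells() == ds.wells()
        assert back.schedule == ds.schedule
        assert back.conditions == ds.conditions
        tol = 0.0 if suffix == ".h5" else 1e-6
        for key, spec in ds.spectra.items():
            other = back.spectra[key]
            assert np.array_equal(other.ex_grid, spec.ex_grid)
            assert np.max(np.abs(other.intensities - spec.intensities)) <= tol
            assert other.meta == spec.meta
            assert other.time_h == pytest.approx(spec.time_h)

    def test_empty_dataset_round_trip(self, tmp_path, suffix):
        ds = SpectraDataset()
        path = tmp_path / f"empty{suffix}"
        write_spectra(ds, path)
        back = read_spectra(path)
        assert len(back) == 0


class TestFormatErrors:
    def test_nan_cell_fails_with_record_error(self, tmp_path):
        ds = make_dataset(n_wells=1, n_cycles=1)
        path = tmp_path / "spectra.csv"
        write_spectra(ds, path)
        frame = pd.read_csv(path)
        frame.loc[3, "intensity"] = np.nan
        frame.to_csv(path, index=False)
        with pytest.raises(FormatError, match="W0"):
            read_spectra(path)

    def test_missing_sidecar(self, tmp_path):
        path = tmp_path / "spectra.csv"
        path.write_text("well_id,cycle\n")
        with pytest.raises(FormatError, match="sidecar"):
            read_spectra(path)

    def test_malformed_header(self, tmp_path):
        ds = make_dataset(n_wells=1, n_cycles=1)
        path = tmp_path / "spectra.csv"
        write_spectra(ds, path)
        pd.read_csv(path).drop(columns=["em_nm"]).to_csv(path, index=False)
        with pytest.raises(FormatError, match="header"):
            read_spectra(path)

    def test_unregistered_well_rejected(self):
        ds = SpectraDataset()
        spec = Spectrum2D("W9", 0.1, np.array([280.0, 290.0]), np.array([300.0, 310.0]),
                          np.zeros((2, 2)))
        with pytest.raises(FormatError, match="W9"):
            ds.add(spec, 0)

    def test_offline_table_invariants(self):
        good = pd.DataFrame(
            {"condition_id": ["A"], "replicate": [1], "time_h": [0.0],
             "glycerol_g_L": [9.0], "cdw_g_L": [0.07], "pH": [6.0]}
        )
        validate_offline_table(good)
        bad = good.assign(pH=[9.5])
        with pytest.raises(FormatError, match="pH"):
            validate_offline_table(bad)


class TestExtractSignal:
    def test_constant_blank_series(self, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        sig = extract_signal(ds, 600.0, 600.0)
        assert set(sig.frame.columns) >= {"well_id", "time_h", "intensity"}

    def test_snap_to_nearest_grid_point(self):
        ds = make_dataset()
        sig = extract_signal(ds, 305.0, 300.0)
        assert sig.ex_nm in (300.0, 310.0)
        assert sig.snapped

    def test_out_of_span_raises(self):
        ds = make_dataset()
        with pytest.raises(GridError, match="outside grid span"):
            extract_signal(ds, 900.0, 300.0)

    def test_diagonal_equals_matrix_entry(self):
        ds = make_dataset(n_wells=1, n_cycles=1)
        spec = ds.spectra[("W0", 0)]
        lam = 300.0
        sig = extract_signal(ds, lam, lam)
        i = np.argmin(np.abs(spec.ex_grid - lam))
        j = np.argmin(np.abs(spec.em_grid - lam))
        assert sig.frame["intensity"].iloc[0] == spec.intensities[i, j]

    def test_gfp_signal_non_decreasing_until_depletion(self, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        sig = extract_signal(ds, 420.0, 530.0)
        for _, g in sig.frame.groupby("well_id"):
            assert np.all(np.diff(g.sort_values("time_h")["intensity"]) >= -1e-9)


class TestReplicateStats:
    def test_identical_replicates(self):
        frame = pd.DataFrame(
            {"condition_id": "A", "well_id": ["w1", "w2"], "cycle": [0, 0],
             "time_h": [0.1, 0.1], "intensity": [5.0, 5.0]}
        )
        out = mean_over_replicates(frame)
        assert out["mean"].iloc[0] == 5.0 and out["sd"].iloc[0] == 0.0

    def test_two_values_sample_sd(self):
        frame = pd.DataFrame(
            {"condition_id": "A", "well_id": ["w1", "w2"], "cycle": [0, 0],
             "time_h": [0.1, 0.1], "intensity": [1.0, 3.0]}
        )
        out = mean_over_replicates(frame)
        assert out["mean"].iloc[0] == 2.0
        assert out["sd"].iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_single_replicate_sd_zero(self):
        frame = pd.DataFrame(
            {"condition_id": "A", "well_id": ["w1"], "cycle": [0],
             "time_h": [0.1], "intensity": [4.0]}
        )
        assert mean_over_replicates(frame)["sd"].iloc[0] == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        rows = []
        for w in range(6):
            for c in range(4):
                rows.append(("A", f"w{w}", c, 0.1 + 0.5 * c, rng.normal()))
        frame = pd.DataFrame(rows, columns=["condition_id", "well_id", "cycle", "time_h", "intensity"])
        out = mean_over_replicates(frame)
        for c in range(4):
            vals = frame[frame.cycle == c]["intensity"].to_numpy()
            row = out[out.cycle == c]
            assert row["mean"].iloc[0] == pytest.approx(vals.mean(), rel=1e-12)
            assert row["sd"].iloc[0] == pytest.approx(vals.std(ddof=1), rel=1e-12)

    def test_mismatched_cycles_raise(self):
        frame = pd.DataFrame(
            {"condition_id": "A", "well_id": ["w1", "w1", "w2"], "cycle": [0, 1, 0],
             "time_h": [0.1, 0.6, 0.1], "intensity": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(AlignmentError, match="mismatched"):
            mean_over_replicates(frame)


class TestSpectraAveraging:
    def test_average_of_identical_replicates_is_identity(self, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        avg = mean_spectra_over_replicates(ds, min_replicates=2)
        some_well = [w for w in ds.wells() if ds.conditions[w].condition_id == "II"][0]
        for c in ds.cycles(some_well):
            assert np.allclose(
                avg.spectra[(f"avg:II", c)].intensities, ds.spectra[(some_well, c)].intensities
            )

    def test_too_few_replicates(self, tiny_experiment):
        ds, _, _, _ = tiny_experiment
        with pytest.raises(AlignmentError, match="replicate"):
            mean_spectra_over_replicates(ds, min_replicates=3)

    def test_average_equals_numpy_mean(self):
        ds = make_dataset(n_wells=3, n_cycles=2)
        avg = mean_spectra_over_replicates(ds, min_replicates=3)
        stack = np.stack([ds.spectra[(f"W{i}", 1)].intensities for i in range(3)])
        assert np.array_equal(avg.spectra[("avg:A", 1)].intensities, stack.mean(axis=0))
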