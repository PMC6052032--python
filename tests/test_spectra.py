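"""Spectrum I/O, dark correction, resampling and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import florisight as fl
from florisight.exceptions import CoverageError, DataError, FormatError, GridMismatchError

from conftest import make_spectrum


# ---------------------------------------------------------------------------
# reading


def test_wide_csv_parses_one_spectrum_per_column(tmp_path):
    wl = 400 + np.arange(301)
    df = pd.DataFrame({"wavelength": wl, "s1": 0.2 + 0 * wl, "s2": 0.4 + 0 * wl})
    path = tmp_path / "wide.csv"
    df.to_csv(path, index=False)
    out = fl.read_spectra(path, {"format": "wide"})
    assert len(out) == 2
    assert out[0].meta["replicate_id"] == "s1"
    assert np.allclose(out[1].values, 0.4)


def test_wide_csv_with_metadata_sidecar(tmp_path):
    wl = 400 + np.arange(301)
    pd.DataFrame({"wavelength": wl, "a": 0.1 + 0 * wl}).to_csv(
        tmp_path / "w.csv", index=False
    )
    pd.DataFrame(
        [{"sample": "a", "species": "X", "part": "petal", "kind": "flower",
          "surface": "n/a", "replicate": "r1"}]
    ).to_csv(tmp_path / "meta.csv", index=False)
    out = fl.read_spectra(
        tmp_path / "w.csv", {"format": "wide", "metadata": tmp_path / "meta.csv"}
    )
    assert out[0].meta["species"] == "X"
    assert out[0].meta["item_kind"] == "flower"


def test_long_csv_populates_metadata_from_columns(tmp_path):
    wl = 400 + np.arange(301)
    rows = []
    for sp, rep in [("A", "r1"), ("A", "r2"), ("B", "r1")]:
        rows.append(
            pd.DataFrame(
                {"wavelength": wl, "value": 0.3, "species": sp, "part": "petal",
                 "kind": "flower", "surface": "n/a", "replicate": rep}
            )
        )
    pd.concat(rows).to_csv(tmp_path / "long.csv", index=False)
    out = fl.read_spectra(tmp_path / "long.csv")
    assert len(out) == 3
    assert {s.meta["species"] for s in out} == {"A", "B"}
    assert all(s.meta["part_label"] == "petal" for s in out)


def test_descending_wavelengths_is_a_data_error(tmp_path):
    wl = np.arange(700, 399, -1)
    pd.DataFrame({"wavelength": wl, "s1": 0.2}).to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(DataError, match="row"):
        fl.read_spectra(tmp_path / "bad.csv", {"format": "wide"})


def test_missing_wavelength_column_is_a_format_error(tmp_path):
    pd.DataFrame({"nm": [400, 500], "v": [0.1, 0.2]}).to_csv(
        tmp_path / "f.csv", index=False
    )
    with pytest.raises(FormatError, match="wavelength"):
        fl.read_spectra(tmp_path / "f.csv", {"format": "wide"})


def test_rows_outside_window_are_retained_and_flagged(tmp_path):
    wl = 380 + np.arange(341)  # 380-720 nm
    pd.DataFrame({"wavelength": wl, "s1": 0.2}).to_csv(tmp_path / "w.csv", index=False)
    out = fl.read_spectra(tmp_path / "w.csv", {"format": "wide"})
    assert out[0].meta["n_outside_window"] == 40
    assert out[0].wavelengths.size == 341


def test_write_read_round_trip(tmp_path, grid):
    s1 = make_spectrum(grid, np.linspace(0.1, 0.5, grid.size), species="A")
    s2 = make_spectrum(grid, np.linspace(0.5, 0.1, grid.size), species="B",
                       item_kind="leaf", surface="upper")
    fl.write_spectra(fl.SpectrumSet([s1, s2]), tmp_path / "out.csv")
    back = fl.read_spectra(tmp_path / "out.csv")
    assert len(back) == 2
    leaf = [s for s in back if s.meta["item_kind"] == "leaf"][0]
    assert np.allclose(leaf.values, s2.values)
    assert leaf.meta["surface"] == "upper"


# ---------------------------------------------------------------------------
# dark correction


@pytest.mark.parametrize(
    "values, expected",
    [
        (np.full(301, 0.30), np.zeros(301)),  # constant collapses to zero
        (None, None),  # three-point case below
    ],
)
def test_dark_correct_subtracts_window_minimum(grid, values, expected):
    if values is None:
        s = make_spectrum([400.0, 550.0, 700.0], [0.05, 0.10, 0.25])
        out = fl.dark_correct(s)
        assert np.allclose(out.values, [0.0, 0.05, 0.20])
    else:
        out = fl.dark_correct(make_spectrum(grid, values))
        assert np.allclose(out.values, expected)
    assert out.values.min() == 0.0


def test_dark_correct_requires_window_coverage():
    s = make_spectrum(np.linspace(420, 700, 50), np.linspace(0.1, 0.2, 50))
    with pytest.raises(CoverageError):
        fl.dark_correct(s)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 10.0), min_size=5, max_size=40))
def test_dark_correct_idempotent_and_zero_minimum(vals):
    wl = np.linspace(350, 750, len(vals))
    s = make_spectrum(wl, vals)
    once = fl.dark_correct(s)
    twice = fl.dark_correct(once)
    assert np.min(once.values[once.window_mask()]) == pytest.approx(0.0, abs=1e-15)
    assert np.allclose(once.values, twice.values)


# ---------------------------------------------------------------------------
# resampling


def test_resample_is_exact_on_a_linear_ramp():
    wl = np.arange(395.0, 706.0, 5.0)
    s = make_spectrum(wl, 0.001 * wl)
    out = fl.resample(s, step=1.0)
    assert out.wavelengths[0] == 400.0 and out.wavelengths[-1] == 700.0
    assert out.wavelengths.size == 301
    assert np.allclose(out.values, 0.001 * out.wavelengths)


def test_resample_native_grid_is_identity(grid):
    s = make_spectrum(grid, np.random.default_rng(0).uniform(0, 1, grid.size))
    out = fl.resample(s, step=1.0)
    assert np.allclose(out.values, s.values)


def test_resample_matches_independent_piecewise_linear_evaluation():
    rng = np.random.default_rng(1)
    wl = 395.0 + np.cumsum(np.full(820, 0.38))  # instrument-like 0.38 nm grid
    vals = rng.uniform(0.0, 1.0, wl.size)
    s = make_spectrum(wl, vals)
    out = fl.resample(s, step=1.0)

    def interp_one(x):  # independent piecewise-linear oracle
        j = np.searchsorted(wl, x) - 1
        j = min(max(j, 0), wl.size - 2)
        t = (x - wl[j]) / (wl[j + 1] - wl[j])
        return (1 - t) * vals[j] + t * vals[j + 1]

    oracle = np.array([interp_one(x) for x in out.wavelengths])
    assert np.allclose(out.values, oracle, atol=1e-12)


def test_resample_refuses_extrapolation():
    s = make_spectrum(np.linspace(420, 700, 100), np.linspace(0, 1, 100))
    with pytest.raises(CoverageError):
        fl.resample(s, step=1.0)


# ---------------------------------------------------------------------------
# aggregation


def test_average_replicates_means_and_counts(grid):
    reps = [make_spectrum(grid, np.full(grid.size, v), replicate_id=f"r{i}")
            for i, v in enumerate([0.2, 0.4])]
    idem = [make_spectrum(grid, np.full(grid.size, 0.7), species="C",
                          replicate_id=f"r{i}") for i in range(5)]
    out = fl.average_replicates(fl.SpectrumSet(reps + idem))
    assert len(out) == 2
    mixed = [s for s in out if s.meta["species"] == "sp"][0]
    same = [s for s in out if s.meta["species"] == "C"][0]
    assert np.allclose(mixed.values, 0.3)
    assert mixed.meta["n_replicates"] == 2
    assert np.allclose(same.values, 0.7)
    assert same.meta["n_replicates"] == 5


def test_average_replicates_rejects_mixed_grids(grid):
    a = make_spectrum(grid, np.full(grid.size, 0.1))
    b = make_spectrum(grid[:-1], np.full(grid.size - 1, 0.1))
    with pytest.raises(GridMismatchError):
        fl.average_replicates(fl.SpectrumSet([a, b]))


def test_mean_background_identity_and_mean(grid):
    leaf = make_spectrum(grid, np.full(grid.size, 0.1), item_kind="leaf")
    assert np.allclose(fl.mean_background(fl.SpectrumSet([leaf])).values, leaf.values)
    leaf2 = make_spectrum(grid, np.full(grid.size, 0.3), item_kind="leaf")
    bg = fl.mean_background(fl.SpectrumSet([leaf, leaf2]))
    assert np.allclose(bg.values, 0.2)
    assert bg.meta["n_replicates"] == 2


def test_mean_background_matches_brute_force_column_mean():
    ss = fl.generate_spectra(
        fl.SpectraScenario(n_leaf_species=28, replicates=1,
                           parts_per_class={"red_edge": 1}), seed=4
    )
    leaves = ss.select(item_kind="leaf")
    assert len(leaves) == 56
    bg = fl.mean_background(leaves)
    brute = np.zeros_like(bg.values)
    for s in leaves:
        brute += s.values
    brute /= len(leaves)
    assert np.allclose(bg.values, brute, atol=1e-14)


def test_mean_background_commutes_with_uniform_scaling(grid):
    rng = np.random.default_rng(2)
    leaves = [make_spectrum(grid, rng.uniform(0, 1, grid.size), item_kind="leaf",
                            replicate_id=f"r{i}") for i in range(5)]
    bg = fl.mean_background(fl.SpectrumSet(leaves))
    scaled = fl.SpectrumSet([s.copy_with(values=3.7 * s.values) for s in leaves])
    bg_scaled = fl.mean_background(scaled)
    assert np.allclose(bg_scaled.values, 3.7 * bg.values)


def test_mean_background_rejects_empty_and_non_leaf(grid):
    with pytest.raises(DataError):
        fl.mean_background(fl.SpectrumSet([]))
    flower = make_spectrum(grid, np.full(grid.size, 0.2), item_kind="flower")
    with pytest.raises(DataError):
        fl.mean_background(fl.SpectrumSet([flower]))


def test_clip_nonnegative_counts_clipped_points(grid):
    vals = np.full(grid.size, 0.2)
    vals[:10] = -0.01
    out = fl.clip_nonnegative(make_spectrum(grid, vals))
    assert out.values.min() == 0.0
    assert out.meta["n_clipped"] == 10
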