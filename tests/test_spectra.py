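"""Spectral containers, CSV round-trips and preprocessing operations."""

import numpy as np
import pytest

from spechvol import (FormatError, InvalidArgumentError, SpectralCollection,
                      Spectrum, aggregate_mean, read_spectra, resample_1nm,
                      splice_correct, trim, write_spectra)
from spechvol.simulate import archetype_curve, make_species_pool


def linear_spectrum(lo=400.0, hi=2400.0, slope=1e-4, base=0.2, meta=None):
    wl = np.arange(lo, hi + 1)
    return Spectrum(wl, base + slope * (wl - lo), meta or {})


class TestSpectrum:
    def test_rejects_mismatched_lengths(self):
        with pytest.raises(InvalidArgumentError):
            Spectrum([400, 401, 402], [0.1, 0.2])

    def test_rejects_non_monotone_wavelengths(self):
        with pytest.raises(InvalidArgumentError):
            Spectrum([500, 499, 501], [0.1, 0.2, 0.3])

    def test_rejects_non_finite_reflectance(self):
        with pytest.raises(InvalidArgumentError):
            Spectrum([400, 401], [0.1, np.nan])


class TestCsvIO:
    @pytest.fixture()
    def collection(self):
        wl = np.arange(400.0, 410.0)
        specs = []
        for i in range(4):
            meta = {"experiment": "FAB", "plot_id": f"p{i % 2}",
                    "species_id": f"sp{i}", "individual_id": f"i{i}",
                    "layer": "top"}
            specs.append(Spectrum(wl, 0.1 + 0.01 * i + 0.001 * (wl - 400), meta))
        return SpectralCollection(specs)

    @pytest.mark.parametrize("dialect", ["wide", "long"])
    def test_round_trip_bit_identical(self, tmp_path, collection, dialect):
        path = tmp_path / f"{dialect}.csv"
        write_spectra(collection, path, dialect=dialect)
        back = read_spectra(path, dialect=dialect)
        assert len(back) == len(collection)
        for a, b in zip(collection, back):
            assert np.array_equal(a.wavelengths, b.wavelengths)
            assert np.array_equal(a.reflectance, b.reflectance)
            assert a.meta["plot_id"] == b.meta["plot_id"]

    def test_wide_and_long_dialects_agree(self, tmp_path, collection):
        write_spectra(collection, tmp_path / "w.csv", dialect="wide")
        write_spectra(collection, tmp_path / "l.csv", dialect="long")
        wide = read_spectra(tmp_path / "w.csv", dialect="wide")
        long = read_spectra(tmp_path / "l.csv", dialect="long")
        for a, b in zip(wide, long):
            assert np.array_equal(a.reflectance, b.reflectance)
            assert a.meta == b.meta

    def test_decreasing_wavelength_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plot_id,species_id,500,499\np1,sp1,0.1,0.2\n")
        with pytest.raises(FormatError):
            read_spectra(path, dialect="wide")

    def test_out_of_range_reflectance_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plot_id,species_id,500,501\np1,sp1,0.1,2.5\n")
        with pytest.raises(FormatError, match="row 0"):
            read_spectra(path, dialect="wide")


class TestSpliceCorrect:
    def test_pure_step_removed(self):
        wl = np.arange(900.0, 1101.0)
        rf = np.where(wl < 1000, 0.40, 0.45)
        out = splice_correct(Spectrum(wl, rf), junctions=[1000])
        assert np.allclose(out.reflectance, 0.40, atol=1e-14)

    def test_continuous_linear_spectrum_unchanged(self):
        s = linear_spectrum()
        out = splice_correct(s, junctions=[1000, 1900])
        assert np.max(np.abs(out.reflectance - s.reflectance)) < 1e-12

    def test_two_junction_steps_recover_truth(self):
        truth = linear_spectrum()
        rf = truth.reflectance.copy()
        wl = truth.wavelengths
        rf[wl >= 1000] += 0.05
        rf[wl >= 1900] -= 0.03
        out = splice_correct(Spectrum(wl, rf), junctions=[1000, 1900])
        assert np.max(np.abs(out.reflectance - truth.reflectance)) < 1e-12

    def test_idempotent_on_curved_spectrum(self):
        arch = make_species_pool(3, seed=5)[0]
        s = Spectrum(np.arange(400.0, 2401.0), archetype_curve(arch))
        once = splice_correct(s, junctions=[1000, 1900])
        twice = splice_correct(once, junctions=[1000, 1900])
        assert np.array_equal(once.reflectance, twice.reflectance)

    def test_junction_outside_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            splice_correct(linear_spectrum(), junctions=[3000])


class TestTrim:
    def test_instrument_range_trimmed_to_window(self):
        wl = np.arange(340.0, 2523.0)
        s = Spectrum(wl, np.full(wl.size, 0.3))
        out = trim(s, 400, 2400)
        assert out.wavelengths[0] == 400 and out.wavelengths[-1] == 2400

    def test_window_wider_than_grid_is_identity(self):
        s = linear_spectrum()
        out = trim(s, 100, 5000)
        assert np.array_equal(out.reflectance, s.reflectance)

    def test_disjoint_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            trim(linear_spectrum(), 3000, 4000)


class TestResample1nm:
    def test_linear_midpoint(self):
        s = Spectrum([400.0, 402.0], [0.1, 0.3])
        out = resample_1nm(s)
        assert out.reflectance[1] == pytest.approx(0.2, abs=1e-15)

    def test_integer_grid_is_identity(self):
        s = linear_spectrum()
        out = resample_1nm(s)
        assert np.array_equal(out.wavelengths, s.wavelengths)
        assert np.array_equal(out.reflectance, s.reflectance)

    def test_svc_like_grid_resamples_to_expected_span(self):
        # 1024 non-uniform bands over 340.5-2522.8 nm -> 341..2522, 2182 bands
        wl = np.sort(np.concatenate([
            [340.5, 2522.8],
            np.random.default_rng(0).uniform(341, 2522, 1022)]))
        out = resample_1nm(Spectrum(wl, np.linspace(0.1, 0.5, 1024)))
        assert out.wavelengths[0] == 341 and out.wavelengths[-1] == 2522
        assert len(out) == 2182

    def test_preserves_values_at_original_integer_nodes(self):
        wl = np.array([400.0, 400.6, 401.0, 402.3, 403.0])
        rf = np.array([0.11, 0.25, 0.14, 0.33, 0.18])
        out = resample_1nm(Spectrum(wl, rf))
        assert out.reflectance[0] == rf[0]
        assert out.reflectance[list(out.wavelengths).index(401)] == rf[2]
        assert out.reflectance[list(out.wavelengths).index(403)] == rf[4]

    def test_single_band_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resample_1nm(Spectrum([400.0], [0.1]))


class TestAggregateMean:
    def _leaves(self):
        wl = np.arange(400.0, 403.0)
        layers = ["top", "top", "mid", "mid", "bottom"]
        return SpectralCollection([
            Spectrum(wl, [0.1 * (i + 1), 0.2, 0.3],
                     {"plot_id": "p1", "individual_id": "i1", "layer": lay})
            for i, lay in enumerate(layers)])

    def test_five_leaves_average_to_three_layer_spectra(self):
        out = aggregate_mean(self._leaves(), by=["individual_id", "layer"])
        assert len(out) == 3
        assert [s.meta["layer"] for s in out] == ["top", "mid", "bottom"]

    def test_group_means_match_hand_arithmetic(self):
        out = aggregate_mean(self._leaves(), by=["individual_id", "layer"])
        top = out[0]
        assert np.allclose(top.reflectance, [(0.1 + 0.2) / 2, 0.2, 0.3])

    def test_identical_spectra_average_to_themselves(self):
        wl = np.arange(400.0, 405.0)
        s = Spectrum(wl, np.linspace(0.1, 0.2, 5), {"plot_id": "p"})
        out = aggregate_mean(SpectralCollection([s, s]), by=["plot_id"])
        assert len(out) == 1
        assert np.array_equal(out[0].reflectance, s.reflectance)

    def test_commutes_with_bandwise_linear_maps(self):
        c = self._leaves()
        a, b = 1.7, 0.03
        mapped_then_agg = aggregate_mean(
            c.map(lambda s: s.with_values(a * s.reflectance + b)),
            by=["layer"])
        agg_then_mapped = aggregate_mean(c, by=["layer"]).map(
            lambda s: s.with_values(a * s.reflectance + b))
        for x, y in zip(mapped_then_agg, agg_then_mapped):
            assert np.allclose(x.reflectance, y.reflectance, atol=1e-14)

    def test_mixed_grids_rejected(self):
        c = SpectralCollection([
            Spectrum([400.0, 401.0], [0.1, 0.2], {"plot_id": "p"}),
            Spectrum([400.0, 402.0], [0.1, 0.2], {"plot_id": "p"})])
        with pytest.raises(InvalidArgumentError):
            aggregate_mean(c, by=["plot_id"])
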