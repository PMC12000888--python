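import numpy as np
import pytest

from fdomlink import eem as eem_mod
from fdomlink.eem import (
    EEM,
    AbsorbanceSpectrum,
    ScatterWidths,
    InnerFilterWarning,
    excise_and_interpolate_scatter,
    harmonize_grid,
    inner_filter_correct,
    load_eem_csv,
    raman_area,
    raman_normalize,
    subtract_blank,
    trim_wavelengths,
    write_eem_csv,
)
from fdomlink.errors import (
    CorrectionError,
    DomainError,
    FormatError,
    GridError,
    ScatterError,
    TrimError,
)

from conftest import make_eem


# ---------- loading ----------


class TestLoadEEMCsv:
    def test_parses_3x3_grid(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("em,250,260,270\n300,1,2,3\n310,4,5,6\n320,7,8,9\n")
        e = load_eem_csv(p)
        assert e.shape == (3, 3)
        assert e.corrections == ()
        np.testing.assert_array_equal(e.ex_nm, [250, 260, 270])
        np.testing.assert_array_equal(e.intensity[1], [4, 5, 6])

    def test_descending_emission_reversed(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("em,250,260\n320,7,8\n310,4,5\n300,1,2\n")
        e = load_eem_csv(p)
        np.testing.assert_array_equal(e.em_nm, [300, 310, 320])
        np.testing.assert_array_equal(e.intensity[0], [1, 2])
        np.testing.assert_array_equal(e.intensity[2], [7, 8])

    def test_corner_header_cell_ignored(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("Sample,250,260\n300,1,2\n310,3,4\n")
        e = load_eem_csv(p)
        assert e.shape == (2, 2)

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("em,250,260\n300,1,oops\n310,3,4\n")
        with pytest.raises(FormatError, match="260"):
            load_eem_csv(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            load_eem_csv(p)

    def test_non_monotone_emission(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("em,250,260\n300,1,2\n500,3,4\n310,5,6\n")
        with pytest.raises(FormatError, match="emission"):
            load_eem_csv(p)

    def test_round_trip_bit_identical(self, tmp_path, small_eem):
        p = tmp_path / "rt.csv"
        write_eem_csv(small_eem, p)
        back = load_eem_csv(p, sample_id=small_eem.sample_id)
        np.testing.assert_array_equal(back.ex_nm, small_eem.ex_nm)
        np.testing.assert_array_equal(back.em_nm, small_eem.em_nm)
        np.testing.assert_array_equal(back.intensity, small_eem.intensity)


# ---------- invariants of the data model ----------


class TestEEMModel:
    def test_shape_mismatch(self):
        with pytest.raises(GridError):
            make_eem([250, 260], [300, 310, 320], np.zeros((2, 3)))

    def test_negative_wavelength(self):
        with pytest.raises(GridError):
            make_eem([-250, 260], [300, 310], np.zeros((2, 2)))

    def test_units_require_raman_flag(self):
        with pytest.raises(CorrectionError):
            make_eem([250, 260], [300, 310], np.zeros((2, 2)), units="RU")

    def test_duplicate_flag_rejected(self):
        with pytest.raises(CorrectionError):
            make_eem([250, 260], [300, 310], np.zeros((2, 2)),
                     corrections=("trimmed", "trimmed"))


# ---------- blank subtraction ----------


class TestSubtractBlank:
    def test_identical_blank_gives_zero(self, small_eem):
        out = subtract_blank(small_eem, small_eem)
        np.testing.assert_array_equal(out.intensity, np.zeros(small_eem.shape))
        assert out.corrections == ("blank_subtracted",)

    def test_constant_offset(self, small_eem):
        import dataclasses
        sample = dataclasses.replace(small_eem, intensity=small_eem.intensity + 5.0)
        out = subtract_blank(sample, small_eem)
        np.testing.assert_allclose(out.intensity, 5.0)

    def test_recovers_generated_truth(self, small_eem):
        rng = np.random.default_rng(0)
        truth = rng.uniform(0, 10, small_eem.shape)
        import dataclasses
        sample = dataclasses.replace(small_eem,
                                     intensity=truth + small_eem.intensity)
        out = subtract_blank(sample, small_eem)
        np.testing.assert_allclose(out.intensity, truth, atol=1e-12)

    def test_grid_mismatch(self, small_eem):
        other = make_eem([250, 300], [300, 350], np.zeros((2, 2)))
        with pytest.raises(GridError):
            subtract_blank(small_eem, other)

    def test_reapplication_raises(self, small_eem):
        once = subtract_blank(small_eem, small_eem)
        with pytest.raises(CorrectionError):
            subtract_blank(once, small_eem)


# ---------- inner-filter correction ----------


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self, small_eem, flat_absorbance):
        out = inner_filter_correct(small_eem, flat_absorbance)
        np.testing.assert_array_equal(out.intensity, small_eem.intensity)
        assert out.has("ife_corrected")

    def test_unit_absorbance_times_ten(self, small_eem):
        wl = np.arange(230.0, 801.0)
        sp = AbsorbanceSpectrum("a", wl, np.ones(wl.size))
        with pytest.warns(InnerFilterWarning):  # A=1 everywhere > nothing; but pairs sum to 1
            out = inner_filter_correct(small_eem, sp, max_reliable_a=0.5)
        np.testing.assert_allclose(out.intensity, small_eem.intensity * 10.0)

    def test_tenth_absorbance_factor(self, small_eem):
        wl = np.arange(230.0, 801.0)
        sp = AbsorbanceSpectrum("a", wl, np.full(wl.size, 0.1))
        out = inner_filter_correct(small_eem, sp)
        np.testing.assert_allclose(out.intensity,
                                   small_eem.intensity * 10 ** 0.1, rtol=1e-12)

    def test_pathlength_scaling(self, small_eem):
        wl = np.arange(230.0, 801.0)
        sp = AbsorbanceSpectrum("a", wl, np.full(wl.size, 0.2), pathlength_cm=2.0)
        out = inner_filter_correct(small_eem, sp)
        np.testing.assert_allclose(out.intensity, small_eem.intensity * 10 ** 0.1,
                                   rtol=1e-12)

    def test_coverage_gap(self, small_eem):
        sp = AbsorbanceSpectrum("a", np.arange(300.0, 801.0), np.zeros(501))
        with pytest.raises(DomainError):
            inner_filter_correct(small_eem, sp)

    def test_high_absorbance_warns(self, small_eem):
        wl = np.arange(230.0, 801.0)
        sp = AbsorbanceSpectrum("a", wl, np.full(wl.size, 2.0))
        with pytest.warns(InnerFilterWarning):
            inner_filter_correct(small_eem, sp)


# ---------- Raman normalization ----------


class TestRamanNormalize:
    def _blank(self, value=1.0, em=None):
        em = np.arange(300.0, 621.0, 1.0) if em is None else em
        ex = np.array([300.0, 350.0, 400.0])
        return make_eem(ex, em, np.full((em.size, ex.size), value), "blank")

    def test_constant_blank_area_is_band_width(self, small_eem):
        blank = self._blank(1.0)
        assert raman_area(blank) == pytest.approx(57.0, abs=1e-9)

    def test_constant_two_narrow_band(self):
        blank = self._blank(2.0)
        assert raman_area(blank, em_band=(380.0, 390.0)) == pytest.approx(20.0)

    def test_triangular_blank_matches_brute_force(self):
        em = np.arange(300.0, 621.0, 2.0)
        ex = np.array([300.0, 350.0, 400.0])
        scan = np.maximum(0.0, 10.0 - np.abs(em - 399.0) / 3.0)
        blank = make_eem(ex, em, np.tile(scan[:, None], (1, 3)), "blank")
        lo, hi = 371.0, 428.0
        pts = np.concatenate(([lo], em[(em > lo) & (em < hi)], [hi]))
        vals = np.interp(pts, em, scan)
        brute = sum((pts[i + 1] - pts[i]) * (vals[i] + vals[i + 1]) / 2.0
                    for i in range(pts.size - 1))
        assert raman_area(blank) == pytest.approx(brute, rel=1e-12)

    def test_divides_and_sets_units(self, small_eem):
        blank = self._blank(2.0)
        out, area = raman_normalize(small_eem, blank, em_band=(380.0, 390.0))
        assert area == pytest.approx(20.0)
        np.testing.assert_allclose(out.intensity, small_eem.intensity / 20.0)
        assert out.units == "RU"

    def test_scale_equivariance(self, small_eem):
        import dataclasses
        blank = self._blank(2.0)
        out1, _ = raman_normalize(small_eem, blank)
        scaled_sample = dataclasses.replace(small_eem,
                                            intensity=small_eem.intensity * 7.0)
        scaled_blank = dataclasses.replace(blank, intensity=blank.intensity * 7.0)
        out2, _ = raman_normalize(scaled_sample, scaled_blank)
        np.testing.assert_allclose(out1.intensity, out2.intensity, rtol=1e-12)

    def test_zero_blank_raises(self, small_eem):
        from fdomlink.errors import NormalizationError
        blank = self._blank(0.0)
        with pytest.raises(NormalizationError):
            raman_normalize(small_eem, blank)


# ---------- scatter excision ----------


class TestScatterExcision:
    def _plane_eem(self):
        # em range chosen so every scatter band is interior to the axis
        ex = np.arange(280.0, 401.0, 10.0)
        em = np.arange(260.0, 561.0, 5.0)
        a, b, c = 2.0, 0.01, 0.02
        plane = a + b * em[:, None] + c * ex[None, :]
        return make_eem(ex, em, plane), plane

    def test_ridge_spike_refilled_to_plane(self):
        eem, plane = self._plane_eem()
        spiked = plane.copy()
        ridge = np.abs(eem.em_nm[:, None] - eem.ex_nm[None, :]) <= 8
        spiked[ridge] += 100.0
        import dataclasses
        eem2 = dataclasses.replace(eem, intensity=spiked)
        out = excise_and_interpolate_scatter(
            eem2, ScatterWidths(rayleigh1=10, raman1=5, rayleigh2=0))
        valid = eem.em_nm[:, None] >= eem.ex_nm[None, :] - 10
        np.testing.assert_allclose(out.intensity[valid], plane[valid], atol=1e-9)

    def test_zero_widths_noop(self, small_eem):
        out = excise_and_interpolate_scatter(
            small_eem, ScatterWidths(rayleigh1=0, raman1=0, rayleigh2=0))
        np.testing.assert_array_equal(out.intensity, small_eem.intensity)

    def test_constant_eem_stays_constant(self):
        # grid chosen with em safely above ex so no zero-fill region applies
        ex = np.arange(250.0, 281.0, 10.0)
        em = np.arange(300.0, 361.0, 5.0)
        eem = make_eem(ex, em, np.full((em.size, ex.size), 3.5))
        out = excise_and_interpolate_scatter(eem)
        np.testing.assert_allclose(out.intensity, 3.5)

    def test_cells_outside_ridges_untouched(self):
        eem, plane = self._plane_eem()
        w = ScatterWidths()
        out = excise_and_interpolate_scatter(eem, w)
        em = eem.em_nm[:, None]
        ex = eem.ex_nm[None, :]
        from fdomlink.eem import raman_emission_nm
        ridge = ((np.abs(em - ex) <= w.rayleigh1)
                 | (np.abs(em - raman_emission_nm(eem.ex_nm)[None, :]) <= w.raman1)
                 | (np.abs(em - 2 * ex) <= w.rayleigh2)
                 | (em < ex - w.rayleigh1))
        np.testing.assert_array_equal(out.intensity[~ridge], plane[~ridge])

    def test_sub_rayleigh_zeroed(self):
        eem, _ = self._plane_eem()
        out = excise_and_interpolate_scatter(eem)
        below = eem.em_nm[:, None] < eem.ex_nm[None, :] - 10
        assert below.any()
        np.testing.assert_array_equal(out.intensity[below], 0.0)

    def test_full_column_excision_raises(self):
        ex = np.array([300.0, 310.0])
        em = np.array([295.0, 300.0, 305.0])
        eem = make_eem(ex, em, np.ones((3, 2)))
        with pytest.raises(ScatterError):
            excise_and_interpolate_scatter(eem, ScatterWidths(rayleigh1=50))


# ---------- trimming ----------


class TestTrim:
    def test_emission_count(self):
        em = np.arange(300.0, 801.0, 2.0)
        ex = np.arange(250.0, 401.0, 10.0)
        eem = make_eem(ex, em, np.ones((em.size, ex.size)))
        out = trim_wavelengths(eem, em_max=600.0, ex_min=250.0)
        assert out.em_nm.size == 151
        assert out.em_nm[-1] == 600.0

    def test_excitation_cut_at_250(self):
        # grid includes 240-248; everything below 250 is dropped
        ex = np.arange(240.0, 451.0, 2.0)
        em = np.arange(300.0, 601.0, 5.0)
        eem = make_eem(ex, em, np.ones((em.size, ex.size)))
        out = trim_wavelengths(eem, ex_min=250.0)
        assert out.ex_nm[0] == 250.0

    def test_empty_trim_raises(self, small_eem):
        with pytest.raises(TrimError):
            trim_wavelengths(small_eem, em_max=100.0)


# ---------- grid harmonization ----------


class TestHarmonize:
    def test_identical_grids_identity(self, small_eem):
        import dataclasses
        e2 = dataclasses.replace(small_eem, sample_id="s2")
        ds = harmonize_grid([small_eem, e2])
        np.testing.assert_array_equal(ds.eems[0].intensity, small_eem.intensity)
        np.testing.assert_array_equal(ds.eems[1].intensity, small_eem.intensity)

    def test_fine_grid_values_at_shared_knots(self):
        ex = np.arange(250.0, 301.0, 10.0)
        em1 = np.arange(300.0, 401.0, 1.0)
        em2 = np.arange(300.0, 401.0, 2.0)
        rng = np.random.default_rng(1)
        i1 = rng.uniform(size=(em1.size, ex.size))
        e1 = make_eem(ex, em1, i1, "fine")
        e2 = make_eem(ex, em2, rng.uniform(size=(em2.size, ex.size)), "coarse")
        ds = harmonize_grid([e1, e2])
        np.testing.assert_array_equal(ds.em_nm, em2)
        shared = np.isin(em1, em2)
        np.testing.assert_allclose(ds.eems[0].intensity, i1[shared], atol=1e-12)

    def test_linear_surface_resampled_exactly(self):
        ex1 = np.arange(250.0, 301.0, 5.0)
        em1 = np.arange(300.0, 401.0, 5.0)
        ex2 = np.arange(250.0, 301.0, 10.0)
        em2 = np.arange(300.0, 401.0, 10.0)

        def plane(em, ex):
            return 1.0 + 0.03 * em[:, None] + 0.07 * ex[None, :]

        e1 = make_eem(ex1, em1, plane(em1, ex1), "a")
        e2 = make_eem(ex2, em2, plane(em2, ex2), "b")
        ds = harmonize_grid([e1, e2])
        np.testing.assert_allclose(ds.eems[0].intensity,
                                   plane(ds.em_nm, ds.ex_nm), atol=1e-12)

    def test_empty_intersection(self):
        e1 = make_eem([250, 260], [300, 310], np.ones((2, 2)), "a")
        e2 = make_eem([400, 410], [500, 510], np.ones((2, 2)), "b")
        with pytest.raises(GridError):
            harmonize_grid([e1, e2])


# ---------- append-only correction flags ----------


@pytest.mark.parametrize("flag", eem_mod.CORRECTION_FLAGS)
def test_corrections_append_only(flag, small_eem, flat_absorbance):
    import dataclasses
    tagged = dataclasses.replace(
        small_eem, corrections=(flag,),
        units="RU" if flag == "raman_normalized" else "arbitrary")
    blank = dataclasses.replace(small_eem, sample_id="blank")
    ops = {
        "blank_subtracted": lambda e: subtract_blank(e, blank),
        "ife_corrected": lambda e: inner_filter_correct(e, flat_absorbance),
        "raman_normalized": lambda e: raman_normalize(
            e, make_eem(np.array([350.0, 400.0]), np.arange(300.0, 621.0),
                        np.ones((321, 2)), "b")),
        "scatter_excised": excise_and_interpolate_scatter,
        "trimmed": lambda e: trim_wavelengths(e, em_max=450.0, ex_min=250.0),
    }
    with pytest.raises(CorrectionError):
        ops[flag](tagged)
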