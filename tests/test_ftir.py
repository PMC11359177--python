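"""Tests for the microFTIR processing pipeline."""

import numpy as np
import pytest

from spectarget.ftir import (
    DEFAULT_BANDS,
    Spectrum,
    amide_area,
    compare_groups,
    crop,
    detect_sub_bands,
    preprocess,
    quantify_bands,
    read_spectra_csv,
    rubberband_baseline,
    sg_second_derivative,
    vector_normalize,
    write_spectra_csv,
)
from spectarget.synthetic import (
    BandMixSpec,
    BandSpec,
    TreatmentEffectSpec,
    analytic_band_area,
    generate_cell_spectra,
)


def make_spectrum(lo=900.0, hi=1800.0, step=1.0, absorbance=None, **kw) -> Spectrum:
    w = np.arange(lo, hi + step / 2, step)
    a = np.zeros_like(w) if absorbance is None else absorbance(w)
    return Spectrum(w, a, **kw)


def gaussian(center, fwhm=25.0, amplitude=1.0):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return lambda w: amplitude * np.exp(-((w - center) ** 2) / (2 * sigma**2))


class TestCrop:
    def test_amide_region(self):
        s = make_spectrum()
        c = crop(s, 1480, 1700)
        assert c.wavenumbers[0] == 1480 and c.wavenumbers[-1] == 1700
        assert c.step == s.step

    def test_full_range_is_identity(self):
        s = make_spectrum(absorbance=gaussian(1650))
        c = crop(s, 900, 1800)
        np.testing.assert_array_equal(c.wavenumbers, s.wavenumbers)
        np.testing.assert_array_equal(c.absorbance, s.absorbance)

    def test_disjoint_window_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            crop(make_spectrum(), 2000, 2100)


class TestRubberband:
    def test_linear_ramp_maps_to_zero(self):
        s = make_spectrum(absorbance=lambda w: 0.3 + 0.002 * w)
        out = rubberband_baseline(s)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_band_on_convex_baseline_recovers_area(self):
        """Subtracting the rubber band from a Gaussian band on a convex
        quadratic baseline recovers the band area within 2% (numeric
        integration vs the closed form)."""
        band = BandSpec(1650.0, 25.0, 1.0)
        s = make_spectrum(
            absorbance=lambda w: 0.2 + 1e-6 * (w - 1300) ** 2 + band.evaluate(w)
        )
        out = rubberband_baseline(s)
        measured = amide_area(out, 1500, 1800)
        expected = analytic_band_area([band], 1500, 1800)
        assert measured == pytest.approx(expected, rel=0.02)

    def test_idempotent_on_corrected_spectrum(self):
        s = make_spectrum(absorbance=gaussian(1400, fwhm=40))
        once = rubberband_baseline(s)
        twice = rubberband_baseline(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-9)

    def test_nonnegative_with_zero_endpoints(self, rng):
        w = np.arange(900.0, 1801.0)
        a = 0.5 + 0.0005 * (w - 1300) + gaussian(1650)(w) + 0.01 * rng.normal(size=w.size)
        out = rubberband_baseline(Spectrum(w, a))
        assert out.absorbance.min() >= -1e-9
        assert out.absorbance[0] == 0.0 and out.absorbance[-1] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            rubberband_baseline(Spectrum(np.array([1.0, 2.0]), np.array([0.0, 1.0])))


class TestVectorNormalize:
    def test_three_four_five(self):
        s = Spectrum(np.array([0.0, 1.0]), np.array([3.0, 4.0]))
        np.testing.assert_allclose(vector_normalize(s).absorbance, [0.6, 0.8])

    def test_scale_invariant_and_idempotent(self, rng):
        a = rng.uniform(0.1, 1, size=50)
        s = Spectrum(np.arange(50.0), a)
        scaled = Spectrum(np.arange(50.0), 7.3 * a)
        n1, n2 = vector_normalize(s), vector_normalize(scaled)
        np.testing.assert_allclose(n1.absorbance, n2.absorbance)
        np.testing.assert_allclose(
            vector_normalize(n1).absorbance, n1.absorbance, atol=1e-15
        )
        assert np.linalg.norm(n1.absorbance) == pytest.approx(1.0)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            vector_normalize(make_spectrum())


class TestSecondDerivative:
    def test_exact_on_quadratic(self):
        a = 0.003
        s = make_spectrum(absorbance=lambda w: a * w**2)
        d2 = sg_second_derivative(s)
        np.testing.assert_allclose(d2.absorbance, 2 * a, rtol=1e-9)

    def test_exact_on_cubic(self):
        a = 1e-6
        s = make_spectrum(absorbance=lambda w: a * w**3)
        d2 = sg_second_derivative(s)
        np.testing.assert_allclose(d2.absorbance, 6 * a * d2.wavenumbers, rtol=1e-7)

    def test_gaussian_minimum_at_center(self):
        s = make_spectrum(absorbance=gaussian(1650))
        d2 = sg_second_derivative(s)
        assert d2.wavenumbers[np.argmin(d2.absorbance)] == 1650.0

    def test_trims_half_window_each_side(self):
        s = make_spectrum()
        d2 = sg_second_derivative(s, window_points=15)
        assert d2.wavenumbers[0] == s.wavenumbers[7]
        assert d2.wavenumbers[-1] == s.wavenumbers[-8]

    @pytest.mark.parametrize(
        "window,order,err",
        [(14, 3, "odd"), (3, 3, "exceed"), (2001, 3, "fewer")],
    )
    def test_parameter_validation(self, window, order, err):
        with pytest.raises(ValueError, match=err):
            sg_second_derivative(make_spectrum(), window, order)


class TestDetectSubBands:
    def test_six_reference_bands_detected(self):
        """A noiseless mixture of the six reference sub-bands yields six
        present bands with centers within 2 cm-1 of the nominal positions."""
        cells, _ = generate_cell_spectra(
            BandMixSpec(noise_sd=0.0), [TreatmentEffectSpec("c", n_cells=2)]
        )
        quant = quantify_bands(cells[0])
        assert all(b.present for b in quant.bands)
        for b in quant.bands:
            assert abs(b.detected_center - b.nominal_center) <= 2.0

    def test_flat_spectrum_has_no_bands(self):
        d2 = Spectrum(np.arange(1480.0, 1701.0), np.zeros(221))
        quant = detect_sub_bands(d2)
        assert not any(b.present for b in quant.bands)
        assert all(b.d2_intensity == 0.0 for b in quant.bands)

    def test_overlapping_pair_matches_analytic_d2_oracle(self):
        """For two bands 12 cm-1 apart the detected centers agree with the
        minima of the analytic second derivative of the band sum, evaluated
        on a dense grid."""
        b1, b2 = BandSpec(1650.0, 25.0, 1.0), BandSpec(1638.0, 25.0, 0.9)
        sigma = 25.0 / (2 * np.sqrt(2 * np.log(2)))

        def d2_analytic(w):
            total = np.zeros_like(w)
            for b in (b1, b2):
                z = w - b.center
                total += b.amplitude * (z**2 / sigma**4 - 1 / sigma**2) * np.exp(
                    -(z**2) / (2 * sigma**2)
                )
            return total

        dense = np.arange(1550.0, 1750.0, 0.001)
        vals = d2_analytic(dense)
        interior = (vals[1:-1] < vals[:-2]) & (vals[1:-1] < vals[2:])
        oracle_minima = dense[1:-1][interior]

        s = make_spectrum(absorbance=lambda w: b1.evaluate(w) + b2.evaluate(w))
        d2 = sg_second_derivative(s)
        table = DEFAULT_BANDS.__class__(((1650.0, "a"), (1638.0, "b")))
        quant = detect_sub_bands(d2, table, match_window=8.0)
        for b in quant.bands:
            assert b.present
            assert min(abs(b.detected_center - m) for m in oracle_minima) <= 1.0

    def test_coverage_violation_rejected(self):
        d2 = Spectrum(np.arange(1500.0, 1701.0), np.zeros(201))
        with pytest.raises(ValueError, match="cover"):
            detect_sub_bands(d2)


class TestAmideArea:
    def test_unit_rectangle(self):
        w = np.arange(1600.0, 1701.0)
        assert amide_area(Spectrum(w, np.ones(101)), 1600, 1700) == pytest.approx(100.0)

    def test_gaussian_closed_form(self):
        amp, fwhm = 0.8, 20.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        s = make_spectrum(absorbance=gaussian(1650, fwhm, amp))
        assert amide_area(s, 1600, 1700) == pytest.approx(
            amp * sigma * np.sqrt(2 * np.pi), rel=0.005
        )

    def test_region_outside_grid_rejected(self):
        s = make_spectrum(hi=1700.0)
        with pytest.raises(ValueError, match="outside"):
            amide_area(s, 1750, 1800)


class TestCompareGroups:
    def test_matches_hand_computed_sums_of_squares(self):
        """F statistic equals the manual between/within sum-of-squares
        arithmetic on a small fixed table."""
        groups = {"g1": [3.0, 4.0, 5.0], "g2": [5.0, 6.0, 7.0], "g3": [8.0, 9.0, 13.0]}
        values = [v for g in groups.values() for v in g]
        labels = [k for k, g in groups.items() for _ in g]
        grand = np.mean(values)
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
        ss_within = sum((v - np.mean(g)) ** 2 for g in groups.values() for v in g)
        f_manual = (ss_between / 2) / (ss_within / 6)

        res = compare_groups(values, labels, measure="toy")
        assert res.f_statistic == pytest.approx(f_manual, rel=1e-12)
        assert 0 <= res.p_value <= 1
        assert [g.n for g in res.groups] == [3, 3, 3]

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups([0.0, 0.0, 0.0, 0.0], ["a", "a", "b", "b"])

    def test_minimum_group_sizes_enforced(self):
        with pytest.raises(ValueError, match="at least 2 values"):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])
        with pytest.raises(ValueError, match="at least 2 groups"):
            compare_groups([1.0, 2.0], ["a", "a"])


class TestPipelineProperties:
    def test_processing_order_contract(self):
        """preprocess = crop -> rubber band -> vector normalize, in that
        order, on the Amide analysis region."""
        cells, _ = generate_cell_spectra(
            BandMixSpec(noise_sd=0.0), [TreatmentEffectSpec("c", n_cells=2)]
        )
        pre = preprocess(cells[0])
        manual = vector_normalize(rubberband_baseline(crop(cells[0], 1480, 1700)))
        np.testing.assert_array_equal(pre.absorbance, manual.absorbance)
        assert np.linalg.norm(pre.absorbance) == pytest.approx(1.0)

    def test_d2_intensity_linear_in_band_amplitude(self):
        """Doubling one band's generator amplitude doubles its
        second-derivative intensity (before normalization), over the
        amplitude grid 0.5/1.0/2.0."""
        intensities = []
        for amp in (0.5, 1.0, 2.0):
            bands = tuple(
                BandSpec(c, 25.0, amp if c == 1635.0 else a)
                for (c, a) in [(1685, 0.6), (1656, 1.0), (1635, 0.7), (1543, 0.8), (1515, 0.5), (1495, 0.4)]
            )
            cells, _ = generate_cell_spectra(
                BandMixSpec(bands=bands, noise_sd=0.0),
                [TreatmentEffectSpec("c", n_cells=2)],
            )
            quant = quantify_bands(cells[0], normalize=False)
            intensities.append(quant.intensity(1635.0))
        base = intensities[1]
        # SG filtering is linear; overlap from fixed neighbours adds a constant
        slope1 = intensities[1] - intensities[0]
        slope2 = intensities[2] - intensities[1]
        assert slope2 == pytest.approx(2 * slope1, rel=0.05)
        assert intensities[0] < intensities[1] < intensities[2]

    def test_amide_downshift_detected(self):
        """Rigidly downshifting the Amide I sub-bands by 3 cm-1 moves the
        detected Amide I absorbance maximum by -3 +/- 1 cm-1."""
        shift_group = TreatmentEffectSpec(
            "shifted",
            center_shift={1685.0: -3.0, 1656.0: -3.0, 1635.0: -3.0},
            n_cells=10,
        )
        cells, _ = generate_cell_spectra(
            BandMixSpec(), [TreatmentEffectSpec("control", n_cells=10), shift_group], seed=5
        )

        def amide_max(s):
            region = crop(preprocess(s), 1600, 1700)
            return region.wavenumbers[np.argmax(region.absorbance)]

        ctrl = np.mean([amide_max(s) for s in cells if s.group == "control"])
        shifted = np.mean([amide_max(s) for s in cells if s.group == "shifted"])
        assert shifted - ctrl == pytest.approx(-3.0, abs=1.0)


class TestSpectraIO:
    def test_round_trip(self, tmp_path, rng):
        w = np.arange(1400.0, 1801.0)
        spectra = [
            Spectrum(w, rng.uniform(0, 1, w.size), cell_id=f"c{i}", group="ctrl")
            for i in range(3)
        ]
        p = tmp_path / "cells.csv"
        write_spectra_csv(spectra, p)
        back = read_spectra_csv(p)
        assert [s.cell_id for s in back] == ["c0", "c1", "c2"]
        assert [s.group for s in back] == ["ctrl"] * 3
        for a, b in zip(spectra, back):
            np.testing.assert_array_equal(a.absorbance, b.absorbance)
            np.testing.assert_array_equal(a.wavenumbers, b.wavenumbers)

    def test_descending_grid_reversed_on_read(self, tmp_path):
        p = tmp_path / "desc.csv"
        lines = ["wavenumber_cm-1,c1", "group,ctrl"]
        for w, a in [(1700, 0.1), (1699, 0.2), (1698, 0.3)]:
            lines.append(f"{w},{a}")
        p.write_text("\n".join(lines) + "\n")
        (s,) = read_spectra_csv(p)
        assert s.wavenumbers.tolist() == [1698.0, 1699.0, 1700.0]
        assert s.absorbance.tolist() == [0.3, 0.2, 0.1]
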