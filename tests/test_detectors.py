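"""Detector footprints, volume averaging, scans, and the charge readout."""
import numpy as np
import pytest
from scipy.special import erf

from protondosim import DetectorSpec, Profile, ReadoutModel
from protondosim.detectors import (
    effective_footprint,
    readout_charge,
    scan_profile,
    size_effect_estimate,
    volume_average,
)
from protondosim.errors import OrientationError, ProtonDosimError
from protondosim.metrics import d50_distal, penumbra_width


def erf_aperture(a, sigma):
    def f(x):
        x = np.asarray(x, dtype=float)
        s = sigma * np.sqrt(2.0)
        return 0.5 * (erf((a - x) / s) + erf((a + x) / s))
    return f


class TestFootprints:
    def test_axial_diode_area_is_1mm2(self, diode):
        assert effective_footprint(diode).area == pytest.approx(1.0)

    def test_chamber_footprint_radius(self, markus):
        fp = effective_footprint(markus)
        assert fp.shape == "disc" and fp.a == pytest.approx(2.65)

    def test_edge_on_scan_extent_is_20um(self, diode_edge):
        fp = effective_footprint(diode_edge)
        assert fp.shape == "rect"
        assert fp.a == pytest.approx(0.020)

    def test_kernels_normalized(self, diode, markus, diode_edge):
        for det in (diode, markus, diode_edge):
            _, w = effective_footprint(det).line_kernel()
            assert w.sum() == pytest.approx(1.0)

    def test_edge_on_chamber_unsupported(self):
        with pytest.raises(OrientationError):
            DetectorSpec(kind="plane_parallel_chamber", radius=2.65,
                         orientation="edge_on")


class TestVolumeAverage:
    def test_uniform_field_returns_value(self, diode, markus, diode_edge):
        f = lambda x: np.full_like(np.asarray(x, dtype=float), 2.75)
        for det in (diode, markus, diode_edge):
            assert volume_average(f, det, 3.0) == pytest.approx(2.75)

    def test_zero_size_footprint_is_point_dose(self):
        det = DetectorSpec(kind="diode", radius=0.0)
        f = lambda x: np.asarray(x, dtype=float) ** 2
        assert volume_average(f, det, 3.0) == pytest.approx(9.0)

    def test_linear_ramp_symmetric_footprint_center_value(self, diode, markus):
        f = lambda x: 5.0 + 1.3 * np.asarray(x, dtype=float)
        for det in (diode, markus):
            assert volume_average(f, det, -2.0) == pytest.approx(
                f(-2.0), abs=2e-3
            )

    def test_reading_bounded_by_field_extrema(self, markus):
        f = erf_aperture(4.0, 0.4)
        xs = np.linspace(-8, 8, 50)
        for x in xs:
            v = volume_average(f, markus, x)
            lo = f(np.linspace(x - 2.65, x + 2.65, 200)).min()
            hi = f(np.linspace(x - 2.65, x + 2.65, 200)).max()
            assert lo - 1e-9 <= v <= hi + 1e-9

    def test_profile_support_warning(self, markus):
        p = Profile(np.linspace(0, 10, 11), np.linspace(1, 2, 11), axis="lateral")
        with pytest.warns(UserWarning, match="support"):
            volume_average(p, markus, 0.5)


class TestScans:
    def test_chamber_partial_volume_on_8mm_beam(self, spec127_8mm, markus):
        """The chamber under-reads the peak of a narrow beam; the diode doesn't."""
        from protondosim.detectors import DetectorSpec

        z_peak = 94.9
        stage = z_peak - markus.window_wet  # SV lands on the Bragg peak
        scan = scan_profile(spec127_8mm, markus, axis="depth",
                            start=stage, stop=stage + 0.01, step=0.1)
        point = scan_profile(spec127_8mm,
                             DetectorSpec(kind="plane_parallel_chamber",
                                          radius=0.0, window_wet=1.06),
                             axis="depth",
                             start=stage, stop=stage + 0.01, step=0.1)
        assert scan.dose[0] < point.dose[0]

    @pytest.mark.parametrize("r", [0.5, 0.564, 1.0])
    def test_axial_disc_broadening_half_r(self, r):
        """20-80 broadening ~= 0.5 r when the edge is detector-dominated.

        The slope-1 rule holds for penumbras comparable to the footprint
        (sigma ~= r/3); a much softer edge dilutes the effect.
        """
        sigma = 0.35 * r
        a = max(8 * r, 4.0)
        f = erf_aperture(a, sigma)
        det = DetectorSpec(kind="diode", radius=r)
        lim = a + r + 6 * sigma + 1
        sp = scan_profile(f, det, axis="lateral", start=-lim, stop=lim, step=0.02)
        pt = Profile(sp.positions, f(sp.positions), axis="lateral")
        broadening = penumbra_width(sp)[2] - penumbra_width(pt)[2]
        assert broadening == pytest.approx(0.5 * r, rel=0.20)

    def test_edge_on_broadening_below_10um(self, diode_edge):
        sigma = 0.2
        f = erf_aperture(4.0, sigma)
        sp = scan_profile(f, diode_edge, axis="lateral", start=-7, stop=7,
                          step=0.005, quad_step=0.002)
        pt = Profile(sp.positions, f(sp.positions), axis="lateral")
        assert penumbra_width(sp)[2] - penumbra_width(pt)[2] < 0.01

    def test_broadening_monotone_in_radius(self):
        f = erf_aperture(10.0, 0.7)
        prev = -1.0
        for r in (0.1, 0.5, 1.0, 2.65):
            kind = "plane_parallel_chamber" if r > 2 else "diode"
            det = DetectorSpec(kind=kind, radius=r)
            sp = scan_profile(f, det, axis="lateral", start=-16, stop=16, step=0.02)
            pt = Profile(sp.positions, f(sp.positions), axis="lateral")
            b = penumbra_width(sp)[2] - penumbra_width(pt)[2]
            assert b >= prev - 1e-6
            prev = b

    def test_window_wet_shifts_uncorrected_depth_scans(self, spec127, diode, markus):
        """Uncorrected stage-coordinate scans differ by the window-WET delta."""
        kw = dict(axis="depth", start=40.0, stop=120.0, step=0.25,
                  window_correction=False)
        d50_diode = d50_distal(scan_profile(spec127, diode, **kw))
        d50_markus = d50_distal(scan_profile(spec127, markus, **kw))
        assert d50_markus - d50_diode == pytest.approx(1.33 - 1.06, abs=0.25)

    def test_corrected_depth_scans_agree(self, spec127, diode, markus):
        kw = dict(axis="depth", start=40.0, stop=120.0, step=0.25)
        d50_diode = d50_distal(scan_profile(spec127, diode, **kw))
        d50_markus = d50_distal(scan_profile(spec127, markus, **kw))
        assert d50_diode == pytest.approx(d50_markus, abs=0.25)

    def test_depth_scan_requires_axial(self, spec127, diode_edge):
        with pytest.raises(OrientationError):
            scan_profile(spec127, diode_edge, axis="depth",
                         start=0, stop=100, step=1.0)


class TestReadout:
    def test_zero_dose_returns_offset(self, diode, readout_noise_free):
        assert readout_charge(0.0, 0.0, 1.5, diode, readout_noise_free) == \
            pytest.approx(readout_noise_free.offset)

    def test_affine_in_dose_noise_free(self, diode):
        model = ReadoutModel(noise_sd=0.0, decay_rate=0.0)
        doses = np.array([0.5, 2.0, 8.0, 16.0])
        q = np.array([readout_charge(d, 0.0, 1.5, diode, model) for d in doses])
        # exactly affine: second differences of q against dose vanish
        slope = (q[1] - q[0]) / (doses[1] - doses[0])
        np.testing.assert_allclose(q, model.offset + slope * doses, rtol=1e-12)
        assert slope == pytest.approx(model.sensitivity * 1000.0)

    def test_decay_factor_one_percent_at_100gy(self, diode):
        model = ReadoutModel(noise_sd=0.0, decay_rate=1e-4)
        fresh = readout_charge(2.0, 0.0, 1.5, diode, model) - model.offset
        aged = readout_charge(2.0, 100.0, 1.5, diode, model) - model.offset
        assert aged / fresh == pytest.approx(0.99)

    def test_orientation_factor_applied_edge_on_only(self, diode, diode_edge):
        model = ReadoutModel(noise_sd=0.0, orientation_factor=0.994)
        ax = readout_charge(2.0, 0.0, 1.5, diode, model) - model.offset
        eo = readout_charge(2.0, 0.0, 1.5, diode_edge, model) - model.offset
        assert eo / ax == pytest.approx(0.994)

    def test_dose_rate_has_no_effect(self, diode, readout_noise_free):
        q = [readout_charge(2.0, 0.0, r, diode, readout_noise_free)
             for r in (0.7, 1.5, 2.3)]
        assert np.ptp(q) == 0.0

    def test_noise_requires_rng(self, diode):
        with pytest.raises(ProtonDosimError):
            readout_charge(2.0, 0.0, 1.5, diode, ReadoutModel(noise_sd=0.01))

    def test_negative_accumulated_rejected(self, diode, readout_noise_free):
        with pytest.raises(ProtonDosimError):
            readout_charge(2.0, -1.0, 1.5, diode, readout_noise_free)

    def test_let_overresponse_toggle(self, diode):
        model = ReadoutModel(noise_sd=0.0, let_threshold=5.0, let_slope=0.02)
        base = readout_charge(2.0, 0.0, 1.5, diode, model,
                              lineal_energy=3.0) - model.offset
        hot = readout_charge(2.0, 0.0, 1.5, diode, model,
                             lineal_energy=10.0) - model.offset
        assert hot / base == pytest.approx(1.0 + 0.02 * 5.0)


class TestSizeEffect:
    def test_axial_diode_rounds_to_0p3(self, diode):
        assert size_effect_estimate(diode) == pytest.approx(0.3)

    def test_edge_on_is_9_microns(self, diode_edge):
        assert size_effect_estimate(diode_edge) == pytest.approx(0.009)

    def test_vanishing_detector(self):
        assert size_effect_estimate(DetectorSpec(kind="diode", radius=0.0)) == 0.0
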