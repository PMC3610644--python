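"""Spectrum container, I/O, normalization, baseline and alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cwesr as cw
from cwesr.exceptions import (
    AlignmentError,
    InvalidSpectrumError,
    SpectrumIOError,
)


class TestSpectrumInvariants:
    def test_rejects_short_spectra(self):
        f = np.linspace(0, 10, 32)
        with pytest.raises(InvalidSpectrumError, match="at least 64"):
            cw.Spectrum(f, np.zeros(32))

    def test_rejects_non_monotone_axis(self):
        f = np.linspace(10, 0, 128)
        with pytest.raises(InvalidSpectrumError, match="non-monotone"):
            cw.Spectrum(f, np.zeros(128))

    def test_rejects_non_uniform_axis(self):
        f = np.sort(np.random.default_rng(0).uniform(0, 100, 128))
        with pytest.raises(InvalidSpectrumError, match="not uniform"):
            cw.Spectrum(f, np.zeros(128))

    def test_meta_positivity(self):
        with pytest.raises(InvalidSpectrumError):
            cw.AcquisitionMeta(modulation_amplitude_G=-1.0)


class TestIO:
    def test_roundtrip_exact(self, triplet, tmp_path):
        """write → read reproduces field and intensity to 1e-9."""
        for dialect in ("whitespace", "csv", "tsv"):
            path = tmp_path / f"spec_{dialect}.txt"
            cw.write_spectrum(triplet, path, dialect=dialect)
            back = cw.read_spectrum(path, dialect=dialect)
            np.testing.assert_allclose(back.field_G, triplet.field_G, atol=1e-9)
            np.testing.assert_allclose(back.intensity, triplet.intensity, atol=1e-9)

    def test_metadata_roundtrip(self, triplet, tmp_path):
        path = tmp_path / "s.txt"
        cw.write_spectrum(triplet, path)
        assert cw.read_spectrum(path).meta.modulation_amplitude_G == pytest.approx(1.0)

    def test_extra_columns_ignored(self, tmp_path):
        path = tmp_path / "three_col.txt"
        f = np.linspace(3300, 3400, 101)
        with open(path, "w") as fh:
            for b in f:
                fh.write(f"{b} {np.sin(b)} 999\n")
        s = cw.read_spectrum(path)
        assert s.n == 101
        np.testing.assert_allclose(s.intensity, np.sin(f))

    def test_descending_field_raises(self, tmp_path):
        path = tmp_path / "desc.txt"
        with open(path, "w") as fh:
            for b in np.linspace(3400, 3300, 101):
                fh.write(f"{b} 0.0\n")
        with pytest.raises(SpectrumIOError, match="non-monotone field axis"):
            cw.read_spectrum(path)

    def test_non_numeric_row_raises(self, tmp_path):
        path = tmp_path / "bad.txt"
        with open(path, "w") as fh:
            fh.write("\n".join(f"{x} 0.0" for x in range(100)))
            fh.write("\noops nan_text\n")
        with pytest.raises(SpectrumIOError, match="non-numeric"):
            cw.read_spectrum(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(SpectrumIOError, match="no such"):
            cw.read_spectrum(tmp_path / "absent.txt")


class TestNormalization:
    def test_unit_double_integral(self, triplet):
        out = cw.normalize_to_unit_spins(triplet)
        assert cw.double_integral(out) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, triplet):
        scaled = triplet.with_intensity(7.3 * triplet.intensity)
        a = cw.normalize_to_unit_spins(triplet)
        b = cw.normalize_to_unit_spins(scaled)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_idempotent(self, triplet):
        once = cw.normalize_to_unit_spins(triplet)
        twice = cw.normalize_to_unit_spins(once)
        np.testing.assert_allclose(once.intensity, twice.intensity, rtol=1e-12)

    def test_inverted_signal_raises(self, triplet):
        with pytest.raises(InvalidSpectrumError, match="positive"):
            cw.normalize_to_unit_spins(triplet.with_intensity(-triplet.intensity))

    def test_equal_mixture_splits_area(self, triplet, powder):
        """Sum of two unit-spin spectra renormalizes to 0.5/0.5 areas."""
        grid = cw.field_axis(3350.0, 39.0, 0.02)
        a = cw.normalize_to_unit_spins(
            cw.Spectrum(grid, np.interp(grid, triplet.field_G, triplet.intensity))
        )
        b = cw.normalize_to_unit_spins(
            cw.Spectrum(grid, np.interp(grid, powder.field_G, powder.intensity))
        )
        both = cw.normalize_to_unit_spins(
            a.with_intensity(a.intensity + b.intensity)
        )
        assert cw.double_integral(both) == pytest.approx(1.0, abs=1e-9)
        # the sum of two unit-spin spectra has DI = 2, so renormalization
        # halves each component: each contributes area 0.5
        a_part = both.with_intensity(both.intensity - 0.5 * b.intensity)
        b_part = both.with_intensity(both.intensity - 0.5 * a.intensity)
        assert cw.double_integral(a_part) == pytest.approx(0.5, abs=1e-6)
        assert cw.double_integral(b_part) == pytest.approx(0.5, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        alpha=st.floats(0.0, 10.0, allow_nan=False),
        beta=st.floats(0.0, 10.0, allow_nan=False),
    )
    def test_double_integral_linearity(self, alpha, beta):
        """DI(αa + βb) = α·DI(a) + β·DI(b) on a shared grid."""
        axis = cw.field_axis(3350.0, 34.0, 0.05)
        a = cw.simulate_isotropic_triplet(
            cw.IsotropicTripletParams(a_N_G=15.0, W0_G=1.5), axis
        )
        b = cw.simulate_isotropic_triplet(
            cw.IsotropicTripletParams(a_N_G=14.0, W0_G=2.0), axis
        )
        combo = a.with_intensity(alpha * a.intensity + beta * b.intensity)
        expected = alpha * cw.double_integral(a) + beta * cw.double_integral(b)
        assert cw.double_integral(combo) == pytest.approx(expected, abs=1e-9 * (1 + expected))


class TestBaseline:
    @pytest.mark.parametrize(
        "order,baseline",
        [
            (0, lambda f: 2.0 * np.ones_like(f)),
            (1, lambda f: 0.05 * (f - f[0]) - 1.0),
            (3, lambda f: 1e-6 * (f - f.mean()) ** 3 + 0.5),
        ],
    )
    def test_polynomial_baseline_removed(self, order, baseline):
        """A pure polynomial drift (no signal) is removed everywhere."""
        f = np.linspace(3300.0, 3400.0, 1001)
        drifted = cw.Spectrum(f, baseline(f))
        fixed = cw.baseline_correct(drifted, order=order)
        assert np.abs(fixed.intensity).max() < 1e-6

    def test_offset_removed_from_spectrum(self, triplet):
        """A constant offset on a real triplet is removed to <1e-6."""
        drifted = triplet.with_intensity(triplet.intensity + 2.0)
        fixed = cw.baseline_correct(drifted, order=0)
        np.testing.assert_allclose(fixed.intensity, triplet.intensity, atol=1e-6)

    def test_identity_on_clean_spectrum(self, triplet):
        out = cw.baseline_correct(triplet, order=0)
        np.testing.assert_allclose(out.intensity, triplet.intensity, atol=1e-9)

    def test_order_limit(self, triplet):
        with pytest.raises(ValueError, match="0..3"):
            cw.baseline_correct(triplet, order=4)


class TestResampleAlign:
    def test_identical_spectra_zero_shift(self, triplet):
        _, _, shift = cw.resample_align(triplet, triplet)
        assert shift == pytest.approx(0.0, abs=1e-9)

    def test_known_shift_recovered(self, triplet):
        """b displaced by +1.2 G along the field axis → shift_G = −1.2."""
        b_int = np.interp(triplet.field_G, triplet.field_G + 1.2, triplet.intensity)
        b = cw.Spectrum(triplet.field_G, b_int)
        a_al, b_al, shift = cw.resample_align(triplet, b)
        assert shift == pytest.approx(-1.2, abs=0.05)
        core = slice(200, a_al.n - 200)
        resid = np.sqrt(np.mean((a_al.intensity[core] - b_al.intensity[core]) ** 2))
        assert resid < 0.02 * np.max(np.abs(a_al.intensity))

    def test_disjoint_ranges_raise(self):
        f1 = np.linspace(3300, 3340, 200)
        f2 = np.linspace(3360, 3400, 200)
        a = cw.Spectrum(f1, np.sin(f1))
        b = cw.Spectrum(f2, np.sin(f2))
        with pytest.raises(AlignmentError, match="insufficient overlap"):
            cw.resample_align(a, b)

    def test_excessive_shift_raises(self, triplet):
        b_int = np.interp(triplet.field_G, triplet.field_G + 6.0, triplet.intensity)
        b = cw.Spectrum(triplet.field_G, b_int)
        with pytest.raises(AlignmentError, match="exceeds"):
            cw.resample_align(triplet, b, max_shift_G=5.0)
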