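import numpy as np
import pytest

from conftest import SPECIES_ORDER, design_matrix
from lipidquant.model import QUANT_WINDOW_ORDER
from lipidquant.nmr import (
    CompositionError,
    MoleVector,
    Spectrum,
    TmsReferenceError,
    WindowAreas,
    integrate_window,
    mole_numbers,
    mole_percents,
    normalize_to_tms,
    quantify,
    weight_percents,
)

MOL_KEYS = ("MAG", "1,2-DAG", "1,3-DAG", "TAG", "FA")


def lorentzian(x, center, hwhm, area=1.0):
    return area * (hwhm / np.pi) / ((x - center) ** 2 + hwhm**2)


def areas_from(mapping):
    base = {k: 0.0 for k in QUANT_WINDOW_ORDER}
    base.update(mapping)
    return WindowAreas(base)


class TestSpectrum:
    def test_ascending_input_normalized_to_descending(self):
        ppm = np.linspace(-0.5, 10.0, 1001)
        spec = Spectrum(ppm, np.ones_like(ppm))
        assert spec.ppm[0] > spec.ppm[-1]
        assert integrate_window(spec, 0.0, 1.0) == pytest.approx(1.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            Spectrum(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([0.0, 1.0]), np.zeros(3))


class TestIntegrateWindow:
    def test_lorentzian_against_analytic_cdf(self):
        # oracle: the Lorentzian CDF integral over the window
        x = np.linspace(-0.5, 10.0, 2**16)
        hwhm, c = 0.002, 2.0
        spec = Spectrum(x, lorentzian(x, c, hwhm))
        lo, hi = 1.8, 2.2
        analytic = (np.arctan((hi - c) / hwhm) - np.arctan((lo - c) / hwhm)) / np.pi
        assert integrate_window(spec, lo, hi) == pytest.approx(analytic, rel=1e-3)
        assert analytic == pytest.approx(1.0, abs=0.01)  # half-width << window

    def test_zero_intensity_integrates_to_zero(self):
        x = np.linspace(0.0, 10.0, 101)
        assert integrate_window(Spectrum(x, np.zeros_like(x)), 2.0, 3.0) == 0.0

    def test_window_outside_range_rejected(self):
        x = np.linspace(0.0, 5.0, 101)
        spec = Spectrum(x, np.ones_like(x))
        with pytest.raises(ValueError, match="outside"):
            integrate_window(spec, 4.5, 5.5)

    def test_edge_interpolation_is_exact_for_linear_trace(self):
        # a straight-line trace integrates exactly under the trapezoid rule,
        # including fractional-gridpoint window borders
        x = np.linspace(0.0, 10.0, 97)
        spec = Spectrum(x, 2.0 * x + 1.0)
        lo, hi = 1.2345, 6.789
        exact = (hi**2 - lo**2) + (hi - lo)
        assert integrate_window(spec, lo, hi) == pytest.approx(exact, rel=1e-12)

    def test_linear_baseline_removes_chord(self):
        x = np.linspace(0.0, 10.0, 1001)
        spec = Spectrum(x, 3.0 * x + 2.0)
        assert integrate_window(spec, 1.0, 4.0, baseline="linear") == pytest.approx(
            0.0, abs=1e-9
        )


class TestNormalizeToTms:
    def _spec_with_tms(self, tms_area):
        x = np.linspace(-0.5, 10.0, 2**15)
        return Spectrum(x, lorentzian(x, 0.0, 0.002, area=tms_area))

    def test_scaling_to_unit_integral(self):
        spec = self._spec_with_tms(5.0)
        normed, raw = normalize_to_tms(spec)
        assert integrate_window(normed, -0.05, 0.05) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(normed.intensity, spec.intensity / raw)

    def test_idempotent(self):
        normed, _ = normalize_to_tms(self._spec_with_tms(5.0))
        again, raw2 = normalize_to_tms(normed)
        assert raw2 == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(again.intensity, normed.intensity, rtol=1e-9)

    def test_flat_zero_spectrum_rejected(self):
        x = np.linspace(-0.5, 10.0, 1024)
        with pytest.raises(TmsReferenceError):
            normalize_to_tms(Spectrum(x, np.zeros_like(x)))


class TestMoleNumbers:
    def test_pure_tag_back_substitution(self):
        mv = mole_numbers(areas_from({"4.11-4.38": 4.0, "2.28-2.38": 6.0}))
        assert mv.as_dict() == pytest.approx(
            {"1-MAG": 0, "2-MAG": 0, "1,2-DAG": 0, "1,3-DAG": 0, "TAG": 1.0, "FA": 0}
        )

    def test_all_zero_areas_give_zero_moles(self):
        assert mole_numbers(areas_from({})).total == 0.0

    def test_mixed_dag_composition(self):
        mv = mole_numbers(
            areas_from(
                {"3.72-3.74": 2.0, "4.05-4.10": 1.0, "4.11-4.38": 6.0, "2.28-2.38": 8.0}
            )
        )
        assert mv.as_dict() == pytest.approx(
            {"1-MAG": 0, "2-MAG": 0, "1,2-DAG": 1.0, "1,3-DAG": 1.0, "TAG": 0, "FA": 0}
        )

    def test_matches_generic_linear_solve_on_random_vectors(self, table):
        # the printed back-substitution must equal a generic solve of the
        # proton-count linear system
        A = design_matrix(table)
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_true = rng.uniform(0.0, 10.0, size=6)
            areas = A @ n_true
            mv = mole_numbers(
                WindowAreas(dict(zip(QUANT_WINDOW_ORDER, areas)))
            )
            n_solved = np.linalg.solve(A, areas)
            got = [mv.as_dict()[k] for k in
                   ("1-MAG", "2-MAG", "1,2-DAG", "1,3-DAG", "TAG", "FA")]
            np.testing.assert_allclose(got, n_solved, atol=1e-10)
            np.testing.assert_allclose(got, n_true, atol=1e-10)

    def test_large_negative_budget_raises(self):
        # a big ester envelope with no alpha-CH2 signal is impossible
        with pytest.raises(CompositionError, match="FA"):
            mole_numbers(areas_from({"4.11-4.38": 4.0, "2.28-2.38": 0.0}))

    def test_small_negative_clamped_with_diagnostic(self):
        mv = mole_numbers(
            areas_from({"4.11-4.38": 4.0, "2.28-2.38": 6.0 - 0.02}),
        )
        assert mv.n_fa == 0.0
        assert mv.clamped == ["FA"]


class TestMolePercents:
    def test_symmetric_dag_split(self):
        mp = mole_percents(MoleVector(0, 0, 1.0, 1.0, 0, 0))
        assert mp["1,2-DAG"] == pytest.approx(50.0)
        assert mp["1,3-DAG"] == pytest.approx(50.0)
        assert mp["DAG"] == pytest.approx(100.0)

    def test_invariant_under_scaling(self):
        base = MoleVector(0.5, 0.5, 1, 1, 2, 1)
        scaled = MoleVector(*(7.3 * v for v in (0.5, 0.5, 1, 1, 2, 1)))
        assert mole_percents(base) == pytest.approx(mole_percents(scaled))

    def test_hand_computed_mixture(self):
        mp = mole_percents(MoleVector(0.5, 0.5, 1, 1, 2, 1))
        assert mp["MAG"] == pytest.approx(100 / 6, abs=1e-9)
        assert mp["DAG"] == pytest.approx(200 / 6, abs=1e-9)
        assert mp["TAG"] == pytest.approx(200 / 6, abs=1e-9)
        assert mp["FA"] == pytest.approx(100 / 6, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(CompositionError, match="undefined|zero"):
            mole_percents(MoleVector(0, 0, 0, 0, 0, 0))

    def test_conservation_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            mv = MoleVector(*rng.uniform(0, 5, size=6))
            if mv.total == 0:
                continue
            mp = mole_percents(mv)
            assert sum(mp[k] for k in MOL_KEYS) == pytest.approx(100.0, abs=1e-6)
            assert mp["DAG"] == mp["1,2-DAG"] + mp["1,3-DAG"]


class TestWeightPercents:
    def test_equimolar_dag_tag(self):
        mp = {"MAG": 0, "1,2-DAG": 50, "1,3-DAG": 0, "DAG": 50, "TAG": 50, "FA": 0}
        wp = weight_percents(mp)
        assert wp["1,2-DAG"] == pytest.approx(
            100 * 620.98 / (620.98 + 885.43), abs=1e-9
        )
        assert wp["1,2-DAG"] == pytest.approx(41.22, abs=0.005)

    def test_single_class_is_all_the_weight(self):
        mp = {"MAG": 0, "1,2-DAG": 100, "1,3-DAG": 0, "DAG": 100, "TAG": 0, "FA": 0}
        assert weight_percents(mp)["1,2-DAG"] == pytest.approx(100.0)

    def test_isomers_share_the_dag_mass(self):
        mp = {"MAG": 0, "1,2-DAG": 50, "1,3-DAG": 50, "DAG": 100, "TAG": 0, "FA": 0}
        wp = weight_percents(mp)
        assert wp["1,2-DAG"] == pytest.approx(50.0)
        assert wp["1,3-DAG"] == pytest.approx(50.0)

    def test_weights_sum_to_100(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mv = MoleVector(*rng.uniform(0, 5, size=6))
            wp = weight_percents(mole_percents(mv))
            assert sum(wp[k] for k in MOL_KEYS) == pytest.approx(100.0, abs=1e-6)


class TestQuantify:
    def test_tms_only_spectrum_has_undefined_composition(self):
        x = np.linspace(-0.5, 10.0, 2**15)
        spec = Spectrum(x, lorentzian(x, 0.0, 0.001, area=1.5))
        with pytest.raises(CompositionError):
            quantify(spec)

    def test_spectrum_without_tms_rejected(self):
        x = np.linspace(-0.5, 10.0, 2**15)
        y = lorentzian(x, 4.245, 0.001, area=4.0)
        y[np.abs(x) < 0.2] = 0.0  # no reference signal at 0 ppm
        with pytest.raises(TmsReferenceError):
            quantify(Spectrum(x, y))
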