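"""Micro-canonical derivatives, canonical reweighting and transition calls."""

import numpy as np
import pytest

from samcpoly.observables import EnergyResolvedObservables
from samcpoly.samc import DOSEstimate
from samcpoly.thermo import (
    EnergyGapError,
    MicroCanonicalCurves,
    canonical_average,
    canonical_curves,
    canonical_moments,
    classify_transitions_micro,
    detect_bimodality,
    energy_distribution,
    locate_transitions_canonical,
    log_partition_function,
    micro_curves,
    specific_heat,
    specific_heat_literal,
)


def _dos(energies, ln_g):
    energies = np.asarray(energies)
    return DOSEstimate(energies, np.asarray(ln_g, float), np.ones(len(energies), int))


def _two_level():
    return _dos([-1, 0], [0.0, 0.0])


def _smooth_50_level():
    # synthetic 50-level DOS with gentle curvature
    e = np.arange(-49, 1)
    return _dos(e, -0.004 * (e + 25.0) ** 2 + 0.3 * np.sin(e / 7.0))


class TestMicroCurves:
    def test_linear_entropy(self):
        e = np.arange(-20, 1)
        c = micro_curves(_dos(e, 1.7 * e))
        assert np.allclose(c.beta_micro, 1.7, atol=1e-12)
        assert np.allclose(c.gamma_e, 0.0, atol=1e-12)

    def test_quadratic_entropy_exact_second_difference(self):
        e = np.arange(-30, 1)
        c = micro_curves(_dos(e, -0.02 * e.astype(float) ** 2))
        assert np.allclose(c.gamma_e, -0.04, atol=1e-12)

    def test_interior_maximum_gives_negative_beta(self):
        # entropy maximum at finite energy: negative micro-canonical
        # temperature beyond it, as for Boltzmann entropies of finite systems
        e = np.arange(-30, 1)
        s = -0.05 * (e + 10.0) ** 2
        c = micro_curves(_dos(e, s))
        signs = np.sign(c.beta_micro)
        assert signs[0] > 0 and signs[-1] < 0

    def test_refuses_gaps_by_default(self):
        e = np.array([-10, -9, -8, -5, -4, -3])
        with pytest.raises(EnergyGapError):
            micro_curves(_dos(e, np.zeros(6)))
        micro_curves(_dos(e, np.zeros(6)), allow_gaps=True)

    def test_smoothing_recorded(self):
        dos = _smooth_50_level()
        c = micro_curves(dos, smoothing=(7, 2))
        assert c.smoothing == "savgol(window=7, polyorder=2)"
        assert micro_curves(dos).smoothing == "none"

    def test_needs_five_levels(self):
        with pytest.raises(ValueError):
            micro_curves(_dos([-3, -2, -1, 0], np.zeros(4)))


class TestClassifyMicro:
    def _curves(self, gamma):
        gamma = np.asarray(gamma, float)
        e = np.arange(len(gamma), dtype=float)
        return MicroCanonicalCurves(
            energies=np.arange(len(gamma) + 2, dtype=float),
            entropy=np.zeros(len(gamma) + 2),
            interior_energies=e,
            beta_micro=np.zeros(len(gamma)),
            gamma_e=gamma,
        )

    def test_positive_peak_is_first_order(self):
        gamma = np.array([-0.1, -0.05, 0.3, -0.05, -0.1])
        recs = classify_transitions_micro(self._curves(gamma))
        assert len(recs) == 1
        assert recs[0].order == "first"
        assert recs[0].diagnostics["gamma_peak_value"] == pytest.approx(0.3)

    def test_negative_peak_is_second_order(self):
        gamma = np.array([-0.5, -0.4, -0.2, -0.4, -0.5])
        recs = classify_transitions_micro(self._curves(gamma))
        assert len(recs) == 1
        assert recs[0].order == "second"

    def test_monotone_curve_has_no_peaks(self):
        recs = classify_transitions_micro(self._curves(np.linspace(-1, 1, 9)))
        assert recs == []


class TestPartitionFunction:
    def test_single_level(self):
        dos = _dos([0], [0.0])
        for t in (0.1, 1.0, 10.0):
            assert log_partition_function(dos, t) == 0.0
            assert specific_heat(dos, t) == 0.0

    def test_two_level_closed_form(self):
        dos = _two_level()
        assert log_partition_function(dos, 1.0) == pytest.approx(
            np.log(1 + np.e), rel=1e-12
        )

    def test_high_temperature_limit(self):
        dos = _dos([-3, -1, 0], [1.0, 0.5, 0.0])
        expected = np.log(np.exp(1.0) + np.exp(0.5) + 1.0)
        assert log_partition_function(dos, 1e8) == pytest.approx(expected, rel=1e-6)

    def test_temperature_validation(self):
        with pytest.raises(ValueError):
            log_partition_function(_two_level(), 0.0)
        with pytest.raises(ValueError):
            specific_heat(_two_level(), -1.0)


class TestSpecificHeat:
    def test_schottky_peak_value(self):
        # two-level system: C(T=1) with gap 1 equals e/(1+e)^2
        dos = _two_level()
        assert specific_heat(dos, 1.0) == pytest.approx(np.e / (1 + np.e) ** 2, rel=1e-12)

    def test_fluctuation_vs_literal_form(self):
        # compared where both routes are numerically stable; at very low T
        # the literal Z-derivative form loses digits to cancellation, which
        # is why the fluctuation form is the production implementation
        dos = _smooth_50_level()
        for t in np.linspace(0.3, 2.0, 40):
            a = specific_heat(dos, t)
            b = specific_heat_literal(dos, t)
            assert b == pytest.approx(a, rel=1e-6, abs=1e-12)

    def test_nonnegative_everywhere(self):
        dos = _smooth_50_level()
        for t in np.linspace(0.02, 5.0, 100):
            assert specific_heat(dos, t) >= 0.0

    def test_energy_from_lnz_derivative(self):
        # <E> = T^2 d(lnZ)/dT, checked by central finite difference
        dos = _smooth_50_level()
        for t in (0.3, 0.7, 1.5):
            h = 1e-5 * t
            d = (
                log_partition_function(dos, t + h)
                - log_partition_function(dos, t - h)
            ) / (2 * h)
            e_mean, _ = canonical_moments(dos, t)
            assert e_mean == pytest.approx(t * t * d, rel=1e-6)


class TestCanonicalAverage:
    def _obs_two_level(self, values):
        obs = EnergyResolvedObservables(n_monomers=2, well_width=1.1, track_contacts=False)
        from samcpoly.observables import _LevelAccumulator

        for e, v in values.items():
            obs._levels[e] = _LevelAccumulator(count=10, rg2_mean=v)
        return obs

    def test_constant_observable(self):
        dos = _two_level()
        obs = self._obs_two_level({-1: 3.3, 0: 3.3})
        for t in (0.2, 1.0, 5.0):
            assert canonical_average(obs, dos, t) == pytest.approx(3.3, rel=1e-12)

    def test_two_level_closed_form(self):
        dos = _two_level()
        obs = self._obs_two_level({-1: 1.0, 0: 0.0})
        assert canonical_average(obs, dos, 1.0) == pytest.approx(
            np.e / (1 + np.e), rel=1e-12
        )

    def test_low_temperature_limit(self):
        dos = _two_level()
        obs = self._obs_two_level({-1: 1.0, 0: 0.0})
        assert canonical_average(obs, dos, 0.01) == pytest.approx(1.0, abs=1e-12)

    def test_missing_level_warns_and_renormalizes(self):
        dos = _dos([-2, -1, 0], [0.0, 0.0, 0.0])
        obs = self._obs_two_level({-1: 1.0, 0: 0.0})
        with pytest.warns(UserWarning, match="renormalizing"):
            val = canonical_average(obs, dos, 1.0)
        assert val == pytest.approx(np.e / (1 + np.e), rel=1e-12)


class TestEnergyDistribution:
    def test_normalized(self):
        dos = _smooth_50_level()
        for t in (0.1, 0.5, 2.0):
            _, p = energy_distribution(dos, t)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_gaussian_bimodal_at_matched_temperature(self):
        a, b, sig = -40.0, -10.0, 4.0
        beta_m = 0.5
        e = np.arange(-55, 1, dtype=float)
        ln_g = np.logaddexp(
            -((e - a) ** 2) / (2 * sig**2), -((e - b) ** 2) / (2 * sig**2)
        ) + beta_m * e
        dos = _dos(e.astype(int), ln_g)
        energies, p = energy_distribution(dos, 1.0 / beta_m)
        bimodal, peaks = detect_bimodality(p)
        assert bimodal
        peak_energies = sorted(int(energies[k]) for k in peaks)
        assert abs(peak_energies[0] - a) <= 2
        assert abs(peak_energies[1] - b) <= 2

    def test_single_gaussian_unimodal(self):
        e = np.arange(-40, 1, dtype=float)
        dos = _dos(e.astype(int), -((e + 20) ** 2) / 30.0)
        _, p = energy_distribution(dos, 1.0)
        bimodal, _ = detect_bimodality(p)
        assert not bimodal


class TestLocateCanonical:
    def test_consensus_and_interval(self):
        t = np.linspace(0.1, 1.0, 181)
        bump = lambda c: np.exp(-((t - c) ** 2) / (2 * 0.02**2))
        rec = locate_transitions_canonical(
            {"cv": (t, bump(0.50)), "drg2": (t, bump(0.54))}
        )
        assert rec.location == pytest.approx(0.52, abs=1e-9)
        assert rec.interval[0] == pytest.approx(0.50, abs=1e-9)
        assert rec.interval[1] == pytest.approx(0.54, abs=1e-9)

    def test_identical_peaks_zero_width(self):
        t = np.linspace(0.1, 1.0, 181)
        y = np.exp(-((t - 0.4) ** 2) / (2 * 0.02**2))
        rec = locate_transitions_canonical({"a": (t, y), "b": (t, y.copy())})
        assert rec.interval == (rec.location, rec.location)

    def test_flat_curves_give_none(self):
        t = np.linspace(0.1, 1.0, 50)
        assert locate_transitions_canonical({"a": (t, np.ones(50))}) is None


class TestMicroCanonicalConsistency:
    def test_canonical_energy_inverts_beta_micro(self):
        # strictly concave S: at T = 1/S'(E*) the canonical mean energy
        # matches E* within one grid spacing
        e = np.arange(-400, 1)
        s = 60.0 * np.sqrt(e - e.min() + 50.0)
        dos = _dos(e, s)
        curves = micro_curves(dos)
        for idx in (100, 200, 300):
            beta = curves.beta_micro[idx]
            e_star = curves.interior_energies[idx]
            e_mean, _ = canonical_moments(dos, 1.0 / beta)
            assert abs(e_mean - e_star) <= 1.0


def test_canonical_curves_bundle():
    dos = _smooth_50_level()
    obs = EnergyResolvedObservables(n_monomers=5, well_width=1.1, track_contacts=False)
    from samcpoly.observables import _LevelAccumulator

    for e in dos.energies:
        obs._levels[int(e)] = _LevelAccumulator(count=5, rg2_mean=float(5 + 0.1 * e))
    grid = np.linspace(0.1, 2.0, 39)
    c = canonical_curves(dos, grid, obs)
    assert c.ln_z.shape == grid.shape
    assert np.all(c.specific_heat >= 0)
    assert np.all(np.isfinite(c.ln_z))
    # <E> increases with T; the linear-in-E observable tracks it
    assert np.all(np.diff(c.e_mean) > 0)
    assert np.allclose(c.rg2_mean, 5 + 0.1 * c.e_mean, rtol=1e-9)
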