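"""Monte Carlo exposure simulation, dominance, profile comparison."""

import math
import warnings

import numpy as np
import pytest

from sanipath import (PointMassFrequency, SimulationSettings, compare_profiles,
                      dose_per_contact, identify_dominant, simulate_exposure)
from sanipath.bayes import ConcentrationPosterior, FrequencyPosterior
from sanipath.exposure import ExposureError, ExposureProfile


def _freq_post(pairs, pathway="produce", population="adult"):
    arr = np.asarray(pairs, dtype=float)
    return FrequencyPosterior(
        pathway=pathway, population=population, neighborhood="n",
        r=arr[:, 0][None, :], p=arr[:, 1][None, :], n_obs=100,
        accept_rate_r=0.4)


def _conc_post(pairs, pathway="produce"):
    arr = np.asarray(pairs, dtype=float)
    return ConcentrationPosterior(
        pathway=pathway, neighborhood="n",
        mu=arr[:, 0][None, :], sigma=arr[:, 1][None, :],
        n_obs=10, n_censored=0, accept_rate_mu=0.4, accept_rate_sigma=0.4)


def _profile(pathway, pct, dose, population="adult"):
    return ExposureProfile(
        pathway=pathway, population=population, neighborhood="n",
        percent_exposed=pct, percent_exposed_ci=(pct, pct),
        mean_log10_dose=dose, mean_log10_dose_ci=(dose, dose),
        arithmetic_mean_dose=10 ** dose if np.isfinite(dose) else float("nan"),
        n_mc_iterations=1000, dose_defined=np.isfinite(dose))


SIM = SimulationSettings(n_iterations=500, pop_size=500)


class TestDosePerContact:
    def test_identity_intake(self, rng):
        assert dose_per_contact(3.0, 0.0, 1.0, rng)[0] == pytest.approx(3.0)

    def test_half_intake_shifts_by_log10_half(self, rng):
        d = dose_per_contact(3.0, 0.0, 0.5, rng)[0]
        assert d == pytest.approx(3 + math.log10(0.5), abs=1e-12)
        assert d == pytest.approx(2.699, abs=5e-4)

    def test_spread_propagates(self, rng):
        d = dose_per_contact(3.0, 1.0, 1.0, rng, size=10_000)
        assert d.std() == pytest.approx(1.0, abs=0.03)

    def test_invalid_intake(self, rng):
        with pytest.raises(ExposureError):
            dose_per_contact(3.0, 1.0, 0.0, rng)


class TestSimulateExposure:
    def test_point_mass_closed_form_dose(self):
        """Two contacts/month at a fixed 10^3 concentration and unit intake
        give exactly log10(2x10^3) = 3.301 and 100% exposure."""
        prof = simulate_exposure(
            PointMassFrequency(2, pathway="produce", population="adult"),
            _conc_post([(3.0, 0.0)]), intake_amount=1.0,
            settings=SIM, seed=11)
        assert prof.percent_exposed == 100.0
        assert prof.mean_log10_dose == pytest.approx(math.log10(2e3),
                                                     abs=1e-12)
        assert prof.mean_log10_dose == pytest.approx(3.301, abs=5e-4)

    def test_percent_exposed_matches_nb_zero_probability(self):
        """P(exposed) = 1 - p^r; r=1, p=0.4 gives 60%."""
        prof = simulate_exposure(
            _freq_post([(1.0, 0.4)]), _conc_post([(3.0, 1.0)]), 1.0,
            SIM, seed=7)
        se = 100 * math.sqrt(0.6 * 0.4 / (SIM.n_iterations * SIM.pop_size))
        assert abs(prof.percent_exposed - 60.0) < 3 * se + 1e-9

    def test_percent_exposed_matches_posterior_mixture(self):
        draws = [(1.0, 0.3), (2.0, 0.5), (0.5, 0.2)]
        expected = 100 * np.mean([1 - p ** r for r, p in draws])
        prof = simulate_exposure(
            _freq_post(draws), _conc_post([(3.0, 1.0)]), 1.0, SIM, seed=7)
        between = np.var([1 - p ** r for r, p in draws])
        se = 100 * math.sqrt(between / SIM.n_iterations
                             + 0.25 / (SIM.n_iterations * SIM.pop_size))
        assert abs(prof.percent_exposed - expected) < 3 * se

    def test_concentration_shift_moves_dose_not_exposure(self):
        freq = _freq_post([(2.0, 0.3)])
        a = simulate_exposure(freq, _conc_post([(3.0, 1.0)]), 1.0, SIM, seed=3)
        b = simulate_exposure(freq, _conc_post([(4.0, 1.0)]), 1.0, SIM, seed=3)
        assert b.percent_exposed == a.percent_exposed  # same contact stream
        assert b.mean_log10_dose - a.mean_log10_dose == pytest.approx(1.0,
                                                                      abs=0.1)

    def test_seeded_runs_identical(self):
        args = (_freq_post([(1.0, 0.4)]), _conc_post([(3.0, 1.0)]), 1.0, SIM)
        assert simulate_exposure(*args, seed=9) == simulate_exposure(*args,
                                                                     seed=9)

    def test_nobody_exposed_flagged_not_crash(self):
        prof = simulate_exposure(
            PointMassFrequency(0), _conc_post([(3.0, 1.0)]), 1.0, SIM, seed=2)
        assert prof.percent_exposed == 0.0
        assert not prof.dose_defined
        assert math.isnan(prof.mean_log10_dose)

    def test_mc_standard_error_scales_as_inverse_sqrt(self):
        """Across 250/1,000/4,000 iterations the between-run sd of percent
        exposed falls roughly 2x per 4x iterations."""
        freq = _freq_post([(1.0, 0.4)])
        conc = _conc_post([(3.0, 1.0)])
        sds = {}
        for nit in (250, 1000, 4000):
            settings = SimulationSettings(n_iterations=nit, pop_size=200)
            vals = [simulate_exposure(freq, conc, 1.0, settings,
                                      seed=6000 + k).percent_exposed
                    for k in range(24)]
            sds[nit] = np.std(vals, ddof=1)
        assert 1.4 < sds[250] / sds[1000] < 2.9
        assert 1.4 < sds[1000] / sds[4000] < 2.9


class TestDominance:
    def test_within_threshold_of_max(self):
        profiles = [_profile("drain_water", 100, 6.0),
                    _profile("ocean_water", 100, 4.5),
                    _profile("produce", 100, 5.5)]
        res = identify_dominant(profiles, threshold_log10=1.0)
        assert set(res.dominant) == {"drain_water", "produce"}
        assert res.ranked[0] == ("drain_water", pytest.approx(6.0))

    def test_boundary_inclusive(self):
        profiles = [_profile("drain_water", 100, 6.0),
                    _profile("produce", 100, 5.01)]
        res = identify_dominant(profiles)
        assert set(res.dominant) == {"drain_water", "produce"}

    def test_single_pathway_dominates_itself(self):
        res = identify_dominant([_profile("produce", 80, 5.0)])
        assert res.dominant == ("produce",)

    def test_percent_exposed_enters_ranking(self):
        # equal doses: 10% exposed trails 100% exposed by 1 log10 exactly
        profiles = [_profile("produce", 100, 5.0),
                    _profile("drain_water", 10, 5.0)]
        res = identify_dominant(profiles, threshold_log10=0.5)
        assert res.dominant == ("produce",)

    def test_all_unexposed_warns_empty(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            res = identify_dominant([_profile("produce", 0, float("nan"))])
        assert res.dominant == ()
        assert any("exposed" in str(x.message) for x in w)


class TestComparison:
    def test_identical_profiles_zero_difference(self):
        a = _profile("produce", 80, 5.94)
        d = compare_profiles(a, a)
        assert d.d_percent_exposed == 0 and d.d_mean_log10_dose == 0

    def test_validation_style_difference(self):
        a = _profile("produce", 80, 5.94)
        b = _profile("produce", 70, 5.40)
        d = compare_profiles(a, b)
        assert d.d_percent_exposed == pytest.approx(10.0)
        assert d.d_mean_log10_dose == pytest.approx(0.54)

    def test_mismatched_profiles_rejected(self):
        with pytest.raises(ExposureError):
            compare_profiles(_profile("produce", 80, 5.9),
                             _profile("drain_water", 80, 5.9))
        with pytest.raises(ExposureError):
            compare_profiles(_profile("produce", 80, 5.9),
                             _profile("produce", 80, 5.9, population="child"))
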