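"""Synthetic deployment generator: determinism, encoding consistency,
plating-noise model, end-to-end parameter recovery."""

import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from sanipath import (GroundTruth, McmcSettings, PathwayTruth, PriorSpec,
                      decoding_bias, effective_monthly_mean, fit_concentration,
                      fit_frequency, generate_deployment, generate_samples,
                      generate_surveys, parse_samples_csv,
                      parse_survey_csv, tabulate_frequencies)
from sanipath.microbiology import estimate_concentrations
from sanipath.synthetic import _assay_series


def _truth(pathways, **kw):
    return GroundTruth(pathways=pathways, **kw)


def _produce_truth(r=2.0, p=0.3, mu=4.0, sigma=1.0, **kw):
    return _truth({"produce": PathwayTruth(
        {"adult": (r, p), "child": (r, p)}, mu=mu, sigma=sigma)}, **kw)


class TestDeterminism:
    def test_same_seed_identical_bytes(self, config):
        truth = _produce_truth(n_households=20)
        assert generate_surveys(truth, config, 42) == \
            generate_surveys(truth, config, 42)
        assert generate_samples(truth, config, 42) == \
            generate_samples(truth, config, 42)

    def test_different_seeds_differ_same_schema(self, config):
        truth = _produce_truth(n_households=20)
        a = generate_deployment(truth, config, 1)
        b = generate_deployment(truth, config, 2)
        assert a.survey_csv != b.survey_csv
        assert a.survey_csv.splitlines()[0] == b.survey_csv.splitlines()[0]
        assert a.samples_csv.splitlines()[0] == b.samples_csv.splitlines()[0]

    def test_truth_echo_round_trips(self):
        truth = _produce_truth()
        again = GroundTruth.from_json(truth.to_json())
        assert again == truth
        assert json.loads(truth.to_json())["n_households"] == 100


class TestSurveyGeneration:
    def test_near_zero_mean_gives_never_answers(self, config):
        truth = _produce_truth(r=0.5, p=0.99, n_households=200,
                               n_school_surveys=0, n_community_surveys=0)
        csv = generate_surveys(truth, config, 3)
        rows = csv.splitlines()[1:]
        nevers = sum(row.split(",")[3] == "never" for row in rows)
        assert nevers / len(rows) >= 0.95

    def test_recommended_battery_size(self, config):
        truth = _produce_truth()
        rows = generate_surveys(truth, config, 3).splitlines()[1:]
        # 100 household + 4 school and 4 community groups of 17
        assert len(rows) == 100 + 8 * 17
        types = {row.split(",")[1] for row in rows}
        assert types == {"household", "school", "community"}

    def test_decoded_mean_tracks_nb_mean(self, tmp_path, config):
        """Encoding to categories and decoding to midpoints preserves the
        NB(2, 0.3) mean within 10%: the analytic decoded expectation sits
        inside that band, and the n=10,000 empirical mean matches the
        analytic expectation within sampling error."""
        r, p = 2.0, 0.3
        true_mean = r * (1 - p) / p
        # independent oracle: expected decoded midpoint via the NB pmf
        k = np.arange(int(stats.nbinom.ppf(1 - 1e-10, r, p)) + 1)
        pmf = stats.nbinom.pmf(k, r, p)
        decoded = np.array([config.category_map.monthly_count(
            config.category_map.encode(int(c))) for c in k])
        expected = float(pmf @ decoded)
        assert expected == pytest.approx(true_mean, rel=0.10)

        truth = _produce_truth(n_households=10_000, n_school_surveys=0,
                               n_community_surveys=0)
        path = tmp_path / "s.csv"
        path.write_text(generate_surveys(truth, config, 8))
        res = parse_survey_csv(path, config)
        counts = np.array(tabulate_frequencies(res.records, "produce",
                                               "adult", config))
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert counts.mean() == pytest.approx(expected, abs=4 * se)

    def test_decoding_bias_bounded_by_category_width(self, config):
        # widest gap between adjacent category values is 30 - 17.3 = 12.7
        truth = PathwayTruth({"adult": (2.0, 0.3)}, mu=4, sigma=1)
        assert abs(decoding_bias(truth, "adult", config)) <= 12.7 / 2


class TestSampleGeneration:
    def test_poisson_count_means_match_plating_model(self, config):
        """Mean counts at each assay step equal 10^c x amount x dilution /
        denominator scale."""
        truth = _produce_truth(mu=5.0, sigma=1e-6, n_samples_per_pathway=200)
        # per_serving scale is 100
        csv = generate_samples(truth, config, 12)
        by_step = {}
        for line in csv.splitlines()[1:]:
            parts = line.split(",")
            d, amt, count = float(parts[4]), float(parts[5]), parts[6]
            if count != "TNTC":
                by_step.setdefault((amt, d), []).append(float(count))
        assert by_step
        for (amt, d), counts in by_step.items():
            lam = 10 ** 5.0 * amt * d / 100.0
            if lam > 150:
                continue  # step truncated by the TNTC rule
            se = np.sqrt(lam / len(counts))
            assert np.mean(counts) == pytest.approx(lam, abs=4 * se + 1e-9)

    def test_assay_series_spans_two_to_three_tenfold_steps(self):
        for mu, scale in [(1.5, 100.0), (4.0, 100.0), (6.5, 100.0),
                          (5.0, 1.0), (3.0, 1.0)]:
            series = _assay_series(mu, scale)
            assert 2 <= len(series) <= 3
            for amount, dilution in series:
                assert 0 < dilution <= 1
                assert 0 < amount <= 100

    def test_concentration_round_trip_unbiased(self, config):
        """With sigma ~ 0, the dilution pipeline recovers mu within Poisson
        noise (bias < 0.1 log10 at n=100)."""
        truth = _produce_truth(mu=4.0, sigma=1e-6, n_samples_per_pathway=100)
        import tempfile
        with tempfile.TemporaryDirectory() as td:
            paths = generate_deployment(truth, config, 21).write(td)
            ests = estimate_concentrations(
                parse_samples_csv(paths["samples"], config), config)
        observed = [e.log10_concentration for e in ests
                    if e.censoring == "observed"]
        assert len(observed) >= 90
        assert abs(np.mean(observed) - 4.0) < 0.1


class TestDeploymentComposition:
    def test_files_parse_cleanly(self, tmp_path, config):
        truth = _produce_truth(n_households=30)
        paths = generate_deployment(truth, config, 5).write(tmp_path)
        res = parse_survey_csv(paths["surveys"], config)
        assert not res.rejects
        samples = parse_samples_csv(paths["samples"], config)
        assert len(samples) == truth.n_samples_per_pathway
        ests = estimate_concentrations(samples, config)
        assert len(ests) == len(samples)


class TestEndToEndRecovery:
    def test_pipeline_recovers_truth_within_credible_intervals(self, config):
        """Over 100 seeded replicates of a default-size deployment (100
        surveys, 10 samples), the 95% intervals for the identified contact
        mean and for (mu, sigma) each cover their target in >=90% of runs."""
        truth = _produce_truth(n_households=100, n_school_surveys=0,
                               n_community_surveys=0)
        target_m = effective_monthly_mean(truth.pathways["produce"], "adult",
                                          config)
        mcmc = McmcSettings(chains=1, iterations=1500, burn_in=500, seed=2)
        hits_m = hits_mu = hits_sigma = 0
        n_rep = 100
        import tempfile
        for rep in range(n_rep):
            with tempfile.TemporaryDirectory() as td:
                paths = generate_deployment(truth, config, 7000 + rep).write(td)
                res = parse_survey_csv(paths["surveys"], config)
                counts = tabulate_frequencies(res.records, "produce", "adult",
                                              config)
                fpost = fit_frequency(counts, PriorSpec(),
                                      dataclasses.replace(mcmc, seed=rep))
                ests = estimate_concentrations(
                    parse_samples_csv(paths["samples"], config), config)
                cpost = fit_concentration(ests, PriorSpec(),
                                          dataclasses.replace(mcmc, seed=rep))
            lo, hi = np.percentile(fpost.mean_contacts, [2.5, 97.5])
            hits_m += lo <= target_m <= hi
            lo, hi = np.percentile(cpost.mu.ravel(), [2.5, 97.5])
            hits_mu += lo <= 4.0 <= hi
            lo, hi = np.percentile(cpost.sigma.ravel(), [2.5, 97.5])
            hits_sigma += lo <= 1.0 <= hi
        assert hits_m / n_rep >= 0.90
        assert hits_mu / n_rep >= 0.90
        assert hits_sigma / n_rep >= 0.90
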