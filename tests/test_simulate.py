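"""Calibration solvers and the synthetic cohort generator."""

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from bdrprs.genotypes import read_dosages
from bdrprs.phenotypes import read_cohort_csv
from bdrprs.prs import compute_prs, standardize
from bdrprs.simulate import (
    BDR_MEAN,
    BDR_SD,
    P_GE_8,
    P_GE_12,
    CalibrationError,
    MixtureParams,
    SimulationConfig,
    calibrate_allele_freqs,
    calibrate_bdr_noise,
    generate_cohort,
    simulate_bdr,
    simulate_covariates,
    simulate_cohort,
    simulate_genotypes,
    solve_logistic_intercept,
    _marginal_moments_and_tails,
)
from bdrprs.weights import VariantRecord, WeightTable
from conftest import reseeded


class TestAlleleFreqCalibration:
    def test_single_variant_closed_form(self):
        # one variant, beta 2: mean = 4p, so mean 2 => p = 0.5 (SD then sqrt(2))
        w = WeightTable([VariantRecord("1", 1, "rs1", "A", 2.0)])
        p = calibrate_allele_freqs(w, target_mean=2.0, target_sd=float(np.sqrt(2.0)))
        assert p[0] == pytest.approx(0.5, abs=1e-6)

    def test_published_moments_reproduced(self, table16):
        p = calibrate_allele_freqs(table16)
        betas = np.array([r.beta for r in table16])
        assert 2 * (p * betas).sum() == pytest.approx(3.84, abs=1e-6)
        assert 2 * (p * (1 - p) * betas**2).sum() == pytest.approx(7.41**2, abs=1e-6)
        assert np.all((p >= 0.01) & (p <= 0.99))

    def test_deterministic(self, table16):
        np.testing.assert_array_equal(
            calibrate_allele_freqs(table16), calibrate_allele_freqs(table16)
        )

    def test_infeasible_mean_reports_range(self, table16):
        with pytest.raises(CalibrationError, match="feasible range"):
            calibrate_allele_freqs(table16, target_mean=100.0)

    def test_infeasible_variance_rejected(self, table16):
        with pytest.raises(CalibrationError, match="variance"):
            calibrate_allele_freqs(table16, target_mean=3.84, target_sd=50.0)


class TestBdrNoiseCalibration:
    def test_self_consistency_with_single_normal_targets(self):
        # targets computed from one N(5.6, 10.2^2), zero PRS effect: the
        # fitted mixture must match all four functionals (components may coincide)
        mean, sd = 5.6, 10.2
        t12 = float(stats.norm.sf(12, mean, sd))
        t8 = float(stats.norm.sf(8, mean, sd))
        mx = calibrate_bdr_noise(mean, sd, t12, t8, effect_per_sd=0.0)
        got = _marginal_moments_and_tails(
            np.array([mx.weight_1, mx.mu_1, mx.sigma_1, mx.mu_2, mx.sigma_2]), 0.0
        )
        np.testing.assert_allclose(got, [mean, sd, t12, t8], rtol=2e-6, atol=2e-6)

    def test_published_targets_feasible(self, continuous_config):
        mx = continuous_config.noise
        got = _marginal_moments_and_tails(
            np.array([mx.weight_1, mx.mu_1, mx.sigma_1, mx.mu_2, mx.sigma_2]), 0.63
        )
        np.testing.assert_allclose(got, [BDR_MEAN, BDR_SD, P_GE_12, P_GE_8], rtol=1e-5)

    def test_inverted_tail_targets_rejected(self):
        with pytest.raises(CalibrationError, match="p_ge_12 < p_ge_8"):
            calibrate_bdr_noise(5.6, 10.2, 0.4, 0.3)

    def test_invalid_mixture_params_rejected(self):
        with pytest.raises(CalibrationError):
            MixtureParams(1.5, 0, 1, 0, 1)
        with pytest.raises(CalibrationError):
            MixtureParams(0.5, 0, -1, 0, 1)


class TestSimulateGenotypes:
    def test_degenerate_frequencies(self):
        m0 = simulate_genotypes(np.array([0.0]), 50, seed=1)
        assert np.all(m0.dosages == 0)
        m1 = simulate_genotypes(np.array([1.0]), 50, seed=1)
        assert np.all(m1.dosages == 2)

    def test_hwe_genotype_class_proportions(self):
        n, p = 100_000, 0.3
        m = simulate_genotypes(np.array([p]), n, seed=2)
        counts = np.bincount(m.dosages[:, 0].astype(int), minlength=3)
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 0.001

    def test_seed_reproducibility(self):
        a = simulate_genotypes(np.array([0.3, 0.7]), 100, seed=3)
        b = simulate_genotypes(np.array([0.3, 0.7]), 100, seed=3)
        np.testing.assert_array_equal(a.dosages, b.dosages)


@pytest.fixture(scope="module")
def big():
    return simulate_covariates(100_000, seed=4)


class TestSimulateCovariates:
    def test_male_fraction(self, big):
        n = len(big)
        se = np.sqrt(0.59 * 0.41 / n)
        assert abs((big["sex"] == "male").mean() - 0.59) < 3 * se

    def test_obese_fraction(self, big):
        n = len(big)
        se = np.sqrt(0.17 * 0.83 / n)
        assert abs((big["bmi_category"] == "obese").mean() - 0.17) < 3 * se

    def test_age_bounds_and_center(self, big):
        assert big["age_years"].between(6, 14).all()
        # truncating N(9.3, 1.9) to [6, 14] shifts the mean; compare with
        # the analytic truncated-normal mean
        a, b = (6 - 9.3) / 1.9, (14 - 9.3) / 1.9
        expected = stats.truncnorm.mean(a, b, loc=9.3, scale=1.9)
        se = stats.truncnorm.std(a, b, loc=9.3, scale=1.9) / np.sqrt(len(big))
        assert abs(big["age_years"].mean() - expected) < 3 * se

    def test_visit_quartiles(self, big):
        q1, med, q3 = big["doctor_visits"].quantile([0.25, 0.5, 0.75])
        assert (q1, med, q3) == (1, 3, 5)

    def test_pcs_standard_normal(self, big):
        assert abs(big["PC1"].mean()) < 0.02
        assert big["PC3"].std() == pytest.approx(1.0, abs=0.02)


class TestSimulateBdr:
    def test_null_effect_gives_uncorrelated_outcome(self, continuous_config):
        cfg = dataclasses.replace(continuous_config, effect_per_sd=0.0, n=100_000)
        rng = np.random.default_rng(5)
        z = rng.standard_normal(cfg.n)
        z = (z - z.mean()) / z.std(ddof=1)
        bdr = simulate_bdr(z, cfg, seed=6)
        r = np.corrcoef(bdr, z)[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n)

    def test_threshold_mode_hits_marginal_prevalence(self, threshold12_config):
        cfg = dataclasses.replace(threshold12_config, n=100_000)
        rng = np.random.default_rng(7)
        z = rng.standard_normal(cfg.n)
        z = (z - z.mean()) / z.std(ddof=1)
        y = simulate_bdr(z, cfg, seed=8)
        se = np.sqrt(P_GE_12 * (1 - P_GE_12) / cfg.n)
        assert abs(y.mean() - P_GE_12) < 3 * se

    def test_same_seed_identical(self, continuous_config):
        z = np.linspace(-2, 2, 100)
        a = simulate_bdr(z, continuous_config, seed=9)
        b = simulate_bdr(z, continuous_config, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_uncalibrated_noise_rejected(self, table16):
        cfg = SimulationConfig(n=10, weights=table16)
        with pytest.raises(CalibrationError, match="noise"):
            simulate_bdr(np.zeros(10), cfg, seed=0)

    def test_intercept_solver_matches_quadrature_target(self):
        alpha = solve_logistic_intercept(0.8, P_GE_12)
        z = np.random.default_rng(10).standard_normal(2_000_000)
        from scipy.special import expit

        assert expit(alpha + np.log(0.8) * z).mean() == pytest.approx(P_GE_12, abs=1e-3)


def _dir_digest(d: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(d).iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestGenerateCohort:
    def test_files_round_trip_and_truth(self, tmp_path, continuous_config):
        cfg = reseeded(continuous_config, 11)
        cfg = dataclasses.replace(cfg, n=150)
        paths = generate_cohort(cfg, tmp_path / "c")
        matrix, cohort, truth = simulate_cohort(cfg)

        back = read_dosages(paths["vcf"], cfg.weights)
        # same variants, possibly different column order (VCF is position-sorted)
        idx = [matrix.variant_ids.index(v) for v in back.variant_ids]
        np.testing.assert_array_equal(back.dosages, matrix.dosages[:, idx])
        assert back.sample_ids == matrix.sample_ids

        pheno = read_cohort_csv(paths["phenotypes"])
        assert len(pheno) == 150
        np.testing.assert_allclose(pheno.bdr_percent, cohort.bdr_percent, atol=1e-9)

        recorded = json.loads(paths["truth"].read_text())
        assert recorded["seed"] == 11
        assert recorded["effect_per_sd"] == cfg.effect_per_sd
        assert len(recorded["allele_freqs"]) == 16

    def test_byte_identical_reruns(self, tmp_path, continuous_config):
        cfg = dataclasses.replace(reseeded(continuous_config, 12), n=80)
        generate_cohort(cfg, tmp_path / "a")
        generate_cohort(cfg, tmp_path / "b")
        assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")

    def test_threshold_mode_writes_responder(self, tmp_path, threshold12_config):
        cfg = dataclasses.replace(reseeded(threshold12_config, 13), n=80)
        paths = generate_cohort(cfg, tmp_path / "t")
        pheno = read_cohort_csv(paths["phenotypes"])
        assert set(pheno.data["responder"]) <= {0, 1}


def test_simulated_prs_moments_match_closed_form(continuous_config):
    """Raw-PRS mean and SD at n = 100000 agree with the HWE closed forms
    (and hence the published 3.84 / 7.41 targets) within 3 MC SEs."""
    cfg = dataclasses.replace(reseeded(continuous_config, 14), n=100_000)
    matrix, _, _ = simulate_cohort(cfg)
    raw = compute_prs(matrix, cfg.weights).raw_score
    n = cfg.n
    se_mean = 7.41 / np.sqrt(n)
    assert abs(raw.mean() - 3.84) < 3 * se_mean
    m2 = raw.var(ddof=1)
    m4 = ((raw - raw.mean()) ** 4).mean()
    se_sd = np.sqrt((m4 - m2**2) / n) / (2 * np.sqrt(m2))
    assert abs(raw.std(ddof=1) - 7.41) < 3 * se_sd
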