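"""Synthetic cohort generator: determinism, truth structure, error models."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from tesomatic import CohortConfig, ConfigError, error_free, simulate_cohort


class TestConfigValidation:
    def test_non_positive_chromosome_length(self):
        with pytest.raises(ConfigError):
            CohortConfig(genome=(("chr1", 0),))

    def test_empty_family_set(self):
        with pytest.raises(ConfigError):
            CohortConfig(families=(), family_weights=())

    def test_probabilities_bounded(self):
        with pytest.raises(ConfigError):
            CohortConfig(caller_fn_rate=1.5)
        with pytest.raises(ConfigError):
            CohortConfig(caller_fp_rate=-0.1)

    def test_multiplier_at_least_one(self):
        with pytest.raises(ConfigError):
            CohortConfig(tumor_l1_multiplier=0.5)

    def test_genome_too_small_for_loci(self):
        with pytest.raises(ConfigError, match="too small"):
            simulate_cohort(CohortConfig(genome=(("chr1", 10_000),), n_germline_loci=500))


class TestDeterminismAndStructure:
    def test_same_seed_identical_output(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        assert a.truth == b.truth
        assert a.calls == b.calls
        assert a.panel == b.panel
        for key in a.expression:
            assert a.expression[key].equals(b.expression[key])

    def test_different_seed_different_output(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(dataclasses.replace(small_config, seed=small_config.seed + 1))
        assert a.truth != b.truth

    def test_carrier_invariants(self, small_config):
        cohort = simulate_cohort(small_config)
        for rec in cohort.truth:
            if rec.origin == "germline":
                patients = {p for p, _ in rec.carriers}
                assert set(rec.carriers) == {(p, t) for p in patients for t in ("normal", "tumor")}
                assert rec.panel_af is not None
            else:
                assert len(rec.carriers) == 1
                assert rec.panel_af is None

    def test_minimum_truth_spacing(self, small_config):
        cohort = simulate_cohort(small_config)
        by_chrom = {}
        for rec in cohort.truth:
            by_chrom.setdefault(rec.chrom, []).append(rec.pos)
        for positions in by_chrom.values():
            positions.sort()
            gaps = np.diff(positions)
            assert (gaps >= small_config.min_spacing).all()

    def test_panel_contains_exactly_germline_plus_extras(self, small_config):
        cohort = simulate_cohort(small_config)
        germline = {(t.chrom, t.pos, t.family) for t in cohort.truth if t.origin == "germline"}
        panel = {(e.chrom, e.pos, e.family) for e in cohort.panel}
        assert germline <= panel
        assert len(panel) == small_config.n_germline_loci + small_config.n_panel_extra
        somatic = {(t.chrom, t.pos, t.family) for t in cohort.truth if t.origin == "somatic"}
        assert not (somatic & panel)


class TestObservationModel:
    def test_zero_somatic_and_fp_rates_give_germline_only_calls(self, small_config):
        cfg = dataclasses.replace(
            small_config, somatic_rate_normal=0.0, somatic_rate_tumor=0.0,
            caller_fp_rate=0.0, caller_fn_rate=0.0, caller_jitter_sd=0.0,
        )
        cohort = simulate_cohort(cfg)
        germline = {(t.chrom, t.pos, t.family) for t in cohort.truth if t.origin == "germline"}
        assert {(c.chrom, c.pos, c.family) for c in cohort.calls} <= germline
        # identical between tissues of each carrier patient
        for patient in cfg.patient_ids:
            for caller in cfg.callers:
                n = {(c.chrom, c.pos) for c in cohort.calls_for(patient, "normal", caller)}
                t = {(c.chrom, c.pos) for c in cohort.calls_for(patient, "tumor", caller)}
                assert n == t

    def test_error_free_calls_equal_truth_per_caller(self, small_config):
        cohort = simulate_cohort(error_free(small_config))
        cfg = cohort.config
        for patient in cfg.patient_ids:
            for tissue in cfg.tissues:
                carried = {
                    (t.chrom, t.pos, t.family)
                    for t in cohort.truth
                    if (patient, tissue) in t.carriers
                }
                for caller in cfg.callers:
                    observed = {
                        (c.chrom, c.pos, c.family)
                        for c in cohort.calls_for(patient, tissue, caller)
                    }
                    assert observed == carried

    def test_jitter_bounded_by_merge_window(self, small_config):
        cohort = simulate_cohort(dataclasses.replace(small_config, caller_jitter_sd=80.0))
        truth_pos = sorted((t.chrom, t.pos) for t in cohort.truth)
        positions = {}
        for chrom, pos in truth_pos:
            positions.setdefault(chrom, []).append(pos)
        for c in cohort.calls:
            arr = positions[c.chrom]
            k = int(np.searchsorted(arr, c.pos))
            d = min(
                abs(arr[i] - c.pos) for i in (k - 1, k) if 0 <= i < len(arr)
            )
            # either a jittered true call (<= window) or a FP far from truth
            assert d <= small_config.merge_window or d >= small_config.min_spacing

    def test_panel_af_distribution_matches_beta(self):
        """KS goodness-of-fit for the configured Beta is not rejected."""
        cfg = CohortConfig(n_germline_loci=1500, seed=77)
        cohort = simulate_cohort(cfg)
        afs = [t.panel_af for t in cohort.truth if t.origin == "germline"]
        a, b = cfg.germline_af_beta
        res = stats.kstest(afs, stats.beta(a, b).cdf)
        assert res.pvalue > 0.01

    def test_tumor_l1_excess_matches_configured_multiplier(self):
        """Truth-level tumor/normal somatic L1 ratio is near the multiplier."""
        cfg = CohortConfig(seed=123, somatic_rate_normal=20.0, somatic_rate_tumor=20.0)
        cohort = simulate_cohort(cfg)
        l1n = sum(
            1 for t in cohort.truth
            if t.origin == "somatic" and t.family == "L1" and t.carriers[0][1] == "normal"
        )
        l1t = sum(
            1 for t in cohort.truth
            if t.origin == "somatic" and t.family == "L1" and t.carriers[0][1] == "tumor"
        )
        # tumor count ~ Poisson(2 * lambda_n); compare within 3 sd of expectation
        lam_n = cfg.somatic_rate_normal * cfg.n_patients
        lam_t = lam_n * cfg.tumor_l1_multiplier
        assert abs(l1n - lam_n) <= 3 * np.sqrt(lam_n)
        assert abs(l1t - lam_t) <= 3 * np.sqrt(lam_t)

    def test_noise_component_mass_below_threshold(self, small_config):
        """Most FP support counts fall under the 5-read cutoff, real ones above."""
        cfg = dataclasses.replace(small_config, caller_fp_rate=0.3)
        cohort = simulate_cohort(cfg)
        truth_keys = {(t.chrom, t.pos) for t in cohort.truth}
        fp_supports, real_supports = [], []
        for c in cohort.calls:
            near_truth = any(
                (c.chrom, c.pos + d) in truth_keys
                for d in range(-cfg.merge_window, cfg.merge_window + 1)
            )
            (real_supports if near_truth else fp_supports).append(c.support_reads)
        assert len(fp_supports) > 30
        frac_low = np.mean([s < 5 for s in fp_supports])
        expected_low = stats.poisson(cfg.support.noise_mean).cdf(4)
        assert frac_low == pytest.approx(expected_low, abs=0.1)
        assert np.mean([s >= 5 for s in real_supports]) > 0.95
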