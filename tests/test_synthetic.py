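"""Synthetic campaign generator: determinism, class structure, trendline
recovery, noise calibration and end-to-end pipeline recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ccslib.ccs_core import fit_single_field
from ccslib.curation import fit_trendline, percent_difference
from ccslib.pipeline import curate
from ccslib.synthetic import (
    DEFAULT_TUNE_MIX,
    SimConfig,
    generate_registry,
    generate_tune_mix,
    simulate_campaign,
    simulate_runs,
    simulate_truth,
)


class TestGenerateRegistry:
    def test_fixed_seed_is_reproducible(self):
        cfg = SimConfig(n_chemicals=100, seed=5)
        assert generate_registry(cfg) == generate_registry(cfg)

    def test_different_seeds_differ(self):
        a = generate_registry(SimConfig(n_chemicals=100, seed=1))
        b = generate_registry(SimConfig(n_chemicals=100, seed=2))
        assert a != b

    def test_pah_only_weights_give_hydrocarbons(self):
        cfg = SimConfig(
            n_chemicals=50,
            seed=9,
            class_weights={"PAH": 1.0},
        )
        for rec in generate_registry(cfg):
            assert rec.chem_class == "PAH"
            assert set(rec.formula) == {"C", "H"}

    def test_pfas_formulas_carry_fluorine(self):
        cfg = SimConfig(n_chemicals=50, seed=9, class_weights={"PFAS": 1.0})
        for rec in generate_registry(cfg):
            assert rec.formula.get("F", 0) >= 9

    def test_class_fractions_match_weights_at_large_n(self):
        cfg = SimConfig(n_chemicals=10000, seed=13)
        registry = generate_registry(cfg)
        total_w = sum(cfg.class_weights.values())
        counts: dict[str, int] = {}
        for rec in registry:
            counts[rec.chem_class] = counts.get(rec.chem_class, 0) + 1
        for cls, w in cfg.class_weights.items():
            assert counts.get(cls, 0) / cfg.n_chemicals == pytest.approx(
                w / total_w, abs=0.02
            )

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chemicals=10, class_weights={"PAH": -1.0})


class TestSimulateTruth:
    def test_zero_scatter_lies_exactly_on_trendlines(self):
        cfg = SimConfig(n_chemicals=200, seed=4, trendline_scatter_pct=0.0)
        truth = simulate_truth(generate_registry(cfg), cfg)
        assert truth
        for ion in truth:
            a, b = cfg.trendline_truth[ion.ion_type]
            assert ion.ccs == pytest.approx(a * ion.mz**b, rel=1e-12)

    def test_trendline_parameters_recovered_from_scattered_truth(self):
        cfg = SimConfig(n_chemicals=1000, seed=21, trendline_scatter_pct=3.0)
        truth = simulate_truth(generate_registry(cfg), cfg)
        pts = [(t.mz, t.ccs) for t in truth if t.ion_type == "[M+H]+"]
        assert len(pts) > 200
        model = fit_trendline(pts)
        a, b = cfg.trendline_truth["[M+H]+"]
        assert abs(model.b - b) <= 0.02
        assert model.a == pytest.approx(a, rel=0.10)

    def test_zero_probability_class_mode_has_no_truth(self):
        cfg = SimConfig(
            n_chemicals=200,
            seed=4,
            class_weights={"PAH": 1.0},
            detection_probs={"PAH": {"ESI+": 0.0, "ESI-": 0.0, "APCI+": 0.8}},
        )
        truth = simulate_truth(generate_registry(cfg), cfg)
        assert truth and all(t.mode == "APCI+" for t in truth)


class TestSimulateRuns:
    def test_noiseless_campaign_round_trips_exactly(self):
        cfg = SimConfig(
            n_chemicals=150,
            seed=6,
            replicate_cv_pct=0.0,
            apci_replicate_cv_pct=0.0,
            multimer_rate=0.0,
            mz_noise_ppm=0.0,
            m1_noise_rel=0.0,
        )
        registry, truth, features, manifest, cal = simulate_campaign(cfg)
        assert manifest == []
        result = curate(registry, features, cal)
        assert result.report.retained == len(truth)
        truth_ccs = {(t.chem_id, t.ion_type, t.mode): t.ccs for t in truth}
        for e in result.entries:
            # entries report CCS to 2 decimals; recovery is exact before rounding
            assert e.ccs == pytest.approx(
                truth_ccs[(e.chem_id, e.ion_type, e.mode)], abs=0.0051
            )

    def test_artifacts_fully_separable_at_40pct_inflation(self):
        cfg = SimConfig(n_chemicals=800, seed=17, multimer_rate=0.05)
        registry, truth, features, manifest, cal = simulate_campaign(cfg)
        assert manifest
        result = curate(registry, features, cal)
        artifact_keys = {(m["chem_id"], m["ion_type"], m["mode"]) for m in manifest}
        library_keys = {(e.chem_id, e.ion_type, e.mode) for e in result.entries}
        # no artifact survives into the library
        assert artifact_keys & library_keys == set()
        # every trendline rejection is an artifact (precision 1.0) and every
        # artifact that reached the trendline stage was rejected (recall 1.0)
        tl_rejected = {
            (d.chem_id, d.ion_type.label, d.mode)
            for d in result.detections
            if d.status == "trendline_outlier"
        }
        reached = {
            (d.chem_id, d.ion_type.label, d.mode)
            for d in result.detections
            if d.status in ("retained", "trendline_outlier")
        }
        assert tl_rejected == artifact_keys & reached

    def test_replicate_gate_failure_matches_monte_carlo_oracle(self):
        """At 0.6% replicate CV the observed 1%-gate failure fraction matches
        a Monte-Carlo oracle within 2 percentage points."""
        cv = 0.6
        cfg = SimConfig(
            n_chemicals=3000,
            seed=23,
            replicate_cv_pct=cv,
            apci_replicate_cv_pct=cv,
            multimer_rate=0.0,
        )
        registry, truth, features, manifest, cal = simulate_campaign(cfg)
        result = curate(registry, features, cal)
        pairs = [d for d in result.detections if len(d.replicate_ccs) == 2]
        observed_fail = sum(
            1 for d in pairs if percent_difference(d.replicate_ccs) > 1.0
        ) / len(pairs)
        rng = np.random.default_rng(99)
        sims = 1.0 + rng.normal(0.0, cv / 100.0, size=(10000, 2))
        oracle_fail = float(
            np.mean(
                100.0 * np.abs(sims[:, 0] - sims[:, 1]) / sims.mean(axis=1) > 1.0
            )
        )
        assert observed_fail == pytest.approx(oracle_fail, abs=0.02)

    def test_feature_schema(self, small_campaign):
        features = small_campaign["features"]
        assert list(features.columns) == [
            "chem_id",
            "mode",
            "replicate_index",
            "observed_mz",
            "observed_m1_ratio",
            "t_A_ms",
        ]
        assert set(features["replicate_index"]) == {1, 2}


class TestGenerateTuneMix:
    def test_zero_noise_recovers_calibration_exactly(self):
        calibrants = generate_tune_mix((0.21, 0.20))
        fit = fit_single_field(calibrants)
        assert fit.beta == pytest.approx(0.21, rel=1e-10)
        assert fit.t_fix == pytest.approx(0.20, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_seeded_noise_reproducible_and_good_fit(self):
        a = generate_tune_mix((0.21, 0.20), noise_ms=0.005, seed=2)
        b = generate_tune_mix((0.21, 0.20), noise_ms=0.005, seed=2)
        assert a == b
        ten_ions = [
            (mz, ccs)
            for mz, ccs in list(DEFAULT_TUNE_MIX)
            + [(200.0, 135.0), (450.0, 175.0), (750.0, 220.0), (1100.0, 268.0)]
        ]
        fit = fit_single_field(
            generate_tune_mix((0.21, 0.20), ten_ions, noise_ms=0.005, seed=2)
        )
        assert fit.r_squared > 0.999

    def test_requires_two_ions(self):
        with pytest.raises(ValueError):
            generate_tune_mix((0.21, 0.20), [(322.0, 153.7)])


def test_end_to_end_determinism():
    """(config, seed) fully determines registry, truth, features, manifest."""
    cfg = SimConfig(n_chemicals=120, seed=31)
    r1, t1, f1, m1, c1 = simulate_campaign(cfg)
    r2, t2, f2, m2, c2 = simulate_campaign(cfg)
    assert r1 == r2 and t1 == t2 and m1 == m2 and c1 == c2
    pd.testing.assert_frame_equal(f1, f2)
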