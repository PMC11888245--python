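"""Ion detection gating, replicate reproducibility, trendline filtering and
library assembly."""

import numpy as np
import pytest

from ccslib.chem_ions import parse_formula, theoretical_ion
from ccslib.curation import (
    ChemicalRecord,
    CurationThresholds,
    IonDetection,
    ReplicateFeature,
    assemble_library,
    classify_candidate,
    detect_ion,
    fit_trendline,
    percent_difference,
    replicate_qc,
    trendline_filter,
)

THEO = theoretical_ion("C10H7N3S", "[M+H]+")  # mz ~ 202.0433


def _feature(mz, m1=None, ccs=150.0, rep=1):
    return ReplicateFeature(
        chem_id="X1",
        mode="ESI+",
        replicate_index=rep,
        observed_mz=mz,
        observed_m1_ratio=THEO.m1_ratio if m1 is None else m1,
        ccs=ccs,
    )


class TestDetectIon:
    def test_detection_inside_both_gates(self):
        observed = THEO.mz * (1 + 8.41e-6)  # +8.41 ppm, inside the 10 ppm gate
        d = detect_ion([_feature(observed, rep=1), _feature(observed, rep=2)], THEO)
        assert d is not None
        assert d.ppm == pytest.approx(8.41, abs=0.01)
        assert d.isotope_ok
        assert len(d.replicate_ccs) == 2

    def test_mass_error_beyond_10ppm_is_absent(self):
        off = THEO.mz * (1 + 25e-6)
        assert detect_ion([_feature(off)], THEO) is None

    def test_boundary_exactly_10ppm_fails_strict_gate(self):
        at_gate = THEO.mz * (1 + 10e-6)
        assert detect_ion([_feature(at_gate)], THEO) is None

    def test_wrong_isotope_pattern_is_absent(self):
        d = detect_ion([_feature(THEO.mz, m1=3 * THEO.m1_ratio)], THEO)
        assert d is None

    def test_rejection_reasons_classified(self):
        far = classify_candidate([_feature(THEO.mz * (1 + 25e-6))], THEO)
        assert far.status == "no_mz_match"
        iso = classify_candidate([_feature(THEO.mz, m1=3 * THEO.m1_ratio)], THEO)
        assert iso.status == "isotope_fail"

    def test_mixed_chemicals_rejected(self):
        f1 = _feature(THEO.mz)
        f2 = ReplicateFeature("X2", "ESI+", 1, THEO.mz, THEO.m1_ratio, ccs=150.0)
        with pytest.raises(ValueError):
            detect_ion([f1, f2], THEO)


class TestPercentDifference:
    def test_pair_mean_denominator(self):
        assert percent_difference([150.0, 151.0]) == pytest.approx(0.6645, abs=1e-3)
        assert percent_difference([150.0, 153.2]) == pytest.approx(2.1108, abs=1e-3)
        assert percent_difference([160.0, 160.0]) == 0.0

    def test_more_than_two_uses_best_agreeing_pair(self):
        # closest pair is (150.0, 150.3): 0.1998%
        assert percent_difference([150.0, 150.3, 158.0]) == pytest.approx(
            0.1998, abs=1e-3
        )

    def test_requires_two_positive_values(self):
        with pytest.raises(ValueError):
            percent_difference([150.0])
        with pytest.raises(ValueError):
            percent_difference([150.0, -1.0])


def _detection(replicates):
    d = IonDetection(
        chem_id="X1",
        ion_type=THEO.ion_type,
        mode="ESI+",
        theoretical_mz=THEO.mz,
        replicate_ccs=list(replicates),
        isotope_ok=True,
        ppm=1.0,
    )
    d.status = "detected"
    return d


class TestReplicateQC:
    def test_agreeing_pair_passes_with_mean(self):
        d = replicate_qc(_detection([160.00, 160.80]))
        assert d.qc_pass
        assert d.mean_ccs == pytest.approx(160.40)
        assert d.pct_diff == pytest.approx(0.4988, abs=1e-3)

    def test_single_replicate_cannot_confirm(self):
        d = replicate_qc(_detection([160.0]))
        assert not d.qc_pass
        assert d.status == "replicate_fail"

    def test_disagreeing_pair_fails(self):
        d = replicate_qc(_detection([160.0, 163.5]))
        assert not d.qc_pass
        assert d.pct_diff == pytest.approx(2.164, abs=1e-3)

    def test_three_replicates_mean_over_agreeing_subset(self):
        # 160.0 and 160.8 agree within 1%; 170.0 is an outlier
        d = replicate_qc(_detection([160.0, 160.8, 170.0]))
        assert d.qc_pass
        assert d.mean_ccs == pytest.approx(160.4)


class TestTrendline:
    def test_exact_power_law_recovered(self):
        mz = np.linspace(100, 900, 50)
        pts = list(zip(mz, 10.0 * mz**0.5))
        model = fit_trendline(pts)
        assert model.a == pytest.approx(10.0, rel=1e-10)
        assert model.b == pytest.approx(0.5, rel=1e-10)

    def test_single_outlier_barely_shifts_large_fit(self):
        rng = np.random.default_rng(3)
        mz = rng.uniform(100, 900, 200)
        ccs = 10.0 * mz**0.5
        clean = fit_trendline(list(zip(mz, ccs)))
        dirty = fit_trendline(list(zip(mz, ccs)) + [(500.0, 1.2 * 10.0 * 500.0**0.5)])
        assert abs(dirty.b - clean.b) < 0.01

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            fit_trendline([(100.0, 100.0), (200.0, 140.0)])

    @pytest.mark.parametrize(
        "factor,kept", [(1.0, True), (1.10, True), (1.20, False), (0.80, False)]
    )
    def test_filter_at_15_percent(self, factor, kept):
        model = fit_trendline([(m, 10.0 * m**0.5) for m in (100.0, 400.0, 900.0)])
        d = _detection([150.0, 150.1])
        d = replicate_qc(d)
        d.mean_ccs = factor * float(model.predict(d.theoretical_mz))
        retained, rejected = trendline_filter([d], model, tol=15.0)
        assert (len(retained) == 1) is kept
        if not kept:
            assert rejected[0].status == "trendline_outlier"


class TestAssembleLibrary:
    def _registry(self, n=3):
        return [
            ChemicalRecord(f"X{i}", f"chem{i}", parse_formula("C10H7N3S"))
            for i in range(1, n + 1)
        ]

    def test_stage_counts_conserved(self):
        # (ion_type, mode) pairs crossed with 3 chemicals give distinct keys
        pairs = [("[M+H]+", "ESI+"), ("[M-H]-", "ESI-"), ("[M+Na]+", "ESI+")]
        detections = []
        for i, status in enumerate(
            ["retained"] * 7 + ["replicate_fail"] * 2 + ["trendline_outlier"]
        ):
            ion, mode = pairs[i // 3 % 3]
            d = IonDetection(
                chem_id=f"X{i % 3 + 1}",
                ion_type=theoretical_ion("C10H7N3S", ion).ion_type,
                mode=mode,
                theoretical_mz=THEO.mz,
                replicate_ccs=[150.0, 150.1],
                pct_diff=0.07,
                mean_ccs=150.05,
            )
            d.status = status
            detections.append(d)
        entries, report = assemble_library(self._registry(), detections)
        assert len(entries) == 7
        assert report.as_dict() == {
            "n_candidates": 10,
            "rejected_ppm": 0,
            "rejected_isotope": 0,
            "rejected_replicate": 2,
            "rejected_trendline": 1,
            "retained": 7,
        }
        assert report.conserved

    def test_empty_detections_empty_library(self):
        entries, report = assemble_library(self._registry(), [])
        assert entries == []
        assert report.n_candidates == 0 and report.conserved

    def test_duplicate_registry_ids_collapse(self):
        reg = self._registry() + [
            ChemicalRecord("X1", "dup", parse_formula("C10H7N3S"))
        ]
        d = _detection([150.0, 150.2])
        d.status = "retained"
        d.pct_diff = 0.13
        d.mean_ccs = 150.1
        entries, _ = assemble_library(reg, [d])
        assert len(entries) == 1
        assert entries[0].name == "chem1"  # first record wins

    def test_duplicate_library_key_raises(self):
        ds = []
        for _ in range(2):
            d = _detection([150.0, 150.2])
            d.status = "retained"
            d.pct_diff = 0.13
            d.mean_ccs = 150.1
            ds.append(d)
        with pytest.raises(ValueError):
            assemble_library(self._registry(), ds)


def test_gate_order_invariance():
    """ppm/isotope gating and replicate QC are applied per candidate, so the
    retained set is the same whichever gate is evaluated first."""
    rng = np.random.default_rng(5)
    candidates = []
    for i in range(200):
        mz = THEO.mz * (1 + rng.normal(0, 6e-6))
        m1 = THEO.m1_ratio * (1 + rng.normal(0, 0.2))
        ccs = 150.0 * (1 + rng.normal(0, 0.004, size=2))
        candidates.append(
            [
                _feature(mz, m1=m1, ccs=float(ccs[0]), rep=1),
                _feature(mz, m1=m1, ccs=float(ccs[1]), rep=2),
            ]
        )
    # route A: detection gate then replicate QC
    route_a = set()
    for i, feats in enumerate(candidates):
        d = detect_ion(feats, THEO)
        if d is not None and replicate_qc(d).qc_pass:
            route_a.add(i)
    # route B: replicate agreement first, then the detection gate
    route_b = set()
    for i, feats in enumerate(candidates):
        if percent_difference([f.ccs for f in feats]) <= 1.0:
            if detect_ion(feats, THEO) is not None:
                route_b.add(i)
    assert route_a == route_b
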