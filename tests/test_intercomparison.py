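"""Inter-comparison tests: report arithmetic, protocol runs, orderings.

The multi-seed invariants mirror the exercise's qualitative findings:
threshold-based segmentation strays further from the true volumes than
CT-geometry segmentation, and the total-source activity error is smaller
than the worst single-compartment error.
"""

import numpy as np
import pandas as pd
import pytest

from dataclasses import replace

from qspect.calibration import CalibrationResult
from qspect.intercomparison import (
    ProtocolResult,
    SiteProtocol,
    compile_report,
    ideal_protocol,
    make_comparison_phantom,
    percent_difference,
    reconstruct_protocol,
    run_protocol,
    site_protocols,
    within_threshold_table,
)
from qspect.phantom import mask_volume
from qspect.quantify import QuantResult, counts_in_voi
from qspect.segmentation import (
    iso_contour_voi,
    otsu_voi,
    shell_subtract,
    sphere_voi,
    source_search_region,
)
from qspect.recon import ReconConfig
from qspect.simulator import AcquisitionConfig, acquire, photopeak_208


class TestPercentDifference:
    def test_exact_match_zero(self):
        assert percent_difference(26.1, 26.1) == 0.0

    def test_hand_value(self):
        assert percent_difference(25.58, 26.1) == pytest.approx(-2.0, abs=0.01)

    def test_antisymmetry_around_truth(self):
        t, d = 26.1, 3.0
        assert percent_difference(t + d, t) == pytest.approx(
            -percent_difference(t - d, t))

    def test_zero_truth_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_difference(1.0, 0.0)


class TestWithinThresholdTable:
    def test_small_example(self):
        tab = within_threshold_table([-2.0, 4.0], [5.0])
        assert tab.iloc[0]["label"] == "2/2 (100%)"

    def test_all_zero_diffs_full_agreement(self):
        tab = within_threshold_table([0.0, 0.0, 0.0])
        assert np.all(tab["proportion"] == 1.0)

    def test_proportions_monotone_in_threshold(self):
        diffs = [-80.0, -12.0, 3.0, 18.0, 47.0, 95.0]
        tab = within_threshold_table(diffs)
        assert np.all(np.diff(tab["proportion"]) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            within_threshold_table([])

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            within_threshold_table([1.0], [10.0, 5.0])


def _fake_result(name, inner, outer, sigma=None):
    quant = {
        "inner": QuantResult(name, "inner", 26.0, inner, sigma),
        "outer": QuantResult(name, "outer", 81.0, outer, sigma),
        "total": QuantResult(name, "total", 107.0, inner + outer, sigma),
    }
    return ProtocolResult(name, CalibrationResult(10.0), quant)


class TestCompileReport:
    def test_single_result_zero_range(self, small_bundle):
        res = _fake_result("H1", 50.0, 11.0)
        report = compile_report([res], small_bundle)
        for s in report.spreads.values():
            assert s["range"] == 0.0

    def test_spread_arithmetic_convention(self, small_bundle):
        # two protocols at -17% and +29% of truth: spread 46, range -17..+29
        t = small_bundle.truth_activity("inner")
        res = [
            _fake_result("A", t * 0.83, small_bundle.truth_activity("outer")),
            _fake_result("B", t * 1.29, small_bundle.truth_activity("outer")),
        ]
        report = compile_report(res, small_bundle)
        s = report.spreads[("activity", "inner")]
        assert s["range"] == pytest.approx(46.0, abs=0.01)
        assert s["min"] == pytest.approx(-17.0, abs=0.01)
        assert s["max"] == pytest.approx(29.0, abs=0.01)
        assert s["mean"] == pytest.approx(6.0, abs=0.01)

    def test_permutation_invariant(self, small_bundle):
        res = [_fake_result(n, a, b) for n, a, b in
               [("H1", 50.0, 11.0), ("H2", 45.0, 9.0), ("H3", 55.0, 12.0)]]
        r1 = compile_report(res, small_bundle)
        r2 = compile_report(res[::-1], small_bundle)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.spreads == r2.spreads

    def test_uncertainty_coverage_flag(self, small_bundle):
        t = small_bundle.truth_activity("inner")
        res = _fake_result("H1", t * 1.05, small_bundle.truth_activity("outer"),
                           sigma=0.10 * t)
        report = compile_report([res], small_bundle)
        row = report.table[(report.table.protocol == "H1")
                           & (report.table.compartment == "inner")]
        assert bool(row["uncertainty_covers_truth"].iloc[0])

    def test_summary_text_renders(self, small_bundle):
        res = [_fake_result("H1", 50.0, 11.0), _fake_result("H2", 45.0, 9.0)]
        text = compile_report(res, small_bundle).summary_text()
        assert "spread" in text and "inner" in text


@pytest.fixture(scope="module")
def ideal_recon(small_bundle):
    """Noise-free ideal-protocol reconstruction at the reduced scale."""
    proto = ideal_protocol(n_projections=24)
    proto = replace(proto, recon=replace(proto.recon, iterations=100, subsets=12))
    ps = acquire(small_bundle.activity, small_bundle.density,
                 proto.acquisition, seed=11, noise=False)
    return reconstruct_protocol(ps, small_bundle.density, proto)


@pytest.fixture(scope="module")
def noisy_recons(small_bundle):
    """Ten independent noisy acquisitions reconstructed with one protocol."""
    proto = ideal_protocol(n_projections=24)
    proto = replace(proto, recon=replace(proto.recon, iterations=12, subsets=8))
    recons = []
    for seed in range(10):
        ps = acquire(small_bundle.activity, small_bundle.density,
                     proto.acquisition, seed=100 + seed, noise=True)
        recons.append(reconstruct_protocol(ps, small_bundle.density, proto))
    return recons


class TestIdealPipeline:
    def test_inner_activity_within_five_percent(self, small_bundle, ideal_recon):
        factor = 10.0  # oracle calibration: the configured sensitivity
        est = counts_in_voi(ideal_recon, small_bundle.masks["inner"]) / factor
        truth = small_bundle.truth_activity("inner")
        assert est == pytest.approx(truth, rel=0.05)

    def test_activity_monotone_in_voi_size(self, small_bundle, ideal_recon):
        # enlarging the VOI around the source strictly increases the
        # estimated activity on a nonnegative image
        src = small_bundle.source
        counts = [
            counts_in_voi(ideal_recon, sphere_voi(
                src.centre_mm, 2 * src.inner_radius_mm, m, small_bundle.grid))
            for m in (0.0, 5.0, 10.0, 15.0)
        ]
        assert np.all(np.diff(counts) > 0)


class TestRunProtocol:
    def test_deterministic_under_seed(self, small_bundle, small_protocols):
        r1 = run_protocol(small_protocols["H6"], small_bundle, seed=7)
        r2 = run_protocol(small_protocols["H6"], small_bundle, seed=7)
        assert r1.quant["inner"].activity_mbq == r2.quant["inner"].activity_mbq
        assert (r1.calibration.factor_cps_per_mbq
                == r2.calibration.factor_cps_per_mbq)

    def test_h6_reports_inner_only_without_uncertainty(self, small_bundle,
                                                       small_protocols):
        res = run_protocol(small_protocols["H6"], small_bundle, seed=7)
        assert set(res.quant) == {"inner"}
        assert res.quant["inner"].sigma_mbq is None
        assert res.quant["inner"].volume_ml is None  # arbitrary 8-cm sphere

    def test_h1_reports_all_compartments_with_uncertainty(self, small_bundle,
                                                          small_protocols):
        res = run_protocol(small_protocols["H1"], small_bundle, seed=3)
        assert set(res.quant) == {"inner", "outer", "total"}
        q = res.quant["inner"]
        assert q.activity_mbq > 0 and q.sigma_mbq > 0
        assert res.quant["total"].activity_mbq == pytest.approx(
            q.activity_mbq + res.quant["outer"].activity_mbq)


class TestResultOrderings:
    def test_threshold_segmentation_worse_than_ct(self, small_bundle,
                                                  noisy_recons):
        """SPECT-threshold volumes stray further from truth than CT volumes."""
        src = small_bundle.source
        grid = small_bundle.grid
        region = source_search_region(src.centre_mm, src.outer_radius_mm, grid)
        truth_inner = small_bundle.truth_volume("inner")

        ct_err, thr_err = [], []
        for recon in noisy_recons:
            v_ct = mask_volume(sphere_voi(src.centre_mm,
                                          2 * src.inner_radius_mm, 0.0, grid))
            ct_err.append(abs(percent_difference(v_ct, truth_inner)))
            v_iso = mask_volume(iso_contour_voi(recon, 0.35, region))
            v_otsu = mask_volume(otsu_voi(recon, region))
            thr_err.append(abs(percent_difference(v_iso, truth_inner)))
            thr_err.append(abs(percent_difference(v_otsu, truth_inner)))
        assert np.mean(thr_err) >= np.mean(ct_err)

    def test_total_error_below_worst_compartment(self, small_bundle,
                                                 noisy_recons):
        """Summing compartments cancels spill between them."""
        src = small_bundle.source
        grid = small_bundle.grid
        factor = 10.0
        inner_voi = sphere_voi(src.centre_mm, 2 * src.inner_radius_mm, 10.0,
                               grid)
        whole_voi = sphere_voi(src.centre_mm, 2 * src.outer_radius_mm, 10.0,
                               grid)
        outer_voi = shell_subtract(whole_voi, inner_voi)
        t_in = small_bundle.truth_activity("inner")
        t_out = small_bundle.truth_activity("outer")

        total_err, worst_err = [], []
        for recon in noisy_recons:
            a_in = counts_in_voi(recon, inner_voi) / factor
            a_out = counts_in_voi(recon, outer_voi) / factor
            e_in = abs(percent_difference(a_in, t_in))
            e_out = abs(percent_difference(a_out, t_out))
            e_tot = abs(percent_difference(a_in + a_out, t_in + t_out))
            total_err.append(e_tot)
            worst_err.append(max(e_in, e_out))
        assert np.mean(total_err) <= np.mean(worst_err)


class TestProtocolSmoke:
    """Every distinctive protocol path runs end to end at reduced scale."""

    @pytest.mark.parametrize("name", ["H2", "H4", "H5", "H7"])
    def test_protocol_produces_sane_results(self, small_bundle,
                                            small_protocols, name):
        proto = small_protocols[name]
        if name == "H4":
            # full 24-iteration preset is exercised at acceptance scale;
            # the wiring (windows, 3-position calibration, manual VOIs)
            # is what this smoke test checks
            proto = replace(proto, recon=replace(proto.recon, iterations=4))
        res = run_protocol(proto, small_bundle, seed=21)
        t_in = small_bundle.truth_activity("inner")
        q = res.quant["inner"]
        assert 0.2 * t_in < q.activity_mbq < 5.0 * t_in
        assert res.calibration.factor_cps_per_mbq > 0
        if name == "H2":
            assert res.iso_thresholds is not None
            lo, hi = sorted(res.iso_thresholds)
            assert 0.0 < lo < hi <= 1.0
        if name == "H7":
            assert res.recovery is not None
            assert res.recovery(26.0) > 0.3
        if name in ("H2", "H5", "H7"):
            assert q.sigma_mbq is not None and q.sigma_mbq >= 0
        assert "outer" in res.quant and "total" in res.quant


class TestCalibrationGeometry:
    def _base(self, calibration, calib_params, seg="truth"):
        return SiteProtocol(
            name=f"test-{calibration}",
            acquisition=AcquisitionConfig(
                n_projections=24, windows=(photopeak_208(),),
                orbit="contoured",
            ),
            recon=ReconConfig(8, 6, "none", resolution_recovery=False,
                              photopeaks=(208,)),
            segmentation=seg,
            calibration=calibration,
            uncertainty="none",
            calib_params=calib_params,
        )

    def test_shell_matched_calibration_beats_other_geometries(self,
                                                              small_bundle):
        """A calibration in the comparison source's own geometry cancels
        its partial-volume loss; mismatched geometries do not."""
        protos = {
            "shell": self._base("shell_matched",
                                {"concentration": 2.0, "offsets_mm": (0.0,)}),
            "sphere16": self._base("sphere16ml",
                                   {"activity_mbq": 20.0, "offsets_mm": (0.0,),
                                    "media": ("water",)}),
            "bottle": self._base("large_homogeneous",
                                 {"volume_ml": 130.0, "concentration": 2.0}),
        }
        t_total = small_bundle.truth_activity("total")
        errors = {}
        for key, proto in protos.items():
            res = run_protocol(proto, small_bundle, seed=9, noise=False)
            errors[key] = abs(percent_difference(
                res.quant["total"].activity_mbq, t_total))
        assert errors["shell"] <= errors["sphere16"] + 2.0
        assert errors["shell"] <= errors["bottle"] + 2.0

    def test_calibration_factor_invariant_to_activity_level(self,
                                                            small_bundle):
        """No dead time is modelled, so the cps/MBq factor is independent
        of how much activity the calibration source holds."""
        factors = []
        for act in (10.0, 40.0):
            proto = self._base("sphere16ml",
                               {"activity_mbq": act, "offsets_mm": (0.0,),
                                "media": ("water",)})
            res = run_protocol(proto, small_bundle, seed=2, noise=False)
            factors.append(res.calibration.factor_cps_per_mbq)
        assert factors[0] == pytest.approx(factors[1], rel=1e-3)
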