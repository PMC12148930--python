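import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from misplice.assays import (
    Bout,
    DyadCounts,
    PointEvent,
    ddct,
    dyad_binomial_test,
    fit_binding,
    fit_binding_replicates,
    interobserver_agreement,
    one_site_binding,
    rip_enrichment,
)
from oracles import binomial_tail_enumeration

X_GRID = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 300.0])


class TestBindingFit:
    def test_noiseless_recovery(self):
        y = one_site_binding(X_GRID, 1.0, 10.0)
        fit = fit_binding(X_GRID, y, normalize=False)
        assert fit.kd == pytest.approx(10.0, abs=1e-6)
        assert fit.bmax == pytest.approx(1.0, abs=1e-6)

    def test_half_saturation_property(self):
        # on the fitted curve, Y at X = Kd equals half of Bmax
        y = one_site_binding(X_GRID, 2.0, 25.0)
        fit = fit_binding(X_GRID, y, normalize=False)
        assert one_site_binding(fit.kd, fit.bmax, fit.kd) == pytest.approx(fit.bmax / 2)

    def test_normalization_preserves_kd_with_baseline_spanning_series(self):
        # when the series reaches both baseline and saturation, min-max
        # normalization leaves Kd essentially unchanged
        x = np.array([0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0])
        y = one_site_binding(x, 3.0, 10.0)
        fit = fit_binding(x, y, normalize=True)
        assert fit.kd == pytest.approx(10.0, rel=0.01)

    def test_scale_equivariance_in_x(self):
        y = one_site_binding(X_GRID, 1.0, 10.0)
        fit1 = fit_binding(X_GRID, y, normalize=False)
        fit2 = fit_binding(X_GRID * 7.0, y, normalize=False)
        assert fit2.kd == pytest.approx(7.0 * fit1.kd, rel=1e-6)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(11)
        curves = []
        for _ in range(3):
            y = one_site_binding(X_GRID, 1.0, 10.0) * (1 + rng.normal(0, 0.05, len(X_GRID)))
            curves.append((X_GRID, y))
        res = fit_binding_replicates(curves, normalize=False)
        assert abs(res["kd_mean"] - 10.0) / 10.0 < 0.15

    def test_residuals_zero_on_noiseless_curve(self):
        y = one_site_binding(X_GRID, 1.0, 10.0)
        fit = fit_binding(X_GRID, y, normalize=False)
        resid = y - one_site_binding(X_GRID, fit.bmax, fit.kd)
        assert np.max(np.abs(resid)) <= 1e-8

    def test_input_validation(self):
        with pytest.raises(ValueError, match="distinct concentrations"):
            fit_binding([1, 1, 2, 2], [0.1, 0.1, 0.2, 0.2])
        with pytest.raises(ValueError, match="order of magnitude"):
            fit_binding([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])


class TestDdct:
    @pytest.mark.parametrize(
        "args,expected",
        [((20, 18, 24, 18), 16.0), ((20, 18, 20, 18), 1.0), ((21, 18, 20, 18), 0.5)],
    )
    def test_fold_change_formula(self, args, expected):
        assert ddct(*args) == pytest.approx(expected)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(5, 35), st.floats(5, 35))
    def test_identity_when_case_equals_control(self, a, b):
        assert ddct(a, b, a, b) == pytest.approx(1.0)


def ct_rows(target, ip_bait, input_bait, ip_ctrl, input_ctrl):
    return [
        {"target": target, "fraction": "IP", "condition": "bait", "ct": ip_bait},
        {"target": target, "fraction": "INPUT", "condition": "bait", "ct": input_bait},
        {"target": target, "fraction": "IP", "condition": "control-bait", "ct": ip_ctrl},
        {"target": target, "fraction": "INPUT", "condition": "control-bait", "ct": input_ctrl},
    ]


class TestRipEnrichment:
    def test_literal_exponent(self):
        # x = (25-22) - (28-22) = -3 -> raw 2^-3 = 0.125
        table = pd.DataFrame(
            ct_rows("Ank2", 25, 22, 28, 22)
            + ct_rows("Nfat5", 25, 22, 25, 22)
            + ct_rows("Fmr1", 25, 22, 25, 22)
        )
        res = rip_enrichment(table, ["Nfat5", "Fmr1"]).set_index("target")
        assert res.at["Ank2", "raw_ip_over_input"] == pytest.approx(0.125)

    def test_all_equal_gives_unity(self):
        table = pd.DataFrame(
            ct_rows("Ank2", 25, 22, 25, 22)
            + ct_rows("Nfat5", 25, 22, 25, 22)
            + ct_rows("Fmr1", 25, 22, 25, 22)
        )
        res = rip_enrichment(table, ["Nfat5", "Fmr1"]).set_index("target")
        assert res.at["Ank2", "normalized"] == pytest.approx(1.0)

    def test_normalization_by_mean_of_negative_controls(self):
        # negative-control raws {0.5, 2.0} -> mean 1.25; target raw 2.5 -> 2.0
        table = pd.DataFrame(
            ct_rows("T", 25 + np.log2(2.5), 22, 25, 22)  # raw 2^log2(2.5) = 2.5
            + ct_rows("Nfat5", 24, 22, 25, 22)           # raw 2^-1 = 0.5
            + ct_rows("Fmr1", 26, 22, 25, 22)            # raw 2^1 = 2.0
        )
        res = rip_enrichment(table, ["Nfat5", "Fmr1"]).set_index("target")
        assert res.at["T", "normalized"] == pytest.approx(2.5 / 1.25)

    def test_negative_control_self_normalizes_to_symmetric_unit(self):
        table = pd.DataFrame(
            ct_rows("Nfat5", 25, 22, 25, 22) + ct_rows("Fmr1", 25, 22, 25, 22)
        )
        res = rip_enrichment(table, ["Nfat5", "Fmr1"]).set_index("target")
        assert res["normalized"].mean() == pytest.approx(1.0)

    def test_sign_flip_inverts_raw(self):
        table = pd.DataFrame(
            ct_rows("T", 25, 22, 28, 22)
            + ct_rows("Nfat5", 25, 22, 25, 22)
            + ct_rows("Fmr1", 25, 22, 25, 22)
        )
        lit = rip_enrichment(table, ["Nfat5", "Fmr1"]).set_index("target")
        flip = rip_enrichment(table, ["Nfat5", "Fmr1"], sign_flip=True).set_index("target")
        assert lit.at["T", "raw_ip_over_input"] * flip.at["T", "raw_ip_over_input"] == pytest.approx(1.0)

    def test_missing_control_bait_rejected(self):
        table = pd.DataFrame(
            [r for r in ct_rows("T", 25, 22, 28, 22) if r["condition"] == "bait"]
            + ct_rows("Nfat5", 25, 22, 25, 22)
            + ct_rows("Fmr1", 25, 22, 25, 22)
        )
        with pytest.raises(ValueError, match="missing Ct"):
            rip_enrichment(table, ["Nfat5", "Fmr1"])


class TestDyadBinomial:
    def test_reproduces_published_threat_communication_p(self):
        # 7% of 15 WT vs 36% of 14 KO dyads -> 1/15 vs 5/14, upper tail
        p = dyad_binomial_test(DyadCounts(1, 15, 5, 14), "greater")
        assert round(p, 4) == 0.0016

    def test_zero_ko_count_upper_tail_is_one(self):
        assert dyad_binomial_test(DyadCounts(1, 15, 0, 14), "greater") == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(1, 14), st.integers(0, 12), st.sampled_from(["greater", "less", "two_sided"])
    )
    def test_matches_pmf_enumeration(self, k_wt, k_ko, direction):
        n_wt, n_ko = 15, 12
        p = dyad_binomial_test(DyadCounts(k_wt, n_wt, k_ko, n_ko), direction)
        expected = binomial_tail_enumeration(k_ko, n_ko, k_wt / n_wt, direction)
        assert p == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_monotone_in_null_rate(self):
        ps = [dyad_binomial_test(DyadCounts(k, 15, 5, 14), "greater") for k in range(1, 8)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="degenerate null"):
            dyad_binomial_test(DyadCounts(0, 15, 5, 14), "greater")
        assert dyad_binomial_test(DyadCounts(0, 15, 0, 14), "greater") == 1.0

    def test_count_validation(self):
        with pytest.raises(ValueError):
            DyadCounts(5, 4, 1, 10)


class TestInterObserverAgreement:
    def test_identical_streams_full_agreement(self):
        stream = {
            "points": [PointEvent(1.0, "sniff"), PointEvent(5.0, "sniff")],
            "bouts": [Bout(10.0, 15.0, "interact")],
        }
        pct, ok = interobserver_agreement(stream, stream)
        assert pct == 100.0 and ok

    def test_point_within_one_second_agrees(self):
        a = {"points": [PointEvent(1.0, "x")], "bouts": []}
        b = {"points": [PointEvent(1.5, "x")], "bouts": []}
        pct, ok = interobserver_agreement(a, b)
        assert pct == 100.0 and ok

    def test_bout_boundary_beyond_two_seconds_fails(self):
        a = {"points": [], "bouts": [Bout(10.0, 15.0, "x")]}
        b = {"points": [], "bouts": [Bout(12.5, 15.0, "x")]}
        pct, ok = interobserver_agreement(a, b)
        assert pct == 0.0 and not ok

    def test_mixed_agreement_fraction(self):
        a = {"points": [PointEvent(1.0, "x"), PointEvent(20.0, "x")], "bouts": []}
        b = {"points": [PointEvent(1.2, "x"), PointEvent(40.0, "x")], "bouts": []}
        pct, ok = interobserver_agreement(a, b)
        # 1 matched, 2 unmatched -> 33.3%
        assert pct == pytest.approx(100 / 3)
        assert not ok

    def test_malformed_bout_rejected(self):
        with pytest.raises(ValueError, match="malformed bout"):
            Bout(15.0, 10.0, "x")
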