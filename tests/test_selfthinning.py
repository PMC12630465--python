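"""Thinning-space transform, period detection methods, slope fitting."""

import numpy as np
import pandas as pd
import pytest

from standbench import (DBH_SCHEME, MissingColumnError, SimConfig,
                        SizeStructure, StandSeries, detect_m1, detect_m2,
                        detect_m3, detect_m4, fit_slope, simulate_stand,
                        to_thinning_space, SelfThinningModel)

from conftest import p3_config


def _structure_single_class(years, label, nstem, cwood):
    rows = []
    for y in years:
        for lab in DBH_SCHEME.labels:
            rows.append({"year": y, "class_label": lab,
                         "nstem_size": nstem if lab == label else 0.0,
                         "cwood_size": cwood if lab == label else 0.0})
    return SizeStructure(pd.DataFrame(rows))


def _series_for(years):
    n = len(years)
    return StandSeries(pd.DataFrame({
        "year": years, "cwood": 10.0, "cwood_ag": 7.0, "cmort": 0.1,
        "wbgrowth": 0.1, "nstem": 1000.0, "ca": 9000.0,
    }))


class TestThinningSpace:
    def test_mass_conversion_to_per_tree(self):
        """1000 stems/ha holding 5 kgC/m2 aboveground = 50 kgC per tree."""
        years = np.arange(3)
        structure = _structure_single_class(years, "<30", 1000.0, 5.0)
        pts = to_thinning_space(_series_for(years), structure)
        np.testing.assert_allclose(pts["lnN"], np.log(1000.0))
        np.testing.assert_allclose(pts["lnM"], np.log(50.0))

    def test_small_trees_excluded(self):
        years = np.arange(3)
        structure = _structure_single_class(years, "<5", 1000.0, 5.0)
        pts = to_thinning_space(_series_for(years), structure, min_dbh=10)
        assert len(pts) == 0

    def test_boundary_class_included(self):
        # "<15" spans [10, 15): its lower edge meets the 10 cm rule
        years = np.arange(3)
        structure = _structure_single_class(years, "<15", 500.0, 2.0)
        pts = to_thinning_space(_series_for(years), structure, min_dbh=10)
        assert len(pts) == 3

    def test_totals_fallback_recorded(self):
        pts = to_thinning_space(_series_for(np.arange(3)), None)
        assert pts.attrs["used_size_structure"] is False
        np.testing.assert_allclose(pts["lnN"], np.log(1000.0))
        np.testing.assert_allclose(pts["lnM"], np.log(10.0 * 1e4 / 1000.0))

    def test_simulator_points_collinear_inside_window(self, default_run):
        _, series, structure, truth = default_run
        pts = to_thinning_space(series, structure)
        t0, t1 = truth.thinning_window
        win = pts[(pts["year"] >= t0) & (pts["year"] < t1)]
        fitted = np.polyfit(win["lnN"], win["lnM"], 1)
        resid = win["lnM"] - np.polyval(fitted, win["lnN"])
        assert np.max(np.abs(resid)) < 1e-12


def _sort_threshold_oracle(values, years):
    """Independent M1/M2 oracle: sort, take the strict top-5% threshold."""
    thr = np.percentile(values, 95)
    return set(np.asarray(years)[np.asarray(values) > thr])


class TestPercentileMethods:
    def test_spike_decade_detected(self, rng):
        rate = np.full(100, 0.5) + rng.uniform(0, 0.01, 100)
        rate[40:50] += 5.0
        years = np.arange(100)
        sel = set(detect_m1(rate, years))
        assert sel == _sort_threshold_oracle(rate, years)
        assert sel <= set(range(40, 50))
        assert len(sel) == 5   # strict top 5% of 100 values

    def test_constant_series_selects_nothing(self):
        assert len(detect_m1(np.full(60, 1.0))) == 0
        assert len(detect_m2(np.full(60, 1.0))) == 0

    def test_permutation_equivariance(self, rng):
        rate = rng.exponential(size=80)
        years = np.arange(80)
        perm = rng.permutation(80)
        sel = set(detect_m2(rate, years))
        sel_perm = set(detect_m2(rate[perm], years[perm]))
        assert sel == sel_perm

    def test_twenty_year_series_selects_one_year(self, rng):
        """ceil(0.05 * 20) = 1: with distinct values only the maximum
        exceeds the 95th percentile."""
        rate = rng.normal(size=20)
        sel = detect_m2(rate, np.arange(20))
        assert len(sel) == 1
        assert sel[0] == int(np.argmax(rate))

    def test_matches_oracle_on_many_random_series(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 200))
            vals = rng.exponential(size=n)
            years = np.arange(n)
            assert set(detect_m1(vals, years)) == \
                _sort_threshold_oracle(vals, years)


def _m3_bruteforce(ln_n, years):
    """Enumerate all runs [i..j] and pick the one maximising the density
    drop; ties prefer the earliest start, then the longest run."""
    best, out = -np.inf, None
    for i in range(len(ln_n)):
        for j in range(i + 1, len(ln_n)):
            drop = ln_n[i] - ln_n[j]
            if drop > best + 1e-15:
                best, out = drop, (i, j)
    if out is None or best <= 0:
        return np.asarray([], dtype=int)
    # re-scan for ties with the preferred ordering
    cands = [(i, j) for i in range(len(ln_n)) for j in range(i + 1, len(ln_n))
             if abs((ln_n[i] - ln_n[j]) - best) <= 1e-15]
    i, j = min(cands, key=lambda c: (c[0], -c[1]))
    return years[i:j + 1]


class TestDensityRunMethod:
    def test_max_to_min_run(self):
        n = np.array([500, 900, 850, 700, 600, 300, 310, 305])
        pts = pd.DataFrame({"year": np.arange(8), "lnN": np.log(n),
                            "lnM": -np.log(n)})
        sel = detect_m3(pts)
        np.testing.assert_array_equal(sel, np.arange(1, 6))  # 900 .. 300

    def test_monotone_decline_selects_everything(self):
        n = np.linspace(1000, 100, 40)
        pts = pd.DataFrame({"year": np.arange(40), "lnN": np.log(n),
                            "lnM": -np.log(n)})
        np.testing.assert_array_equal(detect_m3(pts), np.arange(40))

    def test_never_declining_yields_empty(self):
        n = np.linspace(100, 1000, 10)
        pts = pd.DataFrame({"year": np.arange(10), "lnN": np.log(n),
                            "lnM": -np.log(n)})
        assert len(detect_m3(pts)) == 0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            m = int(rng.integers(3, 60))
            ln_n = rng.normal(size=m)
            years = np.arange(m) + int(rng.integers(0, 5))
            pts = pd.DataFrame({"year": years, "lnN": ln_n, "lnM": -ln_n})
            np.testing.assert_array_equal(detect_m3(pts),
                                          _m3_bruteforce(ln_n, years))

    def test_simulator_window_contained_in_selection(self, default_run):
        _, series, structure, truth = default_run
        pts = to_thinning_space(series, structure)
        sel = set(detect_m3(pts))
        t0, t1 = truth.thinning_window
        inner = set(range(t0 + 1, t1 - 1))
        assert inner <= sel


class TestManualMethod:
    def test_literal_range(self):
        np.testing.assert_array_equal(detect_m4((40, 80)),
                                      np.arange(40, 81))

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError, match="reversed"):
            detect_m4((80, 40))

    def test_manual_overrides_automatic(self, default_run):
        _, series, structure, _ = default_run
        model = SelfThinningModel(series, structure)
        res = model.fit(method=3, manual_range=(60, 100))
        assert res.result.method == 4
        assert res.selected_years == tuple(range(60, 101))


class TestSlopeFit:
    @pytest.mark.parametrize("p", [-2.6, -2.0, -1.5, -1.0])
    def test_noise_free_recovery_exact(self, p):
        cfg = SimConfig(seed=0, thinning_exponent=p)
        series, structure, truth = simulate_stand(cfg)
        res = SelfThinningModel(series, structure).fit(method=3)
        assert res.slope == pytest.approx(p, abs=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert res.k == pytest.approx(truth.k, rel=1e-6)

    def test_boundary_exponents_within_bounds_inclusive(self):
        for p in (-1.0, -2.612):
            cfg = SimConfig(seed=0, thinning_exponent=p)
            series, structure, _ = simulate_stand(cfg)
            res = SelfThinningModel(series, structure).fit(method=3)
            assert res.result.within_bounds

    def test_out_of_band_slope_flagged(self):
        cfg = SimConfig(seed=0, thinning_exponent=-2.8)
        series, structure, _ = simulate_stand(cfg)
        res = SelfThinningModel(series, structure).fit(method=3)
        assert not res.result.within_bounds

    def test_noisy_recovery_unbiased(self):
        """200 seeds, 50-point windows, 5% noise: the mean fitted slope is
        within 0.05 of the generating exponent."""
        slopes = []
        for seed in range(200):
            cfg = SimConfig(years=160, seed=seed, noise_sd=0.05,
                            phase_boundaries=(12, 48, 98))
            series, structure, _ = simulate_stand(cfg)
            slopes.append(SelfThinningModel(series, structure)
                          .fit(method=3).slope)
        assert abs(np.mean(slopes) - (-1.5)) < 0.05

    def test_insufficient_points_rejected(self):
        pts = pd.DataFrame({"year": [0, 1], "lnN": [1.0, 2.0],
                            "lnM": [0.0, 1.0]})
        with pytest.raises(ValueError, match="insufficient"):
            fit_slope(pts)

    def test_zero_density_variance_rejected(self):
        pts = pd.DataFrame({"year": [0, 1, 2], "lnN": [1.0, 1.0, 1.0],
                            "lnM": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="insufficient"):
            fit_slope(pts)

    def test_method1_requires_diagnostic_column(self):
        series = _series_for(np.arange(30))
        model = SelfThinningModel(series, None)
        with pytest.raises(MissingColumnError, match="selfthin_mort_rate"):
            model.fit(method=1)

    def test_method1_on_simulator_diagnostic(self):
        series, structure, truth = simulate_stand(p3_config(0))
        res = SelfThinningModel(series, structure).fit(method=1)
        t0, t1 = truth.thinning_window
        assert set(res.selected_years) <= set(range(t0, t1))
        assert res.slope == pytest.approx(truth.p, abs=1e-9)


class TestSlopeInvariance:
    def test_log_base_and_unit_rescaling(self, default_run):
        """The exponent does not depend on the logarithm base or the mass
        unit; only the intercept shifts."""
        _, series, structure, _ = default_run
        pts = to_thinning_space(series, structure)
        sel = detect_m3(pts)
        base = fit_slope(pts, selected_years=sel)

        # log10 on both axes
        pts10 = pts.copy()
        pts10["lnN"] = pts["lnN"] / np.log(10)
        pts10["lnM"] = pts["lnM"] / np.log(10)
        r10 = fit_slope(pts10, selected_years=sel)
        assert r10.slope == pytest.approx(base.slope, abs=1e-9)

        # kgC -> gC: lnM shifts by ln 1000
        ptsg = pts.copy()
        ptsg["lnM"] = pts["lnM"] + np.log(1000.0)
        rg = fit_slope(ptsg, selected_years=sel)
        assert rg.slope == pytest.approx(base.slope, abs=1e-12)
        assert rg.intercept == pytest.approx(base.intercept + np.log(1000.0),
                                             abs=1e-9)

    def test_summary_reports_fit(self, default_run):
        _, series, structure, _ = default_run
        res = SelfThinningModel(series, structure).fit(method=3)
        text = res.summary()
        assert "slope p" in text and "-1.5" in text
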