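"""Nullclines, fixed points, basins, bifurcation scans, hysteresis."""

import numpy as np
import pytest

from hpatoggle import (ConfigError, DomainError, ModelParameters,
                       ReducedState, adrenal_nullcline, bifurcation_foldchange,
                       classify_basin, cns_nullcline, find_fixed_points,
                       hysteresis_scan, separatrix)
from hpatoggle.phase import smoothed_fixed_points
from hpatoggle.qss import slow_rhs


class TestNullclines:
    @pytest.mark.parametrize("h, u, expected", [(1.0, 1.0, 1.0),
                                                (0.5, 1.0, 2.0),
                                                (1.0, 2.0, 2.0)])
    def test_adrenal_nullcline_tracks_u_over_h(self, nominal, h, u, expected):
        assert adrenal_nullcline(h, u, nominal) == pytest.approx(expected)

    def test_adrenal_nullcline_monotonicity(self, nominal):
        h = np.linspace(0.3, 2.0, 30)
        A = [adrenal_nullcline(hh, 1.0, nominal) for hh in h]
        assert np.all(np.diff(A) < 0)

    @pytest.mark.parametrize("A, expected_branches", [
        (0.5, {"euthymic"}),
        (3.0, {"depressed"}),
        (1.5, {"euthymic", "depressed"}),  # the bistable overlap window
    ])
    def test_cns_nullcline_branch_validity(self, nominal, A,
                                           expected_branches):
        levels = cns_nullcline(A, 1.0, 1.0, nominal)
        assert {branch for _, branch in levels} == expected_branches

    def test_cns_levels_are_high_and_low(self, nominal):
        levels = dict((b, h) for h, b in cns_nullcline(1.5, 1.0, 1.0, nominal))
        assert levels["euthymic"] == pytest.approx(1.0)
        assert levels["depressed"] == pytest.approx(0.5)


class TestFixedPoints:
    def test_nominal_census_three_points(self, nominal):
        points = find_fixed_points(1.0, 1.0, nominal)
        assert [fp.branch for fp in points] == ["euthymic", "threshold",
                                                "depressed"]
        assert [fp.stability for fp in points] == ["stable", "unstable",
                                                   "stable"]
        eu, thr, dep = points
        assert (eu.A, eu.h, eu.x3) == pytest.approx((1.0, 1.0, 1.0))
        assert (thr.A, thr.h, thr.x3) == pytest.approx((1.5, 2 / 3, 1.5))
        assert (dep.A, dep.h, dep.x3) == pytest.approx((2.0, 0.5, 2.0))

    def test_low_stress_is_monostable_euthymic(self, nominal):
        points = find_fixed_points(0.4, 1.0, nominal)
        assert [fp.branch for fp in points] == ["euthymic"]

    def test_high_stress_is_monostable_depressed(self, nominal):
        points = find_fixed_points(2.0, 1.0, nominal)
        assert [fp.branch for fp in points] == ["depressed"]

    def test_smoothed_roots_match_piecewise_algebra(self, nominal):
        exact = [(fp.A, fp.h) for fp in find_fixed_points(1.0, 1.0, nominal)]
        roots = smoothed_fixed_points(1.0, 1.0, nominal, steepness=200.0)
        assert len(roots) == len(exact)
        for (A_r, h_r), (A_e, h_e) in zip(roots, exact):
            assert abs(A_r - A_e) < 1e-2
            assert abs(h_r - h_e) < 1e-2

    def test_smoothed_roots_converge_with_steepness(self, nominal):
        exact = [(fp.A, fp.h) for fp in find_fixed_points(1.0, 1.0, nominal)]
        dists = []
        for m in (10, 50, 200):
            roots = smoothed_fixed_points(1.0, 1.0, nominal, steepness=m)
            dists.append(max(
                max(abs(A_r - A_e), abs(h_r - h_e))
                for (A_r, h_r), (A_e, h_e) in zip(roots, exact)))
        assert dists[0] > dists[1] >= dists[2]
        assert dists[2] < 1e-3

    def test_smoothed_threshold_point_is_a_saddle(self, nominal):
        """Numeric Jacobian of the smoothed system near (1.5, 2/3)."""
        def field(z):
            return np.array(slow_rhs(ReducedState(z[0], z[1]), 1.0, 1.0,
                                     nominal, drive_mode="smooth",
                                     steepness=200.0))
        z0 = np.array([1.5, 2 / 3])
        jac = np.empty((2, 2))
        for j in range(2):
            dz = np.zeros(2)
            dz[j] = 1e-7
            jac[:, j] = (field(z0 + dz) - field(z0 - dz)) / 2e-7
        eig = np.linalg.eigvals(jac)
        assert eig.real.min() < 0 < eig.real.max()


class TestBasins:
    @pytest.mark.parametrize("init, expected", [
        ((0.9, 1.0), "euthymic"),
        ((2.5, 0.5), "depressed"),
        ((1.6, 1 / 1.6), "depressed"),  # just beyond the threshold point
    ])
    def test_basin_labels(self, nominal, init, expected):
        assert classify_basin(ReducedState(*init), 1.0, 1.0, nominal) == \
            expected

    def test_monostable_regime_warns(self, nominal):
        with pytest.warns(UserWarning, match="monostable"):
            label = classify_basin(ReducedState(1.0, 1.0), 0.4, 1.0, nominal)
        assert label == "euthymic"

    def test_separatrix_passes_through_unstable_point(self, nominal):
        curve = separatrix(1.0, 1.0, nominal, [2 / 3])
        assert abs(curve["A_star"].iloc[0] - 1.5) < 1e-3

    def test_separatrix_flips_basin_label_and_is_monotone(self, nominal):
        h_grid = [0.55, 0.65, 0.75]
        curve = separatrix(1.0, 1.0, nominal, h_grid)
        for _, row in curve.iterrows():
            below = classify_basin(ReducedState(row["A_star"] - 5e-3,
                                                row["h"]), 1.0, 1.0, nominal)
            above = classify_basin(ReducedState(row["A_star"] + 5e-3,
                                                row["h"]), 1.0, 1.0, nominal)
            assert below == "euthymic" and above == "depressed"
        assert np.all(np.diff(curve["A_star"]) > 0)

    def test_separatrix_requires_bistability(self, nominal):
        with pytest.raises(DomainError):
            separatrix(0.4, 1.0, nominal, [1.0])


class TestBifurcation:
    @pytest.mark.parametrize("name, direction, expected", [
        ("u", "decrease", 0.75), ("u", "increase", 1.5),
        ("a", "decrease", 0.5), ("a", "increase", 1.5),
        ("b", "decrease", 0.5),
        ("T", "decrease", 2 / 3), ("T", "increase", 4 / 3),
        ("a1", "decrease", 0.75), ("a1", "increase", 1.5),
        ("b1", "decrease", 2 / 3), ("b1", "increase", 4 / 3),
    ])
    def test_critical_fold_changes(self, nominal, name, direction, expected):
        result = bifurcation_foldchange(name, direction, 1.0, nominal)
        assert result.exists
        assert abs(result.critical_fold_change - expected) < 0.01

    def test_b_has_no_upper_bifurcation(self, nominal):
        result = bifurcation_foldchange("b", "increase", 1.0, nominal)
        assert not result.exists
        assert np.isnan(result.critical_fold_change)

    def test_unknown_parameter_rejected(self, nominal):
        with pytest.raises(ConfigError):
            bifurcation_foldchange("zeta", "decrease", 1.0, nominal)

    def test_count_transitions_are_clean(self, nominal):
        """Along a u sweep the stable-point count only takes values 1, 2."""
        counts = []
        for u in np.geomspace(0.1, 10.0, 200):
            stable = [fp for fp in find_fixed_points(u, 1.0, nominal)
                      if fp.stability == "stable"]
            counts.append(len(stable))
        assert set(counts) <= {1, 2}
        switches = np.nonzero(np.diff(counts))[0]
        assert len(switches) == 2  # enter and leave the bistable window


class TestHysteresis:
    def test_nominal_thresholds(self, nominal):
        result = hysteresis_scan((0.4, 2.0), nominal)
        assert result.u1 == pytest.approx(1.5)
        assert result.u2 == pytest.approx(0.75)
        assert result.u2 < result.u1
        assert result.bistable_in_range

    def test_branch_values_at_baseline(self, nominal):
        result = hysteresis_scan((0.4, 2.0), nominal, num=161)
        at_one = result.branches.iloc[
            (result.branches["u"] - 1.0).abs().idxmin()]
        assert at_one["A_euthymic"] == pytest.approx(1.0, abs=1e-2)
        assert at_one["A_depressed"] == pytest.approx(2.0, abs=2e-2)

    def test_branch_existence_respects_thresholds(self, nominal):
        result = hysteresis_scan((0.4, 2.0), nominal, num=161)
        b = result.branches
        assert b.loc[b["u"] > result.u1 + 1e-6, "A_euthymic"].isna().all()
        assert b.loc[b["u"] < result.u2 - 1e-6, "A_depressed"].isna().all()

    def test_window_ordering_across_random_susceptible_draws(self, rng):
        found = 0
        while found < 50:
            factors = rng.uniform(0.8, 1.25, 7)
            params = ModelParameters().replace(
                a=factors[0], b=factors[1], T=1.5 * factors[2],
                a1=0.17 * 1440 * factors[3], b1=0.17 * 1440 * factors[4],
                ah=0.047 * factors[5], bh=0.047 * factors[6])
            if len(find_fixed_points(1.0, 1.0, params)) != 3:
                continue
            result = hysteresis_scan((0.3, 3.0), params)
            assert result.u2 < result.u1
            found += 1
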