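"""Root solving, the finite-bath series, the PDE oracle and fitting."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migrisk.geometry import ContactSystem
from migrisk.migration import (
    DEFAULT_TIMES_H,
    MigrationCurve,
    compute_migration_ratio,
    fit_diffusion,
    migration_curve_model,
    migration_ratio_model,
    pde_oracle,
    read_migration_table,
    series_coefficients,
    series_fraction,
    solve_roots,
)

L = 8.0e-3  # cm, default film thickness
D_REF = 8.00e-11  # cm^2/s


def bisect_root(alpha: float, n: int, iters: int = 200) -> float:
    """Independent bisection oracle for the n-th root of tan q = -alpha*q."""
    f = lambda q: math.sin(q) + alpha * q * math.cos(q)
    lo, hi = (n - 0.5) * math.pi + 1e-12, n * math.pi - 1e-12
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestMigrationRatio:
    def test_zero_and_complete_transfer(self):
        assert compute_migration_ratio(0.0, 6480.0) == 0.0
        assert compute_migration_ratio(6480.0, 6480.0) == 100.0

    def test_default_film_one_percent(self):
        assert compute_migration_ratio(64.8, 6480.0) == pytest.approx(1.0)

    def test_over_100_percent_warned_not_clipped(self):
        with pytest.warns(UserWarning, match="exceeds 100"):
            assert compute_migration_ratio(200.0, 100.0) == pytest.approx(200.0)

    def test_invalid_initial_amount(self):
        with pytest.raises(ValueError):
            compute_migration_ratio(1.0, 0.0)


class TestRoots:
    @pytest.mark.parametrize("alpha", [0.05, 0.328, 1.0, 3.293, 10.088])
    def test_roots_match_bisection_oracle_and_brackets(self, alpha):
        rs = solve_roots(alpha, n_roots=12)
        for n, q in enumerate(rs.roots, start=1):
            assert (n - 0.5) * math.pi < q < n * math.pi
            assert q == pytest.approx(bisect_root(alpha, n), abs=1e-10)
        assert np.all(np.diff(rs.roots) > 0)
        # the raw residual |tan q + aq| has a floating-point floor of
        # ~ f'(q)*q*eps with f'(q) = 1 + (aq)^2 + a at the root; assert the
        # 1e-10 bound wherever that floor allows it, and the floor otherwise
        floor = (1.0 + (alpha * rs.roots) ** 2 + alpha) * rs.roots * 2.3e-16
        assert np.all(rs.residuals < np.maximum(1e-10, 20.0 * floor))
        assert np.all(rs.residuals[:3] < 1e-10)

    def test_unit_alpha_first_root_frozen_value(self):
        # bisection on sin q + q cos q over (pi/2, pi) to 1e-12
        assert solve_roots(1.0, 1).roots[0] == pytest.approx(
            2.028757838110434, abs=1e-12
        )

    def test_small_alpha_limit_approaches_n_pi(self):
        roots = solve_roots(1e-8, 4).roots
        assert roots == pytest.approx(np.arange(1, 5) * math.pi, abs=1e-6)

    def test_large_alpha_limit_approaches_half_odd_pi(self):
        roots = solve_roots(1e8, 4).roots
        assert roots == pytest.approx((np.arange(1, 5) - 0.5) * math.pi, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_roots(0.0, 3)
        with pytest.raises(ValueError):
            solve_roots(1.0, 0)


class TestSeries:
    def test_time_zero_is_exactly_zero(self):
        assert series_fraction(D_REF, 0.0, L, 0.328) == 0.0

    def test_long_time_limit_is_one(self):
        t = 10.0 * L**2 / D_REF
        assert series_fraction(D_REF, t, L, 0.328) == pytest.approx(1.0, abs=1e-10)

    def test_coefficients_sum_to_one_in_the_tail_limit(self):
        # truncation adequacy: the weights sum to 1 over all terms; the
        # remainder after N terms shrinks like 1/N
        alpha = 1.0
        for n, bound in ((200, 2.5e-3), (2000, 2.5e-4)):
            roots = solve_roots(alpha, n).roots
            gap = 1.0 - series_coefficients(alpha, roots).sum()
            assert 0 < gap < bound

    def test_matches_pde_oracle_at_reference_conditions(self):
        t_h = 6.0
        ser = series_fraction(D_REF, t_h * 3600.0, L, 0.328)
        pde, _ = pde_oracle(D_REF, 0.328, L, [t_h], nx=400)
        assert ser == pytest.approx(pde[0], abs=1e-3)

    @given(
        alpha=st.floats(min_value=0.05, max_value=10.0),
        tau=st.floats(min_value=1e-3, max_value=5.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounded_and_monotone_in_time_and_diffusivity(self, alpha, tau):
        t = tau * L**2 / D_REF
        f = series_fraction(D_REF, t, L, alpha)
        assert 0.0 <= f <= 1.0
        assert series_fraction(D_REF, 1.3 * t, L, alpha) >= f
        assert series_fraction(1.3 * D_REF, t, L, alpha) >= f

    def test_truncation_cap_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            series_fraction(1e-13, 1.0, L, 1.0, n_terms=8)

    def test_time_unit_consistency(self):
        # the hour-facing model equals the second-facing series
        times_h = np.array([0.5, 6.0, 72.0])
        via_model = migration_ratio_model(D_REF, 0.328, L, times_h)
        via_series = 100.0 * (0.328 / 1.328) * series_fraction(
            D_REF, times_h * 3600.0, L, 0.328
        )
        np.testing.assert_allclose(via_model, via_series, rtol=1e-12)


class TestCurveModel:
    def test_starts_at_zero_and_reaches_plateau(self):
        curve = migration_curve_model(D_REF, 3.293, L, [0.0, 1e4])
        assert curve.mr_percent[0] == 0.0
        assert curve.mr_percent[-1] == pytest.approx(76.7, abs=0.05)

    def test_monotone_non_decreasing(self):
        curve = migration_curve_model(D_REF, 0.328, L, DEFAULT_TIMES_H)
        assert np.all(np.diff(curve.mr_percent) >= 0)

    def test_curve_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MigrationCurve("x", "y", [1.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="non-negative"):
            MigrationCurve("x", "y", [1.0, 2.0], [-1.0, 1.0])


class TestPDEOracle:
    @pytest.mark.parametrize("alpha", [0.3, 3.0])
    def test_series_equivalence_spot_checks(self, alpha):
        taus = np.geomspace(1e-3, 10.0, 12)
        t_h = taus * L**2 / D_REF / 3600.0
        ser = series_fraction(D_REF, taus * L**2 / D_REF, L, alpha)
        pde, mass_err = pde_oracle(D_REF, alpha, L, t_h, nx=400)
        assert np.abs(ser - pde).max() < 1e-3
        assert mass_err < 1e-6

    def test_large_alpha_matches_infinite_bath_closed_form(self):
        taus = np.array([0.05, 0.2, 1.0])
        t_h = taus * L**2 / D_REF / 3600.0
        pde, _ = pde_oracle(D_REF, 1e4, L, t_h, nx=400)
        n = np.arange(1, 500)[:, None]
        closed = 1.0 - (
            8.0 / ((2 * n - 1) ** 2 * math.pi**2)
            * np.exp(-((2 * n - 1) ** 2) * math.pi**2 * taus[None, :] / 4.0)
        ).sum(axis=0)
        assert np.abs(pde - closed).max() < 1e-3

    def test_grid_too_coarse_rejected(self):
        with pytest.raises(ValueError, match="nx"):
            pde_oracle(D_REF, 1.0, L, [1.0], nx=10)


class TestFit:
    def test_noiseless_co_fit_recovers_generating_parameters(self, system):
        curve = migration_curve_model(
            D_REF, 0.328, L, DEFAULT_TIMES_H, "TPhP", "Eastern leaf"
        )
        fit = fit_diffusion(curve, system, mode="co_fit_alpha")
        assert fit.converged
        assert fit.d_cm2_s == pytest.approx(D_REF, rel=5e-3)
        assert fit.alpha == pytest.approx(0.328, rel=1e-3)
        assert fit.r_squared > 0.9999
        assert fit.k_pf == pytest.approx(system.volume_ratio / fit.alpha, rel=1e-12)

    def test_plateau_mode_recovers_d_when_curve_has_plateaued(self, system):
        # with a fast diffuser the 72 h point sits on the plateau, so the
        # plateau-derived alpha is accurate and D follows
        d_true = 5.0e-10
        curve = migration_curve_model(d_true, 1.0, L, DEFAULT_TIMES_H)
        fit = fit_diffusion(curve, system, mode="fix_alpha_from_plateau")
        assert fit.alpha == pytest.approx(1.0, rel=1e-3)
        assert fit.d_cm2_s == pytest.approx(d_true, rel=0.02)

    def test_degenerate_inputs_rejected(self, system):
        with pytest.raises(ValueError, match="at least 4"):
            fit_diffusion(
                MigrationCurve("x", "y", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), system
            )
        with pytest.raises(ValueError, match="all-zero"):
            fit_diffusion(
                MigrationCurve("x", "y", [1.0, 2.0, 3.0, 4.0], [0.0] * 4), system
            )


class TestMigrationIO:
    def test_replicates_averaged_and_concentration_converted(self, system):
        text = io.StringIO(
            "compound,food,time_h,replicate,conc_ng_ml\n"
            "TPhP,Beer,1,1,10.0\n"
            "TPhP,Beer,1,2,12.0\n"
            "TPhP,Beer,2,1,20.0\n"
            "TPhP,Beer,2,2,22.0\n"
        )
        curves = read_migration_table(text, system=system)
        assert len(curves) == 1
        curve = curves[0]
        # MR = 100 * conc * V_F / m_i with V_F = 15 mL, m_i = 6480 ng
        assert curve.mr_percent[0] == pytest.approx(100 * 11.0 * 15.0 / 6480.0)
        assert curve.mr_percent[1] == pytest.approx(100 * 21.0 * 15.0 / 6480.0)
        assert curve.n_replicates == 2

    def test_missing_columns_rejected(self, system):
        with pytest.raises(ValueError, match="missing required columns"):
            read_migration_table(io.StringIO("compound,food\n"), system=system)
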