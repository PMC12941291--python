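"""Finite-bath Fickian migration: series solution, PDE oracle and fitting.

An additive initially distributed uniformly in a polymer film (thickness
``L``, zero-flux back face) diffuses with constant coefficient ``D`` into a
finite, well-stirred food phase whose equilibrium capacity relative to the
film is the dimensionless ratio ``α``.  The fraction of the ultimately
migrating amount transferred by time ``t`` is the classical limited-volume
sorption series

    M_F,t / M_F,∞ = 1 − Σ_n  [2α(1+α) / (1 + α + α²q_n²)] · exp(−D t q_n² / L²)

where ``q_n`` is the n-th positive root of ``tan q = −α q``.  The observable
migration ratio follows as ``MR(t)% = 100 · α/(1+α) · M_F,t/M_F,∞``.

The module provides the root solver, the truncated series, an independent
finite-volume PDE solver used as a numerical oracle, and least-squares
estimation of ``(D, α)`` from observed migration curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh_tridiagonal
from scipy.optimize import brentq, least_squares

from .geometry import ContactSystem, equilibrium_fraction, partition_from_alpha

__all__ = [
    "RootSet",
    "MigrationCurve",
    "DiffusionFit",
    "compute_migration_ratio",
    "solve_roots",
    "series_coefficients",
    "series_fraction",
    "migration_ratio_model",
    "migration_curve_model",
    "pde_oracle",
    "fit_diffusion",
    "read_migration_table",
    "fits_to_frame",
]

SECONDS_PER_HOUR = 3600.0

#: default sampling grid of the migration experiment (hours)
DEFAULT_TIMES_H: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 24.0, 48.0, 72.0)


# ---------------------------------------------------------------------------
# migration ratio arithmetic
# ---------------------------------------------------------------------------

def compute_migration_ratio(m_m: float, m_i: float) -> float:
    """Migration ratio MR(%) = 100·m_m/m_i.

    ``m_m`` is the additive mass found in the food (ng) and ``m_i`` the
    initial amount in the film specimen (ng).  Values above 100 % are
    physically impossible but can arise from measurement noise; they are
    returned as-is with a warning.
    """
    if not m_i > 0:
        raise ValueError(f"initial amount m_i must be strictly positive, got {m_i!r}")
    if m_m < 0:
        raise ValueError(f"migrated amount m_m must be non-negative, got {m_m!r}")
    mr = 100.0 * m_m / m_i
    if mr > 100.0:
        warnings.warn(
            f"migration ratio {mr:.2f}% exceeds 100% (measurement noise?)",
            stacklevel=2,
        )
    return mr


# ---------------------------------------------------------------------------
# transcendental roots of tan q = -alpha q
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RootSet:
    """The first positive roots of ``tan q = −α q``, in ascending order.

    The n-th root lies strictly inside ``((n−½)π, nπ)``.  ``residuals``
    records ``|tan q_n + α q_n|``; note this raw residual is amplified by
    ``sec² q_n ≈ (α q_n)²`` near the left bracket edge, so for very large α
    it saturates well above the root-coordinate accuracy actually achieved.
    """

    alpha: float
    roots: np.ndarray
    residuals: np.ndarray

    def __len__(self) -> int:
        return len(self.roots)


def _char(q: float, alpha: float) -> float:
    # sign-stable form of tan q + alpha*q: same roots, no poles
    return math.sin(q) + alpha * q * math.cos(q)


def solve_roots(alpha: float, n_roots: int = 64, tol: float = 1e-10) -> RootSet:
    """Solve ``tan q = −α q`` for the first ``n_roots`` positive roots.

    Each root is bracketed in ``((n−½)π, nπ)`` where the pole-free form
    ``sin q + α q cos q`` changes sign, solved by Brent's method and
    polished with Newton steps on ``tan q + α q``.  Convergence is judged
    on the Newton correction (root-coordinate error) against ``tol``.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be strictly positive, got {alpha!r}")
    if n_roots < 1:
        raise ValueError(f"n_roots must be >= 1, got {n_roots!r}")

    roots = np.empty(n_roots)
    residuals = np.empty(n_roots)
    for n in range(1, n_roots + 1):
        lo = (n - 0.5) * math.pi
        hi = n * math.pi
        eps = 1e-13 * hi
        try:
            q = brentq(_char, lo + eps, hi - eps, args=(alpha,), xtol=1e-14, rtol=1e-15)
        except ValueError as exc:  # pragma: no cover - bracket is sign-changing by construction
            raise ArithmeticError(f"root bracketing failed in interval n={n}") from exc
        # Newton polish on f = tan q + alpha q (guard the pole at the left edge)
        correction = math.inf
        for _ in range(4):
            c = math.cos(q)
            if abs(c) < 1e-300:
                break
            t = math.tan(q)
            f = t + alpha * q
            fp = 1.0 + t * t + alpha
            correction = f / fp
            q_new = q - correction
            if lo < q_new < hi:
                q = q_new
            if abs(correction) < 1e-15 * q:
                break
        if abs(correction) > tol * max(1.0, q):
            raise ArithmeticError(
                f"root refinement did not converge in interval n={n} "
                f"(correction {correction:.3e})"
            )
        roots[n - 1] = q
        residuals[n - 1] = abs(math.tan(q) + alpha * q)
    return RootSet(alpha=alpha, roots=roots, residuals=residuals)


@lru_cache(maxsize=4096)
def _cached_roots(alpha: float, n_roots: int) -> tuple[float, ...]:
    return tuple(solve_roots(alpha, n_roots).roots)


def series_coefficients(alpha: float, roots: np.ndarray) -> np.ndarray:
    """Series weights ``2α(1+α)/(1+α+α²q_n²)``; they sum to 1 over all n."""
    return 2.0 * alpha * (1.0 + alpha) / (1.0 + alpha + alpha**2 * roots**2)


# ---------------------------------------------------------------------------
# series solution
# ---------------------------------------------------------------------------

def _terms_needed(tau_min: float, tol: float, cap: int) -> int:
    # coefficients are < 1 and q_n ~ n*pi, so term n < exp(-tau * (n pi)^2)
    if tau_min <= 0:
        return cap
    n = math.sqrt(max(math.log(1.0 / tol), 1.0) / tau_min) / math.pi
    return min(cap, max(4, int(math.ceil(n)) + 2))


def series_fraction(
    d_cm2_s: float,
    t_s: float | Sequence[float] | np.ndarray,
    thickness_cm: float,
    alpha: float,
    n_terms: int = 200,
    tol: float = 1e-12,
) -> np.ndarray | float:
    """Fraction of the equilibrium migration reached at time(s) ``t_s``.

    Evaluates the limited-volume sorption series with adaptive truncation:
    the number of retained terms is chosen so the first neglected term is
    below ``tol`` at the smallest positive time, capped at ``n_terms`` (a
    warning is emitted if the cap binds).  ``t = 0`` returns exactly 0 and
    results are clamped to [0, 1].
    """
    if not d_cm2_s > 0:
        raise ValueError(f"D must be strictly positive, got {d_cm2_s!r}")
    if not thickness_cm > 0:
        raise ValueError(f"thickness must be strictly positive, got {thickness_cm!r}")
    t = np.asarray(t_s, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")

    tau = d_cm2_s * t / thickness_cm**2
    positive = tau > 0
    out = np.zeros_like(tau)
    if positive.any():
        tau_min = tau[positive].min()
        n_used = _terms_needed(tau_min, tol, n_terms)
        if n_used >= n_terms and _terms_needed(tau_min, tol, n_terms + 1) > n_terms:
            warnings.warn(
                f"series truncated at the {n_terms}-term cap; requested tolerance "
                f"{tol:g} may not be met at the smallest time",
                stacklevel=2,
            )
        roots = np.array(_cached_roots(alpha, n_used))
        coeff = series_coefficients(alpha, roots)
        decay = np.exp(-np.outer(tau[positive], roots**2))
        out[positive] = 1.0 - decay @ coeff
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def migration_ratio_model(
    d_cm2_s: float,
    alpha: float,
    thickness_cm: float,
    times_h: Sequence[float] | np.ndarray,
    n_terms: int = 200,
) -> np.ndarray:
    """Model migration ratio MR(t)% at contact times given in hours."""
    t_s = np.asarray(times_h, dtype=float) * SECONDS_PER_HOUR
    frac = series_fraction(d_cm2_s, t_s, thickness_cm, alpha, n_terms=n_terms)
    return 100.0 * equilibrium_fraction(alpha) * np.atleast_1d(frac)


# ---------------------------------------------------------------------------
# observed curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationCurve:
    """An observed (or simulated) migration time series for one pair.

    ``mr_percent`` holds replicate means; ``mr_sd`` the replicate standard
    deviations (zeros when n_replicates == 1).
    """

    compound: str
    food: str
    times_h: np.ndarray
    mr_percent: np.ndarray
    mr_sd: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        mr = np.asarray(self.mr_percent, dtype=float)
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "mr_percent", mr)
        if self.mr_sd is not None:
            object.__setattr__(self, "mr_sd", np.asarray(self.mr_sd, dtype=float))
        if times.ndim != 1 or times.size != mr.size:
            raise ValueError("times_h and mr_percent must be 1-D with equal length")
        if self.mr_sd is not None and self.mr_sd.size != times.size:
            raise ValueError("mr_sd length mismatch")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any(mr < 0):
            raise ValueError("mr_percent must be non-negative")


def migration_curve_model(
    d_cm2_s: float,
    alpha: float,
    thickness_cm: float,
    times_h: Sequence[float] | np.ndarray,
    compound: str = "",
    food: str = "",
) -> MigrationCurve:
    """Noise-free model curve as a :class:`MigrationCurve`."""
    mr = migration_ratio_model(d_cm2_s, alpha, thickness_cm, times_h)
    times = np.asarray(times_h, dtype=float)
    return MigrationCurve(
        compound=compound,
        food=food,
        times_h=times,
        mr_percent=mr,
        mr_sd=np.zeros_like(times),
        n_replicates=1,
    )


# ---------------------------------------------------------------------------
# finite-volume PDE oracle
# ---------------------------------------------------------------------------

def pde_oracle(
    d_cm2_s: float,
    alpha: float,
    thickness_cm: float,
    times_h: Sequence[float] | np.ndarray,
    nx: int = 800,
) -> tuple[np.ndarray, float]:
    """Numerically solve Fick's second law with a well-mixed finite bath.

    Solves ∂C/∂t = D ∂²C/∂x² on a cell-centred grid of ``nx`` cells over
    0 ≤ x ≤ L with a zero-flux face at x = 0 and, at x = L, an interface in
    local partition equilibrium with a well-stirred bath of dimensionless
    capacity α.  The semi-discrete system conserves total mass identically
    and is advanced *exactly* in time through the eigendecomposition of the
    (symmetrised) discrete operator, so the only error is spatial.

    Returns ``(fractions, mass_error)`` where ``fractions`` is
    M_F,t/M_F,∞ at each requested time and ``mass_error`` is the largest
    relative deviation of total mass from its initial value.
    """
    if nx < 100:
        raise ValueError(f"nx must be >= 100 for a trustworthy oracle, got {nx!r}")
    if not alpha > 0:
        raise ValueError(f"alpha must be strictly positive, got {alpha!r}")
    t_s = np.asarray(times_h, dtype=float) * SECONDS_PER_HOUR
    if np.any(t_s < 0):
        raise ValueError("times must be non-negative")

    h = 1.0 / nx  # dimensionless cell width
    # state y = [u_1..u_nx, b]; u cell-average concentration / C0, b = K*C_F/C0
    # interior: du/dtau = (u_{i-1} - 2u_i + u_{i+1})/h^2
    # left face: zero flux; right face: flux 2(u_N - b)/h into the bath
    # bath: alpha db/dtau = 2(u_N - b)/h
    n = nx + 1
    main = np.empty(n)
    off = np.empty(n - 1)
    main[0] = -1.0 / h**2
    main[1 : nx - 1] = -2.0 / h**2
    main[nx - 1] = -(1.0 / h + 2.0 / h) / h
    main[nx] = -2.0 / (h * alpha)
    off[: nx - 1] = 1.0 / h**2
    off[nx - 1] = 2.0 / (h * alpha)  # placeholder, fixed by symmetrisation below

    # weights of the conserved inner product: w_i = h for cells, w_b = alpha
    # symmetrise A under W: S = W^{1/2} A W^{-1/2}; S is tridiagonal symmetric
    # coupling terms: A[N-1, b] = 2/h^2 (cell eq), A[b, N-1] = 2/(h alpha)
    # => S off-diagonal = sqrt(A_ij * A_ji) with consistent sign (+)
    off[nx - 1] = math.sqrt((2.0 / h**2) * (2.0 / (h * alpha)))

    evals, evecs = eigh_tridiagonal(main, off)
    # y(tau) = W^{-1/2} V exp(L tau) V^T W^{1/2} y0
    sqrt_w = np.empty(n)
    sqrt_w[:nx] = math.sqrt(h)
    sqrt_w[nx] = math.sqrt(alpha)
    y0 = np.zeros(n)
    y0[:nx] = 1.0
    z0 = evecs.T @ (sqrt_w * y0)

    tau = d_cm2_s * t_s / thickness_cm**2
    bath = np.empty(tau.size)
    mass_err = 0.0
    mass0 = h * nx  # = 1, total initial dimensionless mass
    for k, tk in enumerate(tau):
        z = z0 * np.exp(evals * tk)
        y = (evecs @ z) / sqrt_w
        bath[k] = y[nx]
        mass = h * y[:nx].sum() + alpha * y[nx]
        mass_err = max(mass_err, abs(mass - mass0) / mass0)
    # M_F,t / M_F,inf = alpha*b / (alpha/(1+alpha)) = b (1+alpha)
    fractions = np.clip(bath * (1.0 + alpha), 0.0, 1.0)
    return fractions, mass_err


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

FitMode = Literal["fix_alpha_from_plateau", "co_fit_alpha"]

_LOG10_D_BOUNDS = (-13.0, -9.0)
_ALPHA_BOUNDS = (1e-6, 1e3)


@dataclass(frozen=True)
class DiffusionFit:
    """Result of fitting the sorption series to an observed curve."""

    compound: str
    food: str
    d_cm2_s: float
    alpha: float
    k_pf: float
    r_squared: float
    n_terms_used: int
    converged: bool
    mode: str = "co_fit_alpha"


def _plateau_alpha(mr_last: float) -> float:
    mr = min(max(mr_last, 1e-6), 99.9)
    return mr / (100.0 - mr)


def fit_diffusion(
    curve: MigrationCurve,
    system: ContactSystem,
    mode: FitMode = "co_fit_alpha",
    n_terms: int = 64,
) -> DiffusionFit:
    """Estimate ``D`` (and optionally α) by least squares on MR(t).

    In ``fix_alpha_from_plateau`` mode α is set from the last observed
    point (treating it as the equilibrium plateau) and only ``log10 D`` is
    fitted; in ``co_fit_alpha`` mode α is fitted jointly, with the plateau
    value as the starting point.  ``log10 D`` is initialised by a coarse
    grid search over [−13, −9].
    """
    if curve.times_h.size < 4:
        raise ValueError("at least 4 time points are required to fit")
    obs = curve.mr_percent
    if np.all(obs == 0):
        raise ValueError("all-zero migration curve cannot be fitted")
    thickness = system.film.thickness_cm
    alpha0 = _plateau_alpha(float(obs[-1]))

    def model(log10_d: float, alpha: float) -> np.ndarray:
        # the truncation warning is irrelevant while scanning tiny D values,
        # where the model is ~0 regardless of the neglected terms
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return migration_ratio_model(
                10.0**log10_d, alpha, thickness, curve.times_h, n_terms=n_terms
            )

    grid = np.arange(_LOG10_D_BOUNDS[0], _LOG10_D_BOUNDS[1] + 0.25, 0.5)
    sse = [float(np.sum((model(g, alpha0) - obs) ** 2)) for g in grid]
    log10_d0 = float(grid[int(np.argmin(sse))])

    if mode == "fix_alpha_from_plateau":
        def resid(x: np.ndarray) -> np.ndarray:
            return model(x[0], alpha0) - obs

        x0 = np.array([log10_d0])
        lo = np.array([_LOG10_D_BOUNDS[0]])
        hi = np.array([_LOG10_D_BOUNDS[1]])
    elif mode == "co_fit_alpha":
        def resid(x: np.ndarray) -> np.ndarray:
            return model(x[0], x[1]) - obs

        x0 = np.array([log10_d0, alpha0])
        lo = np.array([_LOG10_D_BOUNDS[0], _ALPHA_BOUNDS[0]])
        hi = np.array([_LOG10_D_BOUNDS[1], _ALPHA_BOUNDS[1]])
    else:
        raise ValueError(f"unknown fit mode {mode!r}")

    result = least_squares(
        resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    d_fit = 10.0 ** float(result.x[0])
    alpha_fit = alpha0 if mode == "fix_alpha_from_plateau" else float(result.x[1])
    ss_res = float(np.sum(result.fun**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DiffusionFit(
        compound=curve.compound,
        food=curve.food,
        d_cm2_s=d_fit,
        alpha=alpha_fit,
        k_pf=partition_from_alpha(alpha_fit, system),
        r_squared=r2,
        n_terms_used=n_terms,
        converged=bool(result.success),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def read_migration_table(
    path, system: ContactSystem | None = None
) -> list[MigrationCurve]:
    """Read migration curves from a delimited text table.

    Expected columns: ``compound, food, time_h, replicate`` and either
    ``mr_percent`` or ``conc_ng_ml`` (the latter is converted to MR via the
    film's initial amount and the food volume, requiring ``system``).
    Replicates are averaged; the sample standard deviation is retained.
    """
    df = pd.read_csv(path)
    required = {"compound", "food", "time_h", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if "mr_percent" not in df.columns:
        if "conc_ng_ml" not in df.columns:
            raise ValueError("need either 'mr_percent' or 'conc_ng_ml' column")
        if system is None:
            raise ValueError("a ContactSystem is required to convert concentrations")
        m_i = system.film.initial_amount_ng
        df = df.assign(
            mr_percent=100.0 * df["conc_ng_ml"] * system.food_volume_ml / m_i
        )
    curves = []
    for (compound, food), group in df.groupby(["compound", "food"], sort=True):
        stats = (
            group.groupby("time_h")["mr_percent"]
            .agg(["mean", "std", "count"])
            .sort_index()
            .fillna({"std": 0.0})
        )
        curves.append(
            MigrationCurve(
                compound=str(compound),
                food=str(food),
                times_h=stats.index.to_numpy(dtype=float),
                mr_percent=stats["mean"].to_numpy(),
                mr_sd=stats["std"].to_numpy(),
                n_replicates=int(stats["count"].max()),
            )
        )
    return curves


def fits_to_frame(fits: Sequence[DiffusionFit]) -> pd.DataFrame:
    """Arrange fit results as a table mirroring the fitted-parameter report."""
    return pd.DataFrame(
        {
            "food": [f.food for f in fits],
            "compound": [f.compound for f in fits],
            "alpha": [f.alpha for f in fits],
            "k_pf": [f.k_pf for f in fits],
            "d_cm2_s": [f.d_cm2_s for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "n_terms": [f.n_terms_used for f in fits],
            "converged": [f.converged for f in fits],
            "mode": [f.mode for f in fits],
        }
    )
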