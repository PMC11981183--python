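"""Temperature-dependent development-rate models.

Fits the three standard descriptions of an insect's thermal performance
curve to per-temperature mean development rates (rate = 1/mean duration in
days):

* **linear degree-day model** ``r(T) = a + b·T`` — valid over the
  intermediate, near-linear range; yields the thermal constant
  ``K = 1/b`` (degree-days) and lower threshold ``t_min = −a/b``;
* **Brière-1** ``r(T) = a·T·(T − t_min)·√(t_max − T)`` on
  ``[t_min, t_max]`` and 0 outside — an asymmetric 3-parameter curve with
  explicit lower and upper limits;
* **Lactin-2** ``r(T) = exp(ρT) − exp(ρ·t_max_param − (t_max_param − T)/Δ) + λ``
  — a 4-parameter curve whose zero-crossings define the thermal limits and
  whose argmax is the optimum.

Nonlinear fits use multi-start Levenberg–Marquardt least squares over a
fixed grid of initial values; the converged start with the lowest residual
sum of squares wins (ties broken by grid order), which makes fitting fully
deterministic. Derived thresholds come from bisection on sign changes of
the fitted curve and bounded maximization for the optimum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RatePoint",
    "FitDiagnostics",
    "LinearFit",
    "Briere1Fit",
    "Lactin2Fit",
    "make_rate_points",
    "fit_linear",
    "briere1_rate",
    "lactin2_rate",
    "briere1_topt_closed_form",
    "fit_nonlinear",
    "compare_models",
    "predict_duration",
    "ThermalFitError",
]


class ThermalFitError(RuntimeError):
    """A model could not be fitted to the supplied rate points."""


@dataclass(frozen=True)
class RatePoint:
    """Mean development rate at one temperature.

    ``rate_per_day`` is the reciprocal of the mean duration. A zero-rate
    point (no development at that temperature) is represented with an
    infinite duration via :meth:`zero_rate`.
    """

    temperature_c: float
    mean_duration_days: float
    n: int = 0

    def __post_init__(self):
        if not self.mean_duration_days > 0:
            raise ValueError("mean_duration_days must be positive")

    @property
    def rate_per_day(self) -> float:
        return 0.0 if math.isinf(self.mean_duration_days) else 1.0 / self.mean_duration_days

    @classmethod
    def zero_rate(cls, temperature_c: float, n: int = 0) -> "RatePoint":
        """A point recording that development fails at ``temperature_c``."""
        return cls(temperature_c=temperature_c, mean_duration_days=math.inf, n=n)


@dataclass(frozen=True)
class FitDiagnostics:
    r_squared: float
    rss: float
    aic: float
    n_points: int
    n_params: int


@dataclass(frozen=True)
class LinearFit:
    """Degree-day model: rate = intercept_a + slope_b·T."""

    slope_b: float
    intercept_a: float
    diagnostics: FitDiagnostics

    @property
    def K_degree_days(self) -> float:
        return 1.0 / self.slope_b

    @property
    def t_min_c(self) -> float:
        return -self.intercept_a / self.slope_b

    def rate(self, temperature_c) -> float:
        return self.intercept_a + self.slope_b * np.asarray(temperature_c, dtype=float)


@dataclass(frozen=True)
class Briere1Fit:
    a_coeff: float
    t_min_c: float
    t_max_c: float
    t_opt_c: float
    diagnostics: FitDiagnostics

    def rate(self, temperature_c):
        return briere1_rate(temperature_c, self.a_coeff, self.t_min_c, self.t_max_c)


@dataclass(frozen=True)
class Lactin2Fit:
    rho: float
    t_max_param_c: float
    delta_width: float
    lambda_shift: float
    t_min_c: Optional[float]
    t_opt_c: float
    t_max_c: Optional[float]
    diagnostics: FitDiagnostics

    def rate(self, temperature_c):
        return lactin2_rate(
            temperature_c, self.rho, self.t_max_param_c, self.delta_width, self.lambda_shift
        )


# ---------------------------------------------------------------------------
# Rate points and the linear model
# ---------------------------------------------------------------------------


def make_rate_points(
    mean_durations: dict[float, float] | Iterable[tuple[float, float]] | Iterable[tuple[float, float, int]],
) -> list[RatePoint]:
    """Build temperature-ordered rate points from per-temperature mean durations.

    Accepts a mapping ``{temperature: mean duration}`` or an iterable of
    ``(temperature, mean_duration[, n])`` tuples. Temperatures where no
    individual completed development should simply be left out (or added
    afterwards with :meth:`RatePoint.zero_rate` for Lactin-2 fitting).
    """
    if isinstance(mean_durations, dict):
        items = [(t, d, 0) for t, d in mean_durations.items()]
    else:
        items = [tuple(it) + (0,) * (3 - len(tuple(it))) for it in mean_durations]
    return [
        RatePoint(temperature_c=float(t), mean_duration_days=float(d), n=int(n))
        for t, d, n in sorted(items)
    ]


def _diagnostics(rates: np.ndarray, fitted: np.ndarray, k: int) -> FitDiagnostics:
    rss = float(np.sum((rates - fitted) ** 2))
    tss = float(np.sum((rates - rates.mean()) ** 2))
    n = rates.size
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    # AIC up to a constant shared by all models on the same points:
    # n·ln(RSS/n) + 2k, with k the number of fitted parameters
    aic = n * math.log(rss / n) + 2 * k if rss > 0 else -math.inf
    return FitDiagnostics(r_squared=r2, rss=rss, aic=aic, n_points=n, n_params=k)


def fit_linear(points: Sequence[RatePoint]) -> LinearFit:
    """Ordinary least squares of rate on temperature (degree-day model)."""
    if len(points) < 3:
        raise ThermalFitError("linear fit needs at least 3 rate points")
    T = np.array([p.temperature_c for p in points])
    r = np.array([p.rate_per_day for p in points])
    if np.unique(T).size < 2:
        raise ThermalFitError("all rate points share one temperature; design is singular")
    res = stats.linregress(T, r)
    fitted = res.intercept + res.slope * T
    return LinearFit(
        slope_b=float(res.slope),
        intercept_a=float(res.intercept),
        diagnostics=_diagnostics(r, fitted, k=2),
    )


def predict_duration(K_degree_days: float, t_min_c: float, temperature_c: float) -> float:
    """Expected development time K/(T − t_min) from the degree-day model."""
    if not temperature_c > t_min_c:
        raise ValueError(
            f"temperature {temperature_c} must exceed the lower threshold {t_min_c}; "
            "development time diverges at the threshold"
        )
    return K_degree_days / (temperature_c - t_min_c)


# ---------------------------------------------------------------------------
# Nonlinear model curves
# ---------------------------------------------------------------------------


def briere1_rate(temperature_c, a_coeff: float, t_min_c: float, t_max_c: float):
    """Brière-1 curve; exactly zero outside [t_min, t_max]."""
    if not t_min_c < t_max_c:
        raise ValueError("t_min_c must be below t_max_c")
    T = np.asarray(temperature_c, dtype=float)
    inside = (T >= t_min_c) & (T <= t_max_c)
    out = np.zeros_like(T)
    Ti = T[inside]
    out[inside] = a_coeff * Ti * (Ti - t_min_c) * np.sqrt(t_max_c - Ti)
    return out if out.ndim else float(out)


def lactin2_rate(temperature_c, rho: float, t_max_param_c: float, delta_width: float, lambda_shift: float):
    """Lactin-2 curve; real-valued, may be negative away from the optimum."""
    if delta_width == 0:
        raise ValueError("delta_width must be nonzero")
    T = np.asarray(temperature_c, dtype=float)
    with np.errstate(over="ignore"):
        out = (
            np.exp(rho * T)
            - np.exp(rho * t_max_param_c - (t_max_param_c - T) / delta_width)
            + lambda_shift
        )
    return out if out.ndim else float(out)


def briere1_topt_closed_form(t_min_c: float, t_max_c: float) -> float:
    """Analytic argmax of the Brière-1 curve on [t_min, t_max]."""
    return (
        4 * t_max_c
        + 3 * t_min_c
        + math.sqrt(16 * t_max_c**2 + 9 * t_min_c**2 - 16 * t_min_c * t_max_c)
    ) / 10


# ---------------------------------------------------------------------------
# Multi-start nonlinear fitting
# ---------------------------------------------------------------------------

#: Initial-value grids for the multi-start fits. Chosen to cover the
#: biologically plausible range for temperate insects; fitting is the best
#: converged start by RSS, ties broken by grid order, so results are
#: deterministic and independent of any RNG.
LACTIN2_START_GRID = {
    "rho": (0.05, 0.1, 0.15, 0.2),
    "t_max_param_c": (32.0, 35.0, 38.0, 41.0),
    "delta_width": (2.0, 5.0, 8.0),
    "lambda_shift": (-1.5, -1.0, -0.5, 0.0),
}
BRIERE1_START_GRID = {
    "a_coeff": (1e-5, 5e-5, 1e-4),
    "t_min_c": (0.0, 5.0, 10.0),
    "t_max_c": (33.0, 36.0, 40.0),
}

_BISECT_TOL_C = 1e-6


def _bisect_zero(f, lo: float, hi: float) -> Optional[float]:
    """Root of f on [lo, hi] by bisection; None if no sign change."""
    flo, fhi = f(lo), f(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if flo * fhi > 0:
        return None
    while hi - lo > _BISECT_TOL_C:
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if fmid == 0:
            return mid
        if flo * fmid < 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    return 0.5 * (lo + hi)


def _maximize(f, lo: float, hi: float) -> float:
    res = optimize.minimize_scalar(lambda t: -f(t), bounds=(lo, hi), method="bounded")
    return float(res.x)


def fit_nonlinear(
    points: Sequence[RatePoint],
    model: str,
    zero_rate_temps: Sequence[float] = (),
) -> "Briere1Fit | Lactin2Fit":
    """Fit a Brière-1 or Lactin-2 curve by multi-start least squares.

    ``zero_rate_temps`` appends zero-rate observations at temperatures where
    development is known to fail; anchoring the upper limb this way is how
    the Lactin-2 upper threshold becomes identifiable from a short series
    of viable temperatures.

    Raises :class:`ThermalFitError` when no start converges, listing the
    attempted starts.
    """
    points = list(points) + [RatePoint.zero_rate(t) for t in zero_rate_temps]
    points.sort(key=lambda p: p.temperature_c)
    T = np.array([p.temperature_c for p in points])
    r = np.array([p.rate_per_day for p in points])
    if model == "briere1":
        grid = BRIERE1_START_GRID
        k = 3

        def residuals(theta):
            a, tmin, tmax = theta
            if tmin >= tmax:
                return np.full_like(r, 1e6)
            return briere1_rate(T, a, tmin, tmax) - r

    elif model == "lactin2":
        grid = LACTIN2_START_GRID
        k = 4

        def residuals(theta):
            with np.errstate(over="ignore", invalid="ignore"):
                vals = lactin2_rate(T, *theta) - r
            return np.nan_to_num(vals, nan=1e6, posinf=1e6, neginf=-1e6)

    else:
        raise ValueError(f"model must be 'briere1' or 'lactin2', got {model!r}")

    if len(points) < k + 1:
        raise ThermalFitError(f"{model} needs at least {k + 1} rate points")

    starts = list(itertools.product(*grid.values()))
    best_rss, best_theta = math.inf, None
    for start in starts:
        try:
            res = optimize.least_squares(
                residuals, x0=np.array(start), method="lm", max_nfev=20000
            )
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun**2))
        if rss < best_rss:  # strict: ties keep the earlier grid start
            best_rss, best_theta = rss, res.x
    if best_theta is None:
        raise ThermalFitError(
            f"no converged {model} start; attempted {len(starts)} initial values "
            f"over grid {grid}"
        )

    diagnostics = _diagnostics(r, r + residuals(best_theta), k=k)
    if model == "briere1":
        a, tmin, tmax = (float(v) for v in best_theta)
        topt = _maximize(lambda t: briere1_rate(t, a, tmin, tmax), tmin, tmax)
        return Briere1Fit(a_coeff=a, t_min_c=tmin, t_max_c=tmax, t_opt_c=topt, diagnostics=diagnostics)

    rho, tmaxp, delta, lam = (float(v) for v in best_theta)
    curve = lambda t: lactin2_rate(t, rho, tmaxp, delta, lam)  # noqa: E731
    upper_search = max(tmaxp, T.max() + 5.0)
    topt = _maximize(curve, -20.0, upper_search)
    tmin = _bisect_zero(curve, -20.0, topt)
    tmax = _bisect_zero(curve, topt, upper_search + 50.0)
    return Lactin2Fit(
        rho=rho,
        t_max_param_c=tmaxp,
        delta_width=delta,
        lambda_shift=lam,
        t_min_c=tmin,
        t_opt_c=topt,
        t_max_c=tmax,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def compare_models(fits: dict[str, "LinearFit | Briere1Fit | Lactin2Fit"]):
    """Rank fitted models by R² (higher better), RSS and AIC (lower better).

    Returns a pandas DataFrame with one row per model and a rank column per
    criterion. Fits must come from the same rate points for the comparison
    to be meaningful.
    """
    import pandas as pd

    rows = []
    for name, fit in fits.items():
        d = fit.diagnostics
        rows.append(
            {
                "model": name,
                "n_params": d.n_params,
                "r_squared": d.r_squared,
                "rss": d.rss,
                "aic": d.aic,
            }
        )
    table = pd.DataFrame(rows)
    table["rank_r_squared"] = table["r_squared"].rank(ascending=False, method="min").astype(int)
    table["rank_rss"] = table["rss"].rank(ascending=True, method="min").astype(int)
    table["rank_aic"] = table["aic"].rank(ascending=True, method="min").astype(int)
    return table.set_index("model")
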