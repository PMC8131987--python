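"""Two-state thermal unfolding model and nonlinear least-squares fitting.

The observed spectroscopic signal of a protein undergoing reversible two-state
unfolding (N ⇌ D) is modelled as a population-weighted average of two linear
temperature baselines,

    I(T) = [I_N + a·T + (I_D + b·T)·K(T)] / (1 + K(T)),

with a van't Hoff equilibrium constant

    K(T) = exp[(ΔH_vh / R) · (1/Tm − 1/T)].

``Tm`` is the temperature at which half the molecules are unfolded
(K(Tm) = 1), ``ΔH_vh`` the van't Hoff enthalpy controlling the sharpness of
the transition, ``I_N + a·T`` the native baseline and ``I_D + b·T`` the
denatured baseline.  All temperatures inside this module are absolute
(Kelvin); Celsius↔Kelvin conversion happens at the I/O boundary.

Fitting is performed on a truncated temperature window (default 330–363 K)
so that only the most linear portions of the baselines constrain the model.
Per-curve fits and a multi-wavelength global fit sharing a single ΔH_vh are
provided; both are trust-region least-squares fits via lmfit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import lmfit
import numpy as np

__all__ = [
    "R_GAS",
    "DEFAULT_WINDOW",
    "TwoStateParams",
    "UnfoldingCurve",
    "FitResult",
    "equilibrium_constant",
    "fraction_unfolded",
    "two_state_intensity",
    "truncate_curve",
    "fit_two_state",
    "global_fit_shared_enthalpy",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: Gas constant, J/(mol·K).
R_GAS = 8.314

#: Default truncation window for fitting, Kelvin (≈57–90 °C).
DEFAULT_WINDOW = (330.0, 363.0)

#: Bounds keeping the optimizer away from divergent regions.
TM_BOUNDS = (300.0, 400.0)  # K
DHVH_BOUNDS = (50e3, 2000e3)  # J/mol

#: Number of free parameters of the single-curve model.
N_FREE_PARAMS = 6


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


@dataclass
class TwoStateParams:
    """Parameters of the two-state unfolding signal model.

    Units: ``I_N``, ``I_D`` in a.u.; ``a``, ``b`` in a.u./K; ``Tm`` in K;
    ``dHvh`` in J/mol.
    """

    I_N: float
    a: float
    I_D: float
    b: float
    Tm: float
    dHvh: float

    def validate(self) -> None:
        if not self.Tm > 0:
            raise ValueError(f"Tm must be positive, got {self.Tm}")
        if not self.dHvh > 0:
            raise ValueError(f"dHvh must be positive, got {self.dHvh}")
        if not (self.I_N + self.a * self.Tm > 0
                and self.I_D + self.b * self.Tm > 0):
            raise ValueError("baselines must be positive at the midpoint")

    def as_dict(self) -> dict:
        return {
            "I_N": self.I_N, "a": self.a, "I_D": self.I_D, "b": self.b,
            "Tm": self.Tm, "dHvh": self.dHvh,
        }


@dataclass
class UnfoldingCurve:
    """A single-wavelength melting curve: intensity versus temperature (K)."""

    temperatures: np.ndarray
    intensities: np.ndarray
    wavelength: Optional[float] = None
    condition: object = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.temperatures.shape != self.intensities.shape:
            raise ValueError(
                f"temperature/intensity length mismatch: "
                f"{self.temperatures.shape} vs {self.intensities.shape}"
            )
        if self.temperatures.ndim != 1:
            raise ValueError("curve arrays must be one-dimensional")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass
class FitResult:
    """Outcome of a two-state fit on one curve."""

    params: TwoStateParams
    standard_errors: dict = field(default_factory=dict)
    residual_sum_of_squares: float = np.nan
    converged: bool = False
    n_points_used: int = 0


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    return T


def equilibrium_constant(params: TwoStateParams, T):
    """Van't Hoff equilibrium constant K(T) = exp[(ΔH/R)(1/Tm − 1/T)]."""
    T = _check_temperature(T)
    return np.exp((params.dHvh / R_GAS) * (1.0 / params.Tm - 1.0 / T))


def fraction_unfolded(params: TwoStateParams, T):
    """Unfolded population fraction f = K/(1+K); f(Tm) = 1/2."""
    K = equilibrium_constant(params, T)
    return K / (1.0 + K)


def two_state_intensity(params: TwoStateParams, T):
    """Observed intensity: population-weighted average of the two baselines."""
    T = _check_temperature(T)
    f = fraction_unfolded(params, T)
    native = params.I_N + params.a * T
    denatured = params.I_D + params.b * T
    return (1.0 - f) * native + f * denatured


def truncate_curve(curve: UnfoldingCurve,
                   window: Sequence[float] = DEFAULT_WINDOW) -> UnfoldingCurve:
    """Restrict a curve to ``window[0] ≤ T ≤ window[1]`` (K).

    Raises if fewer than 6 points survive: the two-state model has six free
    parameters and the fit would be under-determined.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"invalid window {window}: lower bound must be below upper")
    keep = (curve.temperatures >= lo) & (curve.temperatures <= hi)
    n = int(keep.sum())
    if n < N_FREE_PARAMS:
        raise ValueError(
            f"only {n} points remain in window [{lo}, {hi}] K; "
            f"need at least {N_FREE_PARAMS} for a two-state fit"
        )
    return UnfoldingCurve(
        temperatures=curve.temperatures[keep],
        intensities=curve.intensities[keep],
        wavelength=curve.wavelength,
        condition=curve.condition,
    )


def _initial_guess(t: np.ndarray, y: np.ndarray) -> TwoStateParams:
    """Data-driven initialization: lines through the first/last 4 points,
    Tm at the steepest point of the 3-point-smoothed curve, ΔH = 400 kJ/mol."""
    a, I_N = np.polyfit(t[:4], y[:4], 1)
    b, I_D = np.polyfit(t[-4:], y[-4:], 1)
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(y, kernel, mode="same")
    slope = np.gradient(smooth, t)
    # ignore the edge points, which the moving average distorts
    interior = slice(1, len(t) - 1)
    i = 1 + int(np.argmax(np.abs(slope[interior])))
    tm0 = float(np.clip(t[i], TM_BOUNDS[0] + 1.0, TM_BOUNDS[1] - 1.0))
    return TwoStateParams(I_N=I_N, a=a, I_D=I_D, b=b, Tm=tm0, dHvh=400e3)


def _make_lm_params(init: TwoStateParams, prefix: str = "",
                    shared_dhvh: bool = False) -> lmfit.Parameters:
    p = lmfit.Parameters()
    p.add(f"{prefix}I_N", value=init.I_N)
    p.add(f"{prefix}a", value=init.a)
    p.add(f"{prefix}I_D", value=init.I_D)
    p.add(f"{prefix}b", value=init.b)
    p.add(f"{prefix}Tm", value=init.Tm, min=TM_BOUNDS[0], max=TM_BOUNDS[1])
    if not shared_dhvh:
        p.add(f"{prefix}dHvh", value=init.dHvh,
              min=DHVH_BOUNDS[0], max=DHVH_BOUNDS[1])
    return p


def _params_from_lm(values: dict, prefix: str = "",
                    dhvh_key: str = None) -> TwoStateParams:
    dhvh_key = dhvh_key or f"{prefix}dHvh"
    return TwoStateParams(
        I_N=values[f"{prefix}I_N"], a=values[f"{prefix}a"],
        I_D=values[f"{prefix}I_D"], b=values[f"{prefix}b"],
        Tm=values[f"{prefix}Tm"], dHvh=values[dhvh_key],
    )


_FIT_KW = dict(method="least_squares", ftol=1e-10, xtol=1e-10, gtol=1e-10,
               max_nfev=5000)


def _stderr_dict(result, prefix: str = "", dhvh_key: str = None) -> dict:
    dhvh_key = dhvh_key or f"{prefix}dHvh"
    names = {"I_N": f"{prefix}I_N", "a": f"{prefix}a", "I_D": f"{prefix}I_D",
             "b": f"{prefix}b", "Tm": f"{prefix}Tm", "dHvh": dhvh_key}
    out = {}
    for short, full in names.items():
        se = result.params[full].stderr
        out[short] = float(se) if se is not None and np.isfinite(se) else np.inf
    return out


def fit_two_state(curve: UnfoldingCurve,
                  init: Optional[TwoStateParams] = None,
                  window: Optional[Sequence[float]] = DEFAULT_WINDOW) -> FitResult:
    """Fit the two-state model to one curve by trust-region least squares.

    ``window=None`` fits the full curve.  An unidentifiable curve (e.g. no
    transition in the window) is reported via ``converged=False`` or an
    inflated ``Tm`` standard error, not an exception.
    """
    work = truncate_curve(curve, window) if window is not None else curve
    if len(work) < N_FREE_PARAMS:
        raise ValueError("under-determined fit: fewer than 6 points")
    t, y = work.temperatures, work.intensities

    if init is not None:
        guesses = [init]
    else:
        # multi-start: the data-driven guess plus midpoints spread over the
        # window, so a distorted steepest-slope estimate cannot strand the
        # optimizer in a runaway basin
        base = _initial_guess(t, y)
        guesses = [base] + [replace(base, Tm=float(tm))
                            for tm in np.quantile(t, [0.35, 0.6, 0.85])]

    def residual(p):
        ps = _params_from_lm(p.valuesdict())
        return two_state_intensity(ps, t) - y

    best = None
    for guess in guesses:
        result = lmfit.minimize(residual, _make_lm_params(guess), **_FIT_KW)
        rss = float(np.sum(np.asarray(result.residual) ** 2))
        if best is None or rss < best[1]:
            best = (result, rss)
    result, rss = best
    fitted = _params_from_lm(result.params.valuesdict())
    return FitResult(
        params=fitted,
        standard_errors=_stderr_dict(result),
        residual_sum_of_squares=rss,
        converged=bool(result.success),
        n_points_used=len(work),
    )


def global_fit_shared_enthalpy(curves: Sequence[UnfoldingCurve],
                               window: Optional[Sequence[float]] = DEFAULT_WINDOW,
                               ) -> tuple[list[FitResult], float, float]:
    """Global fit across wavelengths with one shared van't Hoff enthalpy.

    Every curve keeps its own baselines and Tm; a single ``dHvh`` is shared.
    The objective is the pooled residual sum of squares over all curves.

    Returns ``(per_curve_results, shared_dHvh, shared_dHvh_se)``; each
    per-curve ``FitResult`` carries the shared enthalpy in its params and
    its own residual sum of squares.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    works = [truncate_curve(c, window) if window is not None else c
             for c in curves]
    guesses = [_initial_guess(w.temperatures, w.intensities) for w in works]

    lm_params = lmfit.Parameters()
    dhvh0 = float(np.mean([g.dHvh for g in guesses]))
    lm_params.add("dHvh", value=dhvh0, min=DHVH_BOUNDS[0], max=DHVH_BOUNDS[1])
    for i, g in enumerate(guesses):
        for name, value in _make_lm_params(g, prefix=f"c{i}_",
                                           shared_dhvh=True).items():
            lm_params[name] = value

    def residual(p):
        vals = p.valuesdict()
        parts = []
        for i, w in enumerate(works):
            ps = _params_from_lm(vals, prefix=f"c{i}_", dhvh_key="dHvh")
            parts.append(two_state_intensity(ps, w.temperatures) - w.intensities)
        return np.concatenate(parts)

    result = lmfit.minimize(residual, lm_params, **_FIT_KW)
    vals = result.params.valuesdict()
    shared = float(vals["dHvh"])
    se = result.params["dHvh"].stderr
    shared_se = float(se) if se is not None and np.isfinite(se) else np.inf

    fits = []
    for i, w in enumerate(works):
        ps = _params_from_lm(vals, prefix=f"c{i}_", dhvh_key="dHvh")
        res = two_state_intensity(ps, w.temperatures) - w.intensities
        fits.append(FitResult(
            params=ps,
            standard_errors=_stderr_dict(result, prefix=f"c{i}_",
                                         dhvh_key="dHvh"),
            residual_sum_of_squares=float(np.sum(res ** 2)),
            converged=bool(result.success),
            n_points_used=len(w),
        ))
    return fits, shared, shared_se
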