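"""Photosynthesis-irradiance (P-E) response fitting.

The saturating model is the hyperbolic-tangent light response

    P(E) = Pmax * tanh(E / Ek) - R,

with P the hourly net benthic flux (mmol m-2 h-1), E the PAR
(µmol quanta m-2 s-1), Pmax the maximum gross production rate, Ek the
saturation irradiance and R the dark respiration rate. Under light-limited
conditions (no saturation in the sampled E range) a linear response
P = alpha*E - R is fitted instead; when even the linear light coefficient
is indistinguishable from zero a flat (respiration-only) model is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class PEFit:
    """Fitted light response.

    ``model`` is one of "tanh", "linear", "flat". ``ec`` is the
    compensation irradiance (PAR at P = 0), defined for tanh fits with
    0 < R < Pmax. For linear fits ``alpha`` is the initial slope.
    """

    model: str
    pmax: float | None
    ek: float | None
    r: float
    alpha: float | None
    r_squared: float
    ec: float | None = None
    flags: tuple[str, ...] = ()

    def predict(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        if self.model == "tanh":
            return self.pmax * np.tanh(e / self.ek) - self.r
        if self.model == "linear":
            return self.alpha * e - self.r
        return np.full_like(e, -self.r)


def pe_tanh(e: np.ndarray, pmax: float, ek: float, r: float) -> np.ndarray:
    """Saturating light response Pmax*tanh(E/Ek) - R."""
    return pmax * np.tanh(np.asarray(e, float) / ek) - r


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _fit_linear(e: np.ndarray, p: np.ndarray) -> tuple[float, float, float, float]:
    """OLS P = alpha*E - R. Returns (alpha, r, r2, alpha_se)."""
    res = stats.linregress(e, p)
    return (float(res.slope), float(-res.intercept),
            float(res.rvalue ** 2), float(res.stderr))


def _fit_tanh(e: np.ndarray, p: np.ndarray) -> tuple[float, float, float] | None:
    """Nonlinear least squares for (Pmax, Ek, R); None on failure."""
    pmax0 = max(float(np.max(p) - np.min(p)), 1e-6)
    epos = e[e > 0]
    ek0 = float(np.median(epos)) if len(epos) else 1.0
    night = p[e <= 2.0]
    r0 = float(-np.mean(night)) if len(night) else float(-np.min(p))
    try:
        popt, _ = optimize.curve_fit(
            pe_tanh, e, p, p0=[pmax0, max(ek0, 1e-3), r0],
            maxfev=20000,
            bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]))
    except (RuntimeError, ValueError):
        return None
    return float(popt[0]), float(popt[1]), float(popt[2])


def saturation_check(e: np.ndarray, p: np.ndarray,
                     ek_fraction: float = 0.8,
                     min_ss_gain: float = 0.05) -> str:
    """Decide between the saturating and the linear light model.

    The tanh model is selected only if its fitted Ek lies inside the sampled
    light range (Ek < ek_fraction * max(E)) — i.e. saturation was actually
    observed — and it reduces the residual sum of squares by more than
    ``min_ss_gain`` relative to the linear fit. Otherwise "linear".
    """
    e = np.asarray(e, float)
    p = np.asarray(p, float)
    if len(e) < 6:
        raise ValueError("need at least 6 (E, P) pairs")
    tanh_fit = _fit_tanh(e, p)
    if tanh_fit is None:
        return "linear"
    pmax, ek, r = tanh_fit
    if ek >= ek_fraction * float(np.max(e)):
        return "linear"
    ss_tanh = float(np.sum((p - pe_tanh(e, pmax, ek, r)) ** 2))
    alpha, rl, _, _ = _fit_linear(e, p)
    ss_lin = float(np.sum((p - (alpha * e - rl)) ** 2))
    if ss_lin <= 0:
        return "linear"
    return "tanh" if ss_tanh < (1.0 - min_ss_gain) * ss_lin else "linear"


def fit_pe(e: np.ndarray, p: np.ndarray) -> PEFit:
    """Fit the light response to hourly (PAR, flux) pairs.

    Requires at least 6 pairs spanning day and night. Model selection
    follows :func:`saturation_check`; non-convergent tanh fits fall back to
    the linear model with a flag; a linear light coefficient whose 95% CI
    spans zero yields a flat (respiration-only) model, as seen in seasons
    with no light response.
    """
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(e) != len(p):
        raise ValueError("E and P lengths differ")
    if len(e) < 6:
        raise ValueError("need at least 6 (E, P) pairs")

    if np.ptp(e) == 0:
        # no light variation: only respiration is identifiable
        return PEFit("flat", None, None, float(-np.mean(p)), None,
                     float("nan"), flags=("no_light_variation",))

    flags: list[str] = []
    model = saturation_check(e, p)
    if model == "tanh":
        fitted = _fit_tanh(e, p)
        if fitted is None:
            model = "linear"
            flags.append("tanh_nonconvergent")
        else:
            pmax, ek, r = fitted
            r2 = _r_squared(p, pe_tanh(e, pmax, ek, r))
            ec = compensation_irradiance_values(pmax, ek, r)
            return PEFit("tanh", pmax, ek, r, None, r2, ec, tuple(flags))

    alpha, r, r2, alpha_se = _fit_linear(e, p)
    tcrit = stats.t.ppf(0.975, max(len(e) - 2, 1))
    if abs(alpha) <= tcrit * alpha_se:
        flags.append("light_coefficient_ns")
        return PEFit("flat", None, None, float(-np.mean(p)), None,
                     float("nan"), flags=tuple(flags))
    return PEFit("linear", None, None, r, alpha, r2, None, tuple(flags))


def compensation_irradiance_values(pmax: float, ek: float, r: float) -> float | None:
    """Ec = Ek * atanh(R/Pmax); None when 0 < R < Pmax fails."""
    if pmax is None or ek is None:
        return None
    if not 0 < r < pmax:
        return None
    return float(ek * np.arctanh(r / pmax))


def compensation_irradiance(fit: PEFit) -> float:
    """Compensation irradiance of a saturating fit (PAR at P = 0)."""
    if fit.model != "tanh":
        raise ValueError("compensation irradiance requires a tanh fit")
    ec = compensation_irradiance_values(fit.pmax, fit.ek, fit.r)
    if ec is None:
        raise ValueError("Ec undefined unless 0 < R < Pmax")
    return ec
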