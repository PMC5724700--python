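"""Water-column metabolism from bottle incubations.

Volumetric day/night O2 rates come from linear regressions of bottle O2
time series, partitioned by a PAR threshold; areal water-column rates
follow by multiplying with mean stream depth.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from scipy import stats

from .synthetic import BottleSet

#: PAR below this (µmol quanta m-2 s-1) counts as nighttime.
NIGHT_PAR_THRESHOLD = 2.0

#: areal rates below this (mmol m-2 d-1) are reported as below detection
DETECTION_FLOOR = 0.1

#: regressions with R^2 below this are flagged
MIN_R_SQUARED = 0.8


@dataclass
class VolumetricRates:
    """Depth-averaged volumetric water-column rates (µmol L-1 h-1)."""

    day_rate: float
    night_rate: float
    r2_day: float
    r2_night: float
    daylight_hours: float
    night_hours: float
    flags: list[str] = field(default_factory=list)


@dataclass
class ArealWaterRates:
    """Areal water-column metabolism (mmol m-2 d-1). ``gpp_below_detection``
    marks values stored as 0 but reported as "<0.1"."""

    er: float
    gpp: float
    nem: float
    gpp_below_detection: bool = False

    def render(self) -> dict:
        """Table-style strings, one decimal, "<0.1" below detection."""
        return {
            "ER_w": f"{self.er:.1f}",
            "GPP_w": "<0.1" if self.gpp_below_detection else f"{self.gpp:.1f}",
            "NEM_w": f"{self.nem:.1f}",
        }


def partition_day_night(par: np.ndarray,
                        threshold: float = NIGHT_PAR_THRESHOLD,
                        sample_interval_h: float | None = None
                        ) -> tuple[np.ndarray, float | None]:
    """Day/night mask from PAR: strictly below the threshold is night.

    Returns (day mask, daylight hours if the sampling interval is given).
    All-day or all-night series raise, since rate partitioning is then
    meaningless.
    """
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be non-negative")
    day = par >= threshold
    if day.all() or (~day).all():
        raise ValueError("PAR series never crosses the day/night threshold")
    daylight = float(day.sum() * sample_interval_h) if sample_interval_h else None
    return day, daylight


def fit_bottle_rate(time_h: np.ndarray, o2: np.ndarray,
                    mask: np.ndarray | None = None) -> tuple[float, float]:
    """Least-squares O2 drift rate (µmol L-1 h-1) over the masked span.

    Returns (slope, R^2). Requires at least 5 samples; a constant series
    returns rate 0 with R^2 = nan (degenerate fit, to be flagged upstream).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(o2, dtype=float)
    if mask is not None:
        t, y = t[mask], y[mask]
    if len(t) < 5:
        raise ValueError("need at least 5 samples for a rate fit")
    if np.ptp(y) == 0:
        return 0.0, float("nan")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.rvalue ** 2)


def analyze_bottle_set(bs: BottleSet,
                       threshold: float = NIGHT_PAR_THRESHOLD) -> VolumetricRates:
    """Volumetric day/night rates from a bottle set.

    Daytime rate: clear-bottle slopes over daylight samples, averaged across
    depth positions. Nighttime rate: dark-bottle slopes fitted separately
    over daytime and nighttime samples and averaged with equal weight.
    Fits with R^2 < 0.8 are flagged.
    """
    dt = float(np.median(np.diff(bs.time_h)))
    day, daylight = partition_day_night(bs.par, threshold, dt)
    flags: list[str] = []

    def _mean_r2(fits: list[tuple[float, float]]) -> float:
        finite = [r for _, r in fits if not np.isnan(r)]
        return float(np.mean(finite)) if finite else float("nan")

    day_fits = [fit_bottle_rate(bs.time_h, b.o2, day) for b in bs.clear()]
    day_rate = float(np.mean([s for s, _ in day_fits]))
    r2_day = _mean_r2(day_fits)

    dark_fits = []
    for b in bs.dark():
        dark_fits.append(fit_bottle_rate(bs.time_h, b.o2, day))
        dark_fits.append(fit_bottle_rate(bs.time_h, b.o2, ~day))
    night_rate = float(np.mean([s for s, _ in dark_fits]))
    r2_night = _mean_r2(dark_fits)

    for label, r2 in (("day", r2_day), ("night", r2_night)):
        if not np.isnan(r2) and r2 < MIN_R_SQUARED:
            flags.append(f"low_r2_{label}")
    return VolumetricRates(day_rate, night_rate, r2_day, r2_night,
                           daylight, 24.0 - daylight, flags)


def per_position_rates(bs: BottleSet,
                       threshold: float = NIGHT_PAR_THRESHOLD) -> dict:
    """Clear-bottle daytime slope per depth position (report companion)."""
    dt = float(np.median(np.diff(bs.time_h)))
    day, _ = partition_day_night(bs.par, threshold, dt)
    out: dict[str, float] = {}
    for b in bs.clear():
        slope, _ = fit_bottle_rate(bs.time_h, b.o2, day)
        out[b.position] = slope
    return out


def areal_rates(rates: VolumetricRates, depth: float,
                detection_floor: float = DETECTION_FLOOR) -> ArealWaterRates:
    """Convert volumetric rates to areal water-column metabolism.

    With volumetric rates in µmol L-1 h-1 (= mmol m-3 h-1) and depth in m:

        ER_w  = |night| * 24 * depth
        GPP_w = (day - night) * daylight_hours * depth   (floored at 0)
        NEM_w = (day*daylight + night*night_hours) * depth

    When the daytime rate is undetectable (NaN), NEM_w falls back to the
    nighttime rate scaled to 24 h. Areal GPP below the detection floor is
    stored as 0 and marked below-detection (rendered "<0.1" in reports).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    night = rates.night_rate
    er = abs(night) * 24.0 * depth
    if np.isnan(rates.day_rate):
        nem = night * 24.0 * depth
        return ArealWaterRates(er=er, gpp=0.0, nem=nem, gpp_below_detection=True)
    gpp = max(0.0, (rates.day_rate - night) * rates.daylight_hours * depth)
    below = gpp < detection_floor
    if below:
        gpp = 0.0
    nem = (rates.day_rate * rates.daylight_hours
           + night * rates.night_hours) * depth
    return ArealWaterRates(er=er, gpp=gpp, nem=nem, gpp_below_detection=below)


def net_24h_change(initial: float, final: float, duration_h: float) -> float:
    """Net volumetric rate (µmol L-1 h-1) from endpoint O2 concentrations."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return (final - initial) / duration_h
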