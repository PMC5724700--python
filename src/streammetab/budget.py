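"""Daily, seasonal and annual metabolism budgets.

Definitions (all in mmol O2 m-2 d-1, positive NEM = net autotrophy):

    ER  = |mean nighttime flux| * 24
    NEP = daytime-integrated net flux
    GPP = NEP + ER  (equivalently (day - night flux) * daylight hours)
    NEM = NEP - ER over 24 h = day*daylight + night*night_hours

Budgets are carried at full precision; table-style one-decimal rounding is
applied only when rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

SEASONS = ("spring", "summer", "autumn", "winter")


@dataclass
class MetabolismSummary:
    """Daily metabolism for one compartment of one site-season."""

    site: str
    season: str
    compartment: str          # "benthic" | "water" | "combined"
    er: float                 # mmol m-2 d-1, >= 0
    gpp: float                # mmol m-2 d-1, >= 0
    nem: float                # mmol m-2 d-1
    daylight_hours: float = 12.0
    night_hours: float = 12.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.er < 0 or self.gpp < 0:
            raise ValueError("ER and GPP must be non-negative")
        if abs(self.daylight_hours + self.night_hours - 24.0) > 1e-9:
            raise ValueError("daylight + night hours must equal 24")

    def render(self, decimals: int = 1) -> dict:
        return {"site": self.site, "season": self.season,
                "compartment": self.compartment,
                "ER": round(self.er, decimals), "GPP": round(self.gpp, decimals),
                "NEM": round(self.nem, decimals)}


def daily_benthic_budget(day_flux: float, night_flux: float,
                         daylight_h: float, night_h: float,
                         site: str = "", season: str = "") -> MetabolismSummary:
    """Daily benthic budget from mean day/night hourly fluxes.

    Fluxes in mmol m-2 h-1 (positive = release). A positive nighttime flux
    is physically odd (respiration consumes O2) and triggers a warning.
    """
    if abs(daylight_h + night_h - 24.0) > 1e-9:
        raise ValueError("daylight + night hours must equal 24")
    if night_flux > 0:
        warnings.warn("positive nighttime flux: check sign convention")
    er = abs(night_flux) * 24.0
    gpp = max(0.0, (day_flux - night_flux) * daylight_h)
    nem = day_flux * daylight_h + night_flux * night_h
    return MetabolismSummary(site, season, "benthic", er, gpp, nem,
                             daylight_h, night_h)


def combine_compartments(benthic: MetabolismSummary,
                         water: MetabolismSummary) -> MetabolismSummary:
    """Element-wise sum of benthic and water-column budgets."""
    if (benthic.site, benthic.season) != (water.site, water.season):
        raise ValueError("site/season labels do not match")
    return MetabolismSummary(
        benthic.site, benthic.season, "combined",
        er=benthic.er + water.er, gpp=benthic.gpp + water.gpp,
        nem=benthic.nem + water.nem,
        daylight_hours=benthic.daylight_hours, night_hours=benthic.night_hours,
        flags=sorted(set(benthic.flags) | set(water.flags)),
    )


def relative_contribution(benthic: MetabolismSummary,
                          combined: MetabolismSummary) -> dict:
    """Benthic share (%) of the combined ER, GPP and NEM.

    Ratios with a zero combined denominator are undefined and rendered as
    None; NEM shares where benthic and water terms have opposite signs can
    exceed 100% and carry an ``opposite_sign`` flag.
    """
    out: dict[str, float | None | bool] = {}
    for name in ("er", "gpp", "nem"):
        total = getattr(combined, name)
        out[name] = None if total == 0 else 100.0 * getattr(benthic, name) / total
    water_nem = combined.nem - benthic.nem
    out["opposite_sign"] = bool(benthic.nem * water_nem < 0)
    return out


def annual_mean(summaries: list[MetabolismSummary],
                substitutions: dict[str, MetabolismSummary] | None = None
                ) -> MetabolismSummary:
    """Annual budget as the arithmetic mean of the four seasonal budgets.

    Exactly one summary per season is required. A missing season may be
    supplied through an explicit ``substitutions`` map (season -> summary);
    silent substitution is never performed, and substituted seasons are
    flagged on the result.
    """
    by_season = {s.season: s for s in summaries}
    flags: list[str] = []
    if substitutions:
        for season, sub in substitutions.items():
            if season not in by_season:
                by_season[season] = replace(sub, season=season)
                flags.append(f"substituted_{season}")
    missing = [s for s in SEASONS if s not in by_season]
    if missing:
        raise ValueError(f"missing seasons: {missing}")
    vals = [by_season[s] for s in SEASONS]
    first = vals[0]
    return MetabolismSummary(
        first.site, "annual", first.compartment,
        er=float(np.mean([v.er for v in vals])),
        gpp=float(np.mean([v.gpp for v in vals])),
        nem=float(np.mean([v.nem for v in vals])),
        flags=flags,
    )


def weighted_period_mean(peak_value: float, background_value: float,
                         peak_weeks: float, total_weeks: float) -> float:
    """Time-weighted mean of a short peak over a longer period.

    Used for extrapolating a short-lived production peak (e.g. a one-week
    spring bloom) over a whole season:
    (peak_weeks*peak + (total-peak)*background) / total.
    """
    if total_weeks <= 0:
        raise ValueError("total_weeks must be positive")
    if not 0 <= peak_weeks <= total_weeks:
        raise ValueError("need 0 <= peak_weeks <= total_weeks")
    return (peak_weeks * peak_value
            + (total_weeks - peak_weeks) * background_value) / total_weeks


def o2_to_carbon(value: float, photosynthetic_quotient: float = 1.0) -> float:
    """Convert an O2-based rate to carbon units via a fixed molar quotient."""
    if photosynthetic_quotient <= 0:
        raise ValueError("quotient must be positive")
    return value / photosynthetic_quotient
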