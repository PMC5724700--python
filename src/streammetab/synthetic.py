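"""Synthetic generators for every input the metabolism pipeline consumes.

Each generator carries its ground truth alongside the data, so the flux
extraction, incubation regression, budget arithmetic, and hydrology
regressions can all be validated end to end without field instruments.

Turbulence is modelled as stationary correlated Gaussian fluctuations with
a first-order autoregressive (AR(1)) spectral shape. That is deliberately
minimal: any stationary process with a controllable covariance suffices to
test covariance-flux recovery, and an AR(1) process makes the effective
number of independent samples explicit (record length / 2x integral
timescale).

Unit chain used throughout: O2 in µmol/L is numerically identical to
mmol/m^3, so

    flux [mmol m-2 h-1] = cov(w' [m/s], C' [mmol/m^3]) * 3600.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .series import HighFreqSeries

SECONDS_PER_HOUR = 3600.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurbulenceSpec:
    """Prescription for a synthetic eddy-covariance deployment.

    ``true_flux`` is the turbulent flux carried by the w'-C' covariance at
    sensor height (mmol O2 m-2 h-1, positive upward / released by the bed);
    ``storage_slope`` adds a linear background O2 trend on top of it.
    ``sigma_c`` (mmol/m^3) sets the magnitude of turbulent O2 fluctuations;
    when None it is scaled so the w'-C' correlation is ~0.4, with a floor of
    0.15 mmol/m^3, which mimics how O2 fluctuation amplitude tracks the flux.
    """

    sample_rate: float = 8.0          # Hz
    duration: float = 3.0 * 3600.0    # s
    mean_flow: float = 0.20           # U, m/s
    friction_velocity: float = 0.010  # u*, m/s
    true_flux: float = -5.0           # mmol O2 m-2 h-1
    mean_o2: float = 300.0            # µmol/L
    storage_slope: float = 0.0        # µmol L-1 h-1
    spike_rate: float = 0.001         # fraction of samples
    noise_sd_velocity: float = 0.003  # m/s, white sensor noise
    noise_sd_o2: float = 0.10         # µmol/L, white sensor noise
    sensor_lag: float = 0.5           # s, O2 sensor delay
    qc_fail_fraction: float = 0.005   # fraction of samples failing QC
    integral_timescale: float = 1.0   # s, AR(1) decorrelation scale
    sigma_c: float | None = None      # mmol/m^3 turbulent O2 fluctuation sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.spike_rate < 0.05:
            raise ValueError("spike_rate must lie in [0, 0.05)")
        if self.sensor_lag < 0:
            raise ValueError("sensor_lag must be non-negative")
        if self.friction_velocity < 0:
            raise ValueError("friction_velocity must be non-negative")
        if not 0 <= self.qc_fail_fraction < 0.5:
            raise ValueError("qc_fail_fraction must lie in [0, 0.5)")


@dataclass(frozen=True)
class CampaignSpec:
    """One seasonal field campaign: geometry, light climate, and true rates.

    ``pe_truth`` is the (Pmax, Ek, R) triple of the benthic
    photosynthesis-irradiance response used when generating diel benthic
    fluxes. Day/night split defaults to a temperate-summer 15.2/8.8 h.
    """

    site: str = "SYN"
    season: str = "summer"
    depth: float = 0.37               # m
    width: float = 4.0                # m
    daylight_hours: float = 15.2
    night_hours: float = 8.8
    par_peak: float = 600.0           # µmol quanta m-2 s-1
    pe_truth: tuple[float, float, float] = (16.9, 200.0, 4.4)
    water_day_rate: float = 5.3       # µmol L-1 h-1, clear-bottle daytime
    water_night_rate: float = -1.9    # µmol L-1 h-1, dark-bottle
    noise_sd_o2: float = 1.0          # µmol/L on bottle readings
    sample_interval_h: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if abs(self.daylight_hours + self.night_hours - 24.0) > 1e-9:
            raise ValueError("daylight_hours + night_hours must equal 24")


@dataclass(frozen=True)
class HydrographSpec:
    """Daily discharge record = slow base-flow recession + storm pulses."""

    n_days: int = 60
    baseflow_level: float = 0.20          # m^3/s asymptotic base flow
    baseflow_start: float = 0.30          # m^3/s base flow on day 0
    baseflow_recession_constant: float = 0.05   # d-1, slow recession
    storm_times: tuple[float, ...] = ()   # day indices of storm peaks
    storm_magnitudes: tuple[float, ...] = ()  # m^3/s added at each peak
    storm_recession_constant: float = 1.0     # d-1, fast runoff recession
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if min(self.baseflow_level, self.baseflow_start) <= 0:
            raise ValueError("base flow levels must be positive")
        if len(self.storm_times) != len(self.storm_magnitudes):
            raise ValueError("storm_times and storm_magnitudes lengths differ")
        if any(m < 0 for m in self.storm_magnitudes):
            raise ValueError("storm magnitudes must be non-negative")


# ---------------------------------------------------------------------------
# turbulence
# ---------------------------------------------------------------------------

def _ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series driven by unit-normal innovations."""
    from scipy.signal import lfilter

    e = np.sqrt(1.0 - phi * phi) * innovations
    e[0] = innovations[0]  # start in the stationary distribution
    return lfilter([1.0], [1.0, -phi], e)


def _inject_spikes(rng: np.random.Generator, x: np.ndarray, rate: float,
                   sigma: float) -> np.ndarray:
    """Add isolated 5-10 sigma single-sample excursions at the given rate."""
    if rate <= 0 or sigma <= 0:
        return x
    n = len(x)
    k = int(round(rate * n))
    if k == 0:
        return x
    idx = rng.choice(np.arange(2, n - 2), size=k, replace=False)
    amp = rng.uniform(5.0, 10.0, size=k) * sigma
    sign = rng.choice([-1.0, 1.0], size=k)
    out = x.copy()
    out[idx] += sign * amp
    return out


def gen_turbulence(spec: TurbulenceSpec) -> tuple[HighFreqSeries, dict]:
    """Generate a high-frequency velocity/O2 record with known flux truth.

    Returns the series and a truth record holding the imposed covariance
    flux, friction velocity, mean flow, storage slope and sensor lag.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.sample_rate * spec.duration))
    dt = 1.0 / spec.sample_rate
    t = np.arange(n) * dt
    phi = float(np.exp(-dt / spec.integral_timescale))

    u_star = spec.friction_velocity
    sigma_w = max(1.2 * u_star, 0.005)
    sigma_u = max(2.5 * u_star, 0.010)
    flux_si = spec.true_flux / SECONDS_PER_HOUR  # mmol m-2 s-1

    if spec.sigma_c is not None:
        sigma_c = spec.sigma_c
    else:
        sigma_c = max(abs(flux_si) / (0.4 * sigma_w), 0.15)

    rho_uw = -(u_star ** 2) / (sigma_u * sigma_w)
    rho_wc = flux_si / (sigma_w * sigma_c)
    if abs(rho_uw) > 0.95 or abs(rho_wc) > 0.95:
        raise ValueError("requested covariances exceed attainable correlation")

    g = rng.standard_normal((4, n))
    z_w = g[0]
    z_u = rho_uw * z_w + np.sqrt(1 - rho_uw ** 2) * g[1]
    z_c = rho_wc * z_w + np.sqrt(1 - rho_wc ** 2) * g[2]
    z_v = g[3]

    w_f = sigma_w * _ar1(z_w, phi)
    u_f = sigma_u * _ar1(z_u, phi)
    c_f = sigma_c * _ar1(z_c, phi)
    v_f = sigma_w * _ar1(z_v, phi)

    u = spec.mean_flow + u_f + rng.normal(0, spec.noise_sd_velocity, n)
    v = v_f + rng.normal(0, spec.noise_sd_velocity, n)
    w = w_f + rng.normal(0, spec.noise_sd_velocity, n)
    c = (spec.mean_o2 + spec.storage_slope * (t / SECONDS_PER_HOUR) + c_f
         + rng.normal(0, spec.noise_sd_o2, n))

    # sensor lag: the O2 electrode sees the eddy later than the velocimeter
    lag_samples = int(round(spec.sensor_lag * spec.sample_rate))
    if lag_samples > 0:
        c = np.concatenate([np.full(lag_samples, c[0]), c[:-lag_samples]])

    u = _inject_spikes(rng, u, spec.spike_rate, sigma_u)
    v = _inject_spikes(rng, v, spec.spike_rate, sigma_w)
    w = _inject_spikes(rng, w, spec.spike_rate, sigma_w)
    c = _inject_spikes(rng, c, spec.spike_rate, sigma_c)

    beam = np.clip(rng.normal(85.0, 5.0, n), 0, 100)
    snr = rng.normal(20.0, 3.0, n)
    n_fail = int(round(spec.qc_fail_fraction * n))
    if n_fail:
        bad = rng.choice(n, size=n_fail, replace=False)
        half = n_fail // 2
        beam[bad[:half]] = rng.uniform(10.0, 45.0, half)
        snr[bad[half:]] = rng.uniform(2.0, 9.0, n_fail - half)
        # failing samples carry corrupted velocities, as a real ADV would
        u[bad] += rng.normal(0, 5 * sigma_u, n_fail)
        w[bad] += rng.normal(0, 5 * sigma_w, n_fail)

    series = HighFreqSeries(t, u, v, w, c, beam, snr, spec.sample_rate)
    truth = {
        "true_flux_mmol_m2_h": spec.true_flux,
        "u_star_m_s": u_star,
        "mean_flow_m_s": spec.mean_flow,
        "storage_slope_umol_l_h": spec.storage_slope,
        "sensor_lag_s": lag_samples * dt,
        "sigma_w_m_s": sigma_w,
        "sigma_c_mmol_m3": sigma_c,
        "spec": asdict(spec),
    }
    return series, truth


# ---------------------------------------------------------------------------
# bottles
# ---------------------------------------------------------------------------

@dataclass
class Bottle:
    bottle_id: str
    role: str                 # "clear" | "dark"
    position: str             # "surface" | "mid" | "bottom"
    o2: np.ndarray            # µmol/L


@dataclass
class BottleSet:
    """Time-aligned incubation-bottle O2 series plus ambient PAR."""

    time_h: np.ndarray
    par: np.ndarray           # µmol quanta m-2 s-1
    bottles: list[Bottle]
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = {b.role for b in self.bottles}
        if not {"clear", "dark"} <= roles:
            raise ValueError("a bottle set needs at least one clear and one dark bottle")

    def clear(self) -> list[Bottle]:
        return [b for b in self.bottles if b.role == "clear"]

    def dark(self) -> list[Bottle]:
        return [b for b in self.bottles if b.role == "dark"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.time_h, "par_umol_m2_s": self.par})
        for b in self.bottles:
            df[f"o2_umol_l_{b.bottle_id}"] = b.o2
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def diel_par(time_h: np.ndarray, daylight_hours: float, par_peak: float,
             night_level: float = 0.5, sunrise_h: float | None = None) -> np.ndarray:
    """Half-sinusoid daytime PAR cycle with a small nighttime background.

    Nighttime PAR stays below the 2 µmol quanta m-2 s-1 day/night threshold.
    """
    if sunrise_h is None:
        sunrise_h = 12.0 - daylight_hours / 2.0
    tod = np.mod(time_h, 24.0)
    phase = (tod - sunrise_h) / daylight_hours
    par = np.where((phase >= 0) & (phase <= 1),
                   par_peak * np.sin(np.pi * np.clip(phase, 0, 1)),
                   0.0)
    return np.maximum(par, night_level)


def gen_bottles(campaign: CampaignSpec, n_clear: int = 3, n_dark: int = 1,
                duration_h: float = 24.0, initial_o2: float = 300.0) -> BottleSet:
    """Generate a 24-h bottle incubation with linear O2 drifts.

    Clear bottles drift at ``water_day_rate`` while PAR is above the
    2 µmol quanta m-2 s-1 threshold and at ``water_night_rate`` otherwise;
    dark bottles drift at ``water_night_rate`` throughout.
    """
    rng = np.random.default_rng(campaign.seed)
    time_h = np.arange(0.0, duration_h + 1e-9, campaign.sample_interval_h)
    par = diel_par(time_h, campaign.daylight_hours, campaign.par_peak)
    day = par >= 2.0
    dt = campaign.sample_interval_h

    def drift(day_rate: float, night_rate: float) -> np.ndarray:
        inst = np.where(day, day_rate, night_rate)
        o2 = initial_o2 + np.concatenate([[0.0], np.cumsum(inst[:-1] * dt)])
        return o2

    positions = ["surface", "mid", "bottom"]
    bottles: list[Bottle] = []
    for i in range(n_clear):
        o2 = drift(campaign.water_day_rate, campaign.water_night_rate)
        o2 = o2 + rng.normal(0, campaign.noise_sd_o2, len(o2))
        bottles.append(Bottle(f"clear_{i+1}", "clear", positions[i % 3], o2))
    for i in range(n_dark):
        o2 = drift(campaign.water_night_rate, campaign.water_night_rate)
        o2 = o2 + rng.normal(0, campaign.noise_sd_o2, len(o2))
        bottles.append(Bottle(f"dark_{i+1}", "dark", positions[i % 3], o2))

    truth = {
        "water_day_rate": campaign.water_day_rate,
        "water_night_rate": campaign.water_night_rate,
        "daylight_hours": campaign.daylight_hours,
        "depth_m": campaign.depth,
    }
    return BottleSet(time_h, par, bottles, truth)


def gen_diel_flux(campaign: CampaignSpec, n_days: int = 2,
                  noise_sd: float = 0.5) -> pd.DataFrame:
    """Hourly benthic flux / PAR pairs following a tanh light response.

    Flux(E) = Pmax*tanh(E/Ek) - R with (Pmax, Ek, R) = ``pe_truth``.
    Returns a table with columns hour, par_umol_m2_s, flux_mmol_m2_h.
    """
    rng = np.random.default_rng(campaign.seed + 1)
    pmax, ek, resp = campaign.pe_truth
    hours = np.arange(n_days * 24, dtype=float)
    par = diel_par(hours + 0.5, campaign.daylight_hours, campaign.par_peak)
    flux = pmax * np.tanh(par / ek) - resp + rng.normal(0, noise_sd, len(hours))
    return pd.DataFrame({"hour": hours, "par_umol_m2_s": par,
                         "flux_mmol_m2_h": flux})


# ---------------------------------------------------------------------------
# hydrographs and driver ensembles
# ---------------------------------------------------------------------------

def gen_hydrograph(spec: HydrographSpec) -> pd.DataFrame:
    """Daily discharge with stored base-flow truth.

    Total discharge = base flow (slow exponential recession toward
    ``baseflow_level``) + storm runoff (fast-recession pulses with a one-day
    rise). Columns: day, q_m3_s, baseflow_m3_s. Base flow never exceeds Q.
    """
    days = np.arange(spec.n_days, dtype=float)
    base = (spec.baseflow_level
            + (spec.baseflow_start - spec.baseflow_level)
            * np.exp(-spec.baseflow_recession_constant * days))
    runoff = np.zeros_like(days)
    for t0, mag in zip(spec.storm_times, spec.storm_magnitudes):
        rel = days - t0
        pulse = np.where(rel >= 0, mag * np.exp(-spec.storm_recession_constant * rel), 0.0)
        # one-day linear rise ahead of the peak
        rise = (rel >= -1) & (rel < 0)
        pulse[rise] = mag * (rel[rise] + 1.0)
        runoff += pulse
    q = base + runoff
    return pd.DataFrame({"day": days.astype(int), "q_m3_s": q,
                         "baseflow_m3_s": base})


def true_bfr(hydro: pd.DataFrame, end_day: int, window_days: int = 9) -> float:
    """Mean daily base-flow/discharge ratio over a window ending at end_day."""
    lo = end_day - window_days + 1
    if lo < 0 or end_day >= len(hydro):
        raise ValueError("window not fully covered by hydrograph")
    sl = hydro.iloc[lo:end_day + 1]
    return float((sl["baseflow_m3_s"] / sl["q_m3_s"]).mean())


def gen_driver_ensemble(n_sites: int, seed: int, a: float = 4.6,
                        b: float = 120.0, c: float = -120.0,
                        noise_sd: float = 5.0, window_days: int = 9,
                        n_days: int = 60) -> tuple[pd.DataFrame, dict, dict]:
    """Campaign-level driver points with a known linear NEM dependence.

    Builds one hydrograph per site-campaign, anchors a campaign end day in
    its second half, and constructs

        NEM = a * PAR_total + b * BFR(window_days) + c + noise.

    Returns (points, hydrographs, truth): points has columns site,
    par_total, bfr, nem, end_day; hydrographs maps site -> daily table;
    truth stores (a, b, c, window_days).
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    rows = []
    hydros: dict[str, pd.DataFrame] = {}
    for i in range(n_sites):
        n_storms = int(rng.integers(1, 4))
        storm_times = tuple(sorted(rng.uniform(5, n_days - 5, n_storms)))
        storm_mags = tuple(rng.uniform(0.1, 1.5, n_storms))
        hspec = HydrographSpec(
            n_days=n_days,
            baseflow_level=float(rng.uniform(0.05, 0.4)),
            baseflow_start=float(rng.uniform(0.4, 0.8)),
            baseflow_recession_constant=float(rng.uniform(0.02, 0.08)),
            storm_times=storm_times,
            storm_magnitudes=storm_mags,
            seed=seed + i,
        )
        hydro = gen_hydrograph(hspec)
        site = f"S{i:02d}"
        hydros[site] = hydro
        end_day = int(rng.integers(n_days // 2, n_days - 1))
        bfr9 = true_bfr(hydro, end_day, window_days)
        par = float(rng.uniform(0.3, 28.0))
        nem = a * par + b * bfr9 + c + rng.normal(0, noise_sd)
        rows.append({"site": site, "par_total": par, "bfr": bfr9,
                     "nem": nem, "end_day": end_day})
    points = pd.DataFrame(rows)
    truth = {"a": a, "b": b, "c": c, "window_days": window_days,
             "noise_sd": noise_sd}
    return points, hydros, truth


def write_truth(truth: dict, path) -> None:
    """Persist a generator truth record as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
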