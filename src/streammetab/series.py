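"""High-frequency velocity/O2 time-series container and text I/O.

The container mirrors what an acoustic Doppler velocimeter paired with a
fast O2 microelectrode records: three velocity components, O2
concentration, and per-sample quality channels (beam correlation, SNR) on
a uniform time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sample rates (Hz) accepted for raw deployments
VALID_RATES = (8, 16, 32, 64)


@dataclass
class HighFreqSeries:
    """Uniformly sampled velocity + O2 record.

    Attributes
    ----------
    time : array, seconds from deployment start
    u, v, w : velocity components, m/s (x along nominal flow, z up)
    o2 : O2 concentration, µmol/L (numerically equal to mmol/m^3)
    beam_correlation : %, per-sample velocimeter quality
    snr : dB, per-sample signal-to-noise ratio
    sample_rate : Hz
    """

    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    o2: np.ndarray
    beam_correlation: np.ndarray
    snr: np.ndarray
    sample_rate: float
    start: pd.Timestamp | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("u", "v", "w", "o2", "beam_correlation", "snr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length != time length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self) / self.sample_rate

    def copy(self) -> "HighFreqSeries":
        return HighFreqSeries(
            self.time.copy(), self.u.copy(), self.v.copy(), self.w.copy(),
            self.o2.copy(), self.beam_correlation.copy(), self.snr.copy(),
            self.sample_rate, self.start,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.time,
                "u_m_s": self.u,
                "v_m_s": self.v,
                "w_m_s": self.w,
                "o2_umol_l": self.o2,
                "beam_correlation_pct": self.beam_correlation,
                "snr_db": self.snr,
            }
        )
        if self.start is not None:
            ts = self.start + pd.to_timedelta(self.time, unit="s")
            df.insert(0, "timestamp", ts.strftime("%Y-%m-%dT%H:%M:%S.%f"))
        return df

    def write_csv(self, path) -> None:
        """Write as a delimited table with a header row."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float) -> "HighFreqSeries":
        start = None
        if "timestamp" in df.columns:
            stamps = pd.to_datetime(df["timestamp"])
            start = stamps.iloc[0]
        return cls(
            time=df["time_s"].to_numpy(float),
            u=df["u_m_s"].to_numpy(float),
            v=df["v_m_s"].to_numpy(float),
            w=df["w_m_s"].to_numpy(float),
            o2=df["o2_umol_l"].to_numpy(float),
            beam_correlation=df["beam_correlation_pct"].to_numpy(float),
            snr=df["snr_db"].to_numpy(float),
            sample_rate=sample_rate,
            start=start,
        )

    @classmethod
    def read_csv(cls, path, sample_rate: float) -> "HighFreqSeries":
        return cls.from_frame(pd.read_csv(path), sample_rate)
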