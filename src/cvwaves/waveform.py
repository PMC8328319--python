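"""Uniformly sampled periodic waveform container with CSV I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Waveform"]


@dataclass
class Waveform:
    """One period of a pressure (mmHg) or flow (mL/s) signal at a site.

    ``t`` covers [0, period) uniformly; length = round(period * sampling_rate).
    """

    site: str
    t: np.ndarray
    v: np.ndarray
    period: float
    sampling_rate: float
    quantity: str = "pressure"  # "pressure" | "flow"
    units: str = "mmHg"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1-D arrays of equal length")
        n_expected = round(self.period * self.sampling_rate)
        if len(self.t) != n_expected:
            raise ValueError(
                f"length {len(self.t)} != round(period*sampling_rate) = {n_expected}"
            )
        dt = np.diff(self.t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("non-uniform sampling")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("waveform contains non-finite values")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def n(self) -> int:
        return len(self.t)

    def mean(self) -> float:
        return float(np.mean(self.v))

    def pulse(self) -> float:
        """Peak-to-trough excursion (pulse pressure for pressure waves)."""
        return float(np.max(self.v) - np.min(self.v))

    def shifted(self, n_samples: int) -> "Waveform":
        """Circularly shifted copy (same time base)."""
        return Waveform(
            site=self.site,
            t=self.t.copy(),
            v=np.roll(self.v, n_samples),
            period=self.period,
            sampling_rate=self.sampling_rate,
            quantity=self.quantity,
            units=self.units,
        )

    # ---- CSV round trip: header line `site,quantity,units`, then t_s,value

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# site={self.site},quantity={self.quantity},units={self.units},"
                     f"period={self.period!r},sampling_rate={self.sampling_rate!r}\n")
            fh.write("t_s,value\n")
            for ti, vi in zip(self.t, self.v):
                fh.write(f"{ti:.9g},{vi:.9g}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Waveform":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split(","))
        df = pd.read_csv(path, comment="#")
        return cls(
            site=meta["site"],
            t=df["t_s"].to_numpy(),
            v=df["value"].to_numpy(),
            period=float(meta["period"]),
            sampling_rate=float(meta["sampling_rate"]),
            quantity=meta["quantity"],
            units=meta["units"],
        )
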