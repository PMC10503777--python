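"""Time-series containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Native grid of the observable series, Hz.
OBSERVABLE_HZ = 10.0

#: Default waveform sampling rate, Hz.
WAVEFORM_HZ = 125.0

OBSERVABLE_COLUMNS = ("t", "pa", "pv", "hr", "pp", "rc")


@dataclass
class ObservableSeries:
    """The five observables on a uniform grid (default 10 Hz).

    Channels: mean arterial pressure ``pa`` (mmHg), mean venous pressure
    ``pv`` (mmHg), heart rate ``hr`` (beats/min), pulse pressure ``pp``
    (mmHg) and ``rc`` (s) — the peripheral resistance times the arterial
    compliance, known only up to the pulse-contour scale α_RC.
    """

    t: np.ndarray
    pa: np.ndarray
    pv: np.ndarray
    hr: np.ndarray
    pp: np.ndarray
    rc: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(getattr(self, c), dtype=float)
                for c in OBSERVABLE_COLUMNS]
        n = arrs[0].size
        if any(a.size != n for a in arrs):
            raise ValueError("all observable channels must share the grid")
        for c, a in zip(OBSERVABLE_COLUMNS, arrs):
            object.__setattr__(self, c, a)

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self) > 1 else np.nan

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def window(self, start: float, length: float) -> "ObservableSeries":
        """Sub-series covering ``[start, start + length)`` (grid-aligned)."""
        mask = (self.t >= start - 1e-9) & (self.t < start + length - 1e-9)
        return ObservableSeries(*(getattr(self, c)[mask]
                                  for c in OBSERVABLE_COLUMNS))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in OBSERVABLE_COLUMNS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservableSeries":
        missing = [c for c in OBSERVABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observable table missing columns: {missing}")
        return cls(*(df[c].to_numpy(dtype=float) for c in OBSERVABLE_COLUMNS))


@dataclass
class WaveformRecord:
    """Raw two-channel pressure waveforms (arterial + central venous)."""

    t: np.ndarray          # s, uniform
    abp: np.ndarray        # arterial pressure, mmHg
    cvp: np.ndarray        # venous pressure, mmHg
    fs: float = WAVEFORM_HZ
    artifact_mask: np.ndarray | None = None  # True where an artifact was injected

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        self.cvp = np.asarray(self.cvp, dtype=float)
        if not (self.t.size == self.abp.size == self.cvp.size):
            raise ValueError("waveform channels must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "abp": self.abp, "cvp": self.cvp})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float | None = None) -> "WaveformRecord":
        missing = [c for c in ("t", "abp", "cvp") if c not in df.columns]
        if missing:
            raise ValueError(f"waveform table missing columns: {missing}")
        t = df["t"].to_numpy(dtype=float)
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else WAVEFORM_HZ
        return cls(t, df["abp"].to_numpy(float), df["cvp"].to_numpy(float), fs)


@dataclass(frozen=True)
class SegmentWindow:
    """A 300-s analysis window over an observable series."""

    start: float                 # s
    length: float = 300.0        # s
    valid: bool = True
    reason: str | None = None    # first violated validity criterion
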