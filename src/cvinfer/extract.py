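"""Feature extraction: raw waveforms -> five 10 Hz observables.

Pipeline: beat detection on the arterial channel (diastolic troughs),
per-beat systolic/diastolic extrema and Windkessel decay constant, local
median/MAD outlier clamping, then linear interpolation of all channels onto
a uniform 10 Hz grid.  Segments failing the physiological validity
thresholds are flagged, not repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .series import OBSERVABLE_HZ, ObservableSeries, SegmentWindow, WaveformRecord

#: Refractory period between beat onsets, s.
MIN_BEAT_INTERVAL = 0.2

#: Minimal diastolic run-off length (samples) for an RC fit.
MIN_DIASTOLE_SAMPLES = 5

#: R² below which a per-beat RC fit is rejected and imputed from neighbours.
RC_FIT_MIN_R2 = 0.5

BEAT_COLUMNS = ("onset", "period", "systolic", "diastolic", "pp", "rc",
                "rc_flagged")

#: Validity thresholds, applied in order; the first violation is reported.
VALIDITY_RULES = (
    ("arterial pressure", lambda s: (s.pa > 20.0) & (s.pa < 250.0)),
    ("venous pressure", lambda s: (s.pv > 0.0) & (s.pv < 25.0)),
    ("rc", lambda s: s.rc > 0.0),
    ("heart rate", lambda s: (s.hr > 30.0) & (s.hr < 250.0)),
    ("pulse pressure", lambda s: s.pp > 10.0),
)


def detect_beats(abp: np.ndarray, fs: float) -> pd.DataFrame:
    """Locate beats as diastolic troughs of the arterial waveform.

    Returns a beat table (one row per complete beat) with onset time,
    period, systolic/diastolic extrema and pulse pressure; the ``rc``
    column is NaN until :func:`estimate_rc` fills it.

    A trough is a local minimum whose prominence exceeds a quarter of the
    record's robust pulse amplitude, with a 0.2 s refractory period.
    """
    abp = np.asarray(abp, dtype=float)
    if fs < 50.0:
        raise ValueError("sampling rate must be >= 50 Hz for beat detection")
    if abp.size < 2 * fs:
        raise ValueError("record must be at least 2 s long")

    amp = np.percentile(abp, 95) - np.percentile(abp, 5)
    if amp <= 0:
        return pd.DataFrame(columns=BEAT_COLUMNS)
    troughs, _ = signal.find_peaks(
        -abp, distance=max(1, int(MIN_BEAT_INTERVAL * fs)),
        prominence=0.25 * amp)
    if troughs.size < 2:
        return pd.DataFrame(columns=BEAT_COLUMNS)

    rows = []
    for i0, i1 in zip(troughs[:-1], troughs[1:]):
        seg = abp[i0:i1 + 1]
        rows.append({
            "onset": i0 / fs,
            "period": (i1 - i0) / fs,
            "systolic": float(seg.max()),
            "diastolic": float(abp[i0]),
            "pp": float(seg.max() - abp[i0]),
            "rc": np.nan,
            "rc_flagged": False,
        })
    return pd.DataFrame(rows, columns=BEAT_COLUMNS)


def estimate_rc(diastolic: np.ndarray, dt: float) -> tuple[float, float]:
    """Windkessel decay constant from a diastolic run-off.

    Fits the linearised exponential ``P[i+1] = c + b·P[i]`` by least squares
    (the slope ``b = exp(-dt/τ)`` is invariant to the unknown decay
    asymptote) and returns ``(τ̂, R²)``.  A non-decaying or non-exponential
    run-off yields ``(nan, R²)``.
    """
    p = np.asarray(diastolic, dtype=float)
    if p.size < MIN_DIASTOLE_SAMPLES:
        return np.nan, 0.0
    if p[-1] >= p[0]:
        return np.nan, 0.0   # not a decay
    x, y = p[:-1], p[1:]
    vx = np.var(x)
    if vx <= 0:
        return np.nan, 0.0
    b = np.cov(x, y, bias=True)[0, 1] / vx
    c = y.mean() - b * x.mean()
    resid = y - (c + b * x)
    vy = np.var(y)
    r2 = 1.0 - resid.var() / vy if vy > 0 else 0.0
    if not (0.0 < b < 1.0 - 1e-9):
        return np.nan, r2
    return -dt / np.log(b), r2


def fill_beat_rc(beats: pd.DataFrame, abp: np.ndarray, fs: float,
                 skip_samples: int = 2, trim_samples: int = 2) -> pd.DataFrame:
    """Per-beat RC estimates over the diastolic run-off (peak -> next onset).

    The first ``skip_samples`` after the systolic peak and the last
    ``trim_samples`` before the next onset are excluded — they straddle the
    ejection/decay corners and bias the near-unity AR(1) slope.  Beats whose
    fit quality falls below ``RC_FIT_MIN_R2`` (or whose run-off is too
    short) are flagged and imputed by linear interpolation from
    neighbouring beats.
    """
    beats = beats.copy()
    dt = 1.0 / fs
    taus = np.full(len(beats), np.nan)
    flags = np.zeros(len(beats), dtype=bool)
    for i, row in enumerate(beats.itertuples(index=False)):
        i0 = int(round(row.onset * fs))
        i1 = i0 + int(round(row.period * fs))
        seg = abp[i0:i1 + 1]
        if seg.size < MIN_DIASTOLE_SAMPLES + skip_samples + trim_samples + 2:
            flags[i] = True
            continue
        peak = int(np.argmax(seg))
        run = seg[peak + skip_samples:seg.size - trim_samples]
        tau, r2 = estimate_rc(run, dt)
        if not np.isfinite(tau) or r2 < RC_FIT_MIN_R2:
            flags[i] = True
        else:
            taus[i] = tau
    good = np.isfinite(taus)
    if good.any():
        taus[~good] = np.interp(np.flatnonzero(~good), np.flatnonzero(good),
                                taus[good])
    beats["rc"] = taus
    beats["rc_flagged"] = flags | ~good
    return beats


def replace_outliers(x: np.ndarray, window: int = 200, k: float = 3.0,
                     eps: float = 0.5) -> np.ndarray:
    """Clamp outliers to local median ± k · scaled MAD.

    Points outside ``median ± k·1.4826·MAD`` (computed in a centred sliding
    window) are set to the violated threshold, not removed.  When the local
    MAD is zero (a degenerate constant window), ``eps`` acts as a floor so
    genuinely constant stretches pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    s = pd.Series(x)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()

    def _mad(w: np.ndarray) -> float:
        return np.median(np.abs(w - np.median(w)))

    mad = s.rolling(window, center=True, min_periods=1).apply(
        _mad, raw=True).to_numpy()
    scaled = np.maximum(1.4826 * mad, eps)
    lower = med - k * scaled
    upper = med + k * scaled
    return np.clip(x, lower, upper)


def resample_and_filter(channels: dict[str, tuple[np.ndarray, np.ndarray]],
                        grid: np.ndarray,
                        lowpass_hz: float | None = None) -> ObservableSeries:
    """Linear-interpolate irregular channels onto the uniform 10 Hz grid.

    ``channels`` maps each observable name (pa, pv, hr, pp, rc) to a
    ``(t, values)`` pair.  ``lowpass_hz`` optionally applies a zero-phase
    second-order Butterworth low-pass after interpolation; the default is a
    pass-through, since the observables are already minute-scale envelopes.
    """
    out = {}
    for name in ("pa", "pv", "hr", "pp", "rc"):
        if name not in channels:
            raise ValueError(f"missing channel {name!r}")
        t, v = channels[name]
        if len(t) == 0:
            raise ValueError(f"channel {name!r} is empty")
        out[name] = np.interp(grid, t, v)
    if lowpass_hz is not None:
        nyq = 0.5 * OBSERVABLE_HZ
        if not 0 < lowpass_hz < nyq:
            raise ValueError(f"lowpass cutoff must lie in (0, {nyq}) Hz")
        sos = signal.butter(2, lowpass_hz / nyq, output="sos")
        for name in out:
            out[name] = signal.sosfiltfilt(sos, out[name])
    return ObservableSeries(grid, out["pa"], out["pv"], out["hr"],
                            out["pp"], out["rc"])


def validate_segment(seg: ObservableSeries) -> SegmentWindow:
    """Apply the physiological validity thresholds to one window.

    Valid iff every sample satisfies 20 < Pa < 250 mmHg, 0 < Pv < 25 mmHg,
    RC > 0, 30 < Hr < 250 /min and Pp > 10 mmHg.
    """
    start = float(seg.t[0]) if len(seg) else 0.0
    length = seg.duration + seg.dt if len(seg) > 1 else 0.0
    for reason, rule in VALIDITY_RULES:
        if not np.all(rule(seg)):
            return SegmentWindow(start, length, valid=False, reason=reason)
    return SegmentWindow(start, length, valid=True)


def extract_observables(rec: WaveformRecord,
                        mean_window: float = 10.0,
                        outlier_window: float = 20.0,
                        outlier_k: float = 3.0,
                        lowpass_hz: float | None = None) -> ObservableSeries:
    """Full extraction: waveforms -> outlier-clamped 10 Hz observables.

    Mean pressures come from a ``mean_window``-s moving average of the raw
    channels (slow timescale); heart rate, pulse pressure and RC come from
    the beat table (fast timescale).  Outlier clamping uses a
    ``outlier_window``-s local median/MAD rule per channel.
    """
    if rec.duration < 10.0:
        raise ValueError("record must be at least 10 s long")
    if not np.all(np.isfinite(rec.cvp)):
        raise ValueError("venous channel contains non-finite samples")
    if not np.all(np.isfinite(rec.abp)):
        raise ValueError("arterial channel contains non-finite samples")

    fs = rec.fs
    beats = detect_beats(rec.abp, fs)
    if beats.empty:
        raise ValueError("no beats detected in arterial channel")
    beats = fill_beat_rc(beats, rec.abp, fs)

    # slow channels: moving-average envelope of the raw traces
    win = max(1, int(round(mean_window * fs)))
    kernel = np.ones(win) / win
    pa_slow = _centered_moving_average(rec.abp, win)
    pv_slow = _centered_moving_average(rec.cvp, win)

    grid_dt = 1.0 / OBSERVABLE_HZ
    t0 = np.ceil(rec.t[0] / grid_dt) * grid_dt
    t1 = np.floor(rec.t[-1] / grid_dt) * grid_dt
    grid = np.arange(t0, t1 + 1e-9, grid_dt)

    onset_t = rec.t[0] + beats["onset"].to_numpy()
    hr_beat = 60.0 / beats["period"].to_numpy()
    n_beat_win = max(MIN_DIASTOLE_SAMPLES,
                     int(round(outlier_window / np.median(beats["period"]))))
    n_slow_win = max(3, int(round(outlier_window * OBSERVABLE_HZ)))

    # decimate the slow channels to 10 Hz before clamping (cheaper, same
    # envelope), then clamp every channel with the 20-s median/MAD rule
    pa_10 = np.interp(grid, rec.t, pa_slow)
    pv_10 = np.interp(grid, rec.t, pv_slow)
    channels = {
        "pa": (grid, replace_outliers(pa_10, n_slow_win, outlier_k, eps=0.5)),
        "pv": (grid, replace_outliers(pv_10, n_slow_win, outlier_k, eps=0.5)),
        "hr": (onset_t, replace_outliers(hr_beat, n_beat_win, outlier_k, eps=1.0)),
        "pp": (onset_t, replace_outliers(beats["pp"].to_numpy(), n_beat_win,
                                         outlier_k, eps=0.5)),
        "rc": (onset_t, replace_outliers(beats["rc"].to_numpy(), n_beat_win,
                                         outlier_k, eps=0.01)),
    }
    return resample_and_filter(channels, grid, lowpass_hz=lowpass_hz)


def _centered_moving_average(x: np.ndarray, win: int) -> np.ndarray:
    return (pd.Series(x).rolling(win, center=True, min_periods=1)
            .mean().to_numpy())
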