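"""Synthetic beat-resolved pressure waveforms.

Generates 125 Hz arterial and venous traces whose minute-scale envelope
follows a given :class:`~cvinfer.series.ObservableSeries`: per beat the
arterial channel rises from diastolic to systolic level as a raised
half-cosine (systolic ejection), then decays exponentially with the
Windkessel time constant R·C_a, so that the per-beat mean equals the mean
arterial pressure, the per-beat range equals the pulse pressure, the beat
rate equals the heart rate and the diastolic decay constant encodes the RC
observable.  This is a test-fixture generator — the morphology is
synthetic, chosen only to pin down the envelope statistics the
feature-extraction pipeline must recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import ObservableSeries, WaveformRecord, WAVEFORM_HZ

#: Fraction of the cardiac cycle spent in systolic upstroke.
EJECTION_FRACTION = 0.3


@dataclass(frozen=True)
class WaveformNoise:
    """Additive noise/oscillation configuration for synthesis (SDs in mmHg)."""

    abp_sd: float = 0.0            # white noise on the arterial channel
    cvp_sd: float = 0.0            # white noise on the venous channel
    cvp_cardiac_amp: float = 0.5   # venous a/v-wave oscillation amplitude
    cvp_resp_amp: float = 1.0      # respiratory swing amplitude
    resp_hz: float = 0.4           # respiratory frequency


@dataclass(frozen=True)
class ArtifactConfig:
    """Poisson-rate configuration for movement/flush artifacts."""

    spike_rate: float = 0.0        # events/s
    spike_amp: float = 100.0       # mmHg
    dropout_rate: float = 0.0      # events/s
    dropout_duration: float = 2.0  # s
    wander_amp: float = 0.0        # mmHg, slow baseline wander
    wander_period: float = 60.0    # s


def synthesize_waveforms(obs: ObservableSeries,
                         fs: float = WAVEFORM_HZ,
                         noise: WaveformNoise | None = None,
                         seed: int | None = None,
                         alpha_rc_true: float = 1.0) -> WaveformRecord:
    """Render an observable envelope into beat-resolved waveforms.

    Parameters
    ----------
    obs : ObservableSeries
        Envelope to follow; all channels must be positive with hr > 0.
    fs : float
        Output sampling rate, Hz (default 125).
    noise : WaveformNoise, optional
    seed : int, optional
        Seeds the noise generator; synthesis is deterministic given the seed.
    alpha_rc_true : float
        The ground-truth pulse-contour scale: the diastolic time constant is
        ``rc / alpha_rc_true`` so that an unscaled extractor recovers
        ``rc / alpha_rc_true`` and the estimator's α_RC absorbs the ratio.

    Notes
    -----
    Per beat of period ``T = 60/hr`` the systolic level ``P_s`` solves the
    linear constraint that the beat-averaged pressure equal ``pa`` given
    range ``pp`` and decay constant ``τ``:

    ``P_s = pa + pp·(γ/2 + (1−γ)/(1−E) − (1−γ)·τ/d)``

    with ejection fraction ``γ``, diastolic span ``d = (1−γ)T`` and
    ``E = exp(−d/τ)``.  Diastolic level is ``P_s − pp`` and the decay
    asymptote ``P_s − pp/(1−E)`` (continuity with the next onset).
    """
    if noise is None:
        noise = WaveformNoise()
    if np.any(obs.hr <= 0):
        raise ValueError("heart rate must be positive everywhere")
    if np.any(obs.pp < 0):
        raise ValueError("pulse pressure must be nonnegative")
    if np.any(obs.rc <= 0):
        raise ValueError("rc must be positive")
    if alpha_rc_true <= 0:
        raise ValueError("alpha_rc_true must be positive")

    t0, t_end = float(obs.t[0]), float(obs.t[-1])
    n = int(np.floor((t_end - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    abp = np.empty(n)

    gamma = EJECTION_FRACTION
    # march beat by beat
    t_beat = t0
    idx = 0
    while t_beat < t_end + 1.0 / fs and idx < n:
        hr_k = np.interp(t_beat, obs.t, obs.hr)
        pa_k = np.interp(t_beat, obs.t, obs.pa)
        pp_k = np.interp(t_beat, obs.t, obs.pp)
        tau_k = np.interp(t_beat, obs.t, obs.rc) / alpha_rc_true
        period = 60.0 / hr_k
        d = (1.0 - gamma) * period
        e_decay = np.exp(-d / tau_k)
        p_s = pa_k + pp_k * (gamma / 2.0 + (1.0 - gamma) / (1.0 - e_decay)
                             - (1.0 - gamma) * tau_k / d)
        p_d = p_s - pp_k
        asym = p_s - pp_k / (1.0 - e_decay)

        # sample indices inside this beat
        i_stop = min(n, int(np.floor((t_beat + period - t0) * fs)) + 1)
        u = t[idx:i_stop] - t_beat
        seg = np.empty(u.size)
        sys_mask = u < gamma * period
        seg[sys_mask] = p_d + (p_s - p_d) * 0.5 * (
            1.0 - np.cos(np.pi * u[sys_mask] / (gamma * period)))
        dia = ~sys_mask
        seg[dia] = asym + (p_s - asym) * np.exp(
            -(u[dia] - gamma * period) / tau_k)
        abp[idx:i_stop] = seg
        idx = i_stop
        t_beat += period
    if idx < n:
        abp[idx:] = abp[idx - 1]

    # venous channel: slow envelope plus small cardiac/respiratory ripples
    hr_t = np.interp(t, obs.t, obs.hr)
    phase = 2.0 * np.pi * np.cumsum(hr_t / 60.0) / fs
    cvp = (np.interp(t, obs.t, obs.pv)
           + noise.cvp_cardiac_amp * np.sin(phase)
           + noise.cvp_resp_amp * np.sin(2.0 * np.pi * noise.resp_hz * (t - t0)))

    if noise.abp_sd > 0 or noise.cvp_sd > 0:
        rng = np.random.default_rng(seed)
        if noise.abp_sd > 0:
            abp = abp + rng.normal(0.0, noise.abp_sd, n)
        if noise.cvp_sd > 0:
            cvp = cvp + rng.normal(0.0, noise.cvp_sd, n)

    return WaveformRecord(t, abp, cvp, fs)


def inject_artifacts(rec: WaveformRecord,
                     config: ArtifactConfig,
                     seed: int | None = None) -> WaveformRecord:
    """Add seeded movement-like artifacts; returns a new record with mask.

    Transient spikes (single-sample excursions), flat-line dropouts and
    slow sinusoidal baseline wander are applied to the arterial channel at
    the configured Poisson rates.  The returned record carries a boolean
    ``artifact_mask`` marking every corrupted sample.
    """
    if config.spike_rate < 0 or config.dropout_rate < 0:
        raise ValueError("artifact rates must be nonnegative")
    rng = np.random.default_rng(seed)
    abp = rec.abp.copy()
    mask = np.zeros(len(rec), dtype=bool)
    duration = rec.duration if rec.duration > 0 else len(rec) / rec.fs

    n_spikes = rng.poisson(config.spike_rate * duration)
    if n_spikes:
        pos = rng.integers(0, len(rec), n_spikes)
        sign = rng.choice([-1.0, 1.0], n_spikes)
        abp[pos] += sign * config.spike_amp
        mask[pos] = True

    n_drop = rng.poisson(config.dropout_rate * duration)
    span = int(round(config.dropout_duration * rec.fs))
    for _ in range(n_drop):
        start = int(rng.integers(0, max(1, len(rec) - span)))
        abp[start:start + span] = abp[start]
        mask[start:start + span] = True

    if config.wander_amp > 0:
        wander = config.wander_amp * np.sin(
            2.0 * np.pi * (rec.t - rec.t[0]) / config.wander_period
            + rng.uniform(0, 2 * np.pi))
        abp = abp + wander
        mask[:] = True

    return WaveformRecord(rec.t.copy(), abp, rec.cvp.copy(), rec.fs,
                          artifact_mask=mask)
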