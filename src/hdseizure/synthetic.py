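"""Seeded surrogate iEEG recordings for offline testing of the full
detection pipeline.

Each recording mimics the short-term clinical layout the detector
assumes: a 3 min pre-ictal period, one annotated ictal period of
10–60 s, and a 3 min post-ictal period, at 512 Hz with tens of
channels.  Background activity is 1/f ("pink") noise with a per-channel
gain; the seizure is an additive 3–8 Hz sinusoidal burst, at a
configurable multiple r of the background RMS, on a random subset of
channels, with per-channel random phase and 1 s cosine on/off ramps.

The choice is deliberate: the detector sees nothing but order relations
between consecutive samples, and a slow, large oscillation lengthens
monotone runs and shifts the LBP code statistics exactly the way ictal
rhythms do — without claiming physiological realism (no spatial
propagation, no artifacts, no evolving seizure morphology).  Amplitude
units are arbitrary (the coding is scale-invariant); an optional 16-bit
quantization mimics an ADC front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import Recording, SeizureAnnotation


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults are the study conditions.

    ``amplitude_ratio`` r is the burst amplitude as a multiple of each
    channel's background RMS; r = 0 is a negative control in which ictal
    data are statistically identical to background.
    """

    m_channels: int = 36
    fs: float = 512.0
    pre_s: float = 180.0
    ictal_s_range: tuple[float, float] = (10.0, 60.0)
    post_s: float = 180.0
    amplitude_ratio: float = 4.0
    burst_freq_range_hz: tuple[float, float] = (3.0, 8.0)
    affected_fraction: float = 0.8
    ramp_s: float = 1.0
    channel_gain_sd: float = 0.2
    quantize_adc_bits: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_channels < 1:
            raise ValueError("need at least one channel")
        if min(self.pre_s, self.post_s) < 0 or self.ictal_s_range[0] <= 0:
            raise ValueError("durations must be positive")
        if self.ictal_s_range[0] > self.ictal_s_range[1]:
            raise ValueError("invalid ictal duration range")
        if self.amplitude_ratio < 0:
            raise ValueError("amplitude ratio must be >= 0")
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in (0, 1]")


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # keep DC finite
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _patient_params(config: SynthConfig):
    """Patient-level properties, fixed across that patient's recordings:
    per-channel background gains, the affected-channel subset, and each
    affected channel's burst frequency.  Derived from the master seed so
    every recording of one surrogate patient shares them — the premise
    that makes one-shot learning across seizures meaningful."""
    rng = np.random.default_rng(config.seed)
    m = config.m_channels
    gains = np.exp(rng.normal(0.0, config.channel_gain_sd, size=m))
    n_affected = max(1, int(round(config.affected_fraction * m)))
    affected = rng.choice(m, size=n_affected, replace=False)
    freqs = rng.uniform(*config.burst_freq_range_hz, size=n_affected)
    return gains, affected, freqs


def generate_recording(
    config: SynthConfig,
    seed: int | None = None,
    patient_id: str = "synthP1",
) -> Recording:
    """One surrogate recording with a single ictal annotation at ``pre_s``.

    Bit-identical for a fixed (config, seed); ``seed`` defaults to
    ``config.seed`` and drives only the recording-level variability —
    background noise, burst phases, and the ictal duration.
    """
    gains, affected, freqs = _patient_params(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m, fs = config.m_channels, config.fs
    ictal_s = float(rng.uniform(*config.ictal_s_range))
    duration = config.pre_s + ictal_s + config.post_s
    t_total = int(round(duration * fs))
    t = np.arange(t_total) / fs

    data = np.empty((m, t_total))
    for ch in range(m):
        data[ch] = gains[ch] * pink_noise(t_total, rng)

    phases = rng.uniform(0.0, 2 * np.pi, size=affected.size)

    env = _burst_envelope(t, config.pre_s, config.pre_s + ictal_s, config.ramp_s)
    for j, ch in enumerate(affected):
        amp = config.amplitude_ratio * gains[ch]  # r × that channel's RMS
        data[ch] += amp * env * np.sin(2 * np.pi * freqs[j] * t + phases[j])

    if config.quantize_adc_bits is not None:
        data = _quantize(data, config.quantize_adc_bits)

    return Recording(
        data=data,
        fs=fs,
        annotations=[SeizureAnnotation(config.pre_s, config.pre_s + ictal_s)],
        patient_id=patient_id,
    )


def _burst_envelope(t: np.ndarray, on: float, off: float, ramp: float
                    ) -> np.ndarray:
    """0→1 cosine ramp over ``ramp`` seconds at burst onset and offset."""
    env = np.zeros_like(t)
    inside = (t >= on) & (t < off)
    env[inside] = 1.0
    if ramp > 0:
        rise = inside & (t < on + ramp)
        env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp))
        fall = inside & (t >= off - ramp)
        env[fall] = 0.5 * (1 - np.cos(np.pi * (off - t[fall]) / ramp))
    return env


def _quantize(data: np.ndarray, bits: int) -> np.ndarray:
    full_scale = np.abs(data).max() or 1.0
    levels = 2 ** (bits - 1) - 1
    return np.round(data / full_scale * levels)


def generate_dataset(config: SynthConfig, n_seizures: int,
                     patient_id: str = "synthP1") -> list[Recording]:
    """Independent recordings of one surrogate patient, for split-based
    evaluation: shared channel count and background statistics, distinct
    seed-derived noise and ictal durations."""
    if n_seizures < 2:
        raise ValueError("a dataset needs at least 2 seizures for splitting")
    children = np.random.SeedSequence(config.seed).spawn(n_seizures)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return [
        generate_recording(config, seed=s, patient_id=patient_id)
        for s in seeds
    ]
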