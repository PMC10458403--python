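"""Voltage-recording pipeline: filter, detect action potentials, extract periods.

This is the experimental-data counterpart of the HR simulation path: a
sampled extracellular voltage trace is low-pass filtered (default cutoff
10 kHz), action-potential peaks are located as local maxima that clear a
relative height threshold (default 20% of the largest peak), and the
periods between consecutive peaks form the ISI series fed to the
entropy/sensor stack.

Because the original nerve-rootlet recordings are not redistributable,
:func:`synth_recording` generates *synthetic* recordings that emulate
their two regimes: "rest" (sparser, irregular firing -> higher FuzzyEn)
and "stimulation" (denser, more regular firing in stimulated epochs
interleaved with quiet stretches -> lower FuzzyEn), with periods on the
order of a millisecond in the range ~[0.0001, 0.0088] s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .hr import ISISeries, SpikeTimes, isi_from_spike_times

__all__ = [
    "Recording", "PeakConfig", "lowpass_filter",
    "detect_action_potentials", "periods_from_recording", "synth_recording",
]


@dataclass(frozen=True)
class Recording:
    """Single-channel sampled voltage trace.

    samples : voltage in arbitrary units; sample_rate in Hz.
    regime : optional label ("rest" / "stimulation") for synthetic data.
    """

    sample_rate: float
    samples: np.ndarray
    regime: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        v = np.asarray(self.samples, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("samples must be a finite 1-D sequence")
        object.__setattr__(self, "samples", v)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class PeakConfig:
    """Peak-extraction settings.

    lowpass_cutoff : low-pass corner frequency in Hz.
    height_fraction : keep peaks taller than this fraction of the global
        maximum of the filtered trace.
    local_points : a peak must strictly exceed this many neighbors on
        each side.
    """

    lowpass_cutoff: float = 10_000.0
    height_fraction: float = 0.20
    local_points: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.height_fraction < 1:
            raise ValueError("height_fraction must be in (0, 1)")
        if self.local_points < 1:
            raise ValueError("local_points must be >= 1")


def lowpass_filter(rec: Recording, cutoff: float = 10_000.0) -> Recording:
    """Zero-phase 4th-order Butterworth low-pass filter.

    Zero-phase (forward-backward) filtering preserves peak times; DC is
    passed unchanged.
    """
    nyquist = rec.sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist} Hz)")
    sos = butter(4, cutoff / nyquist, btype="low", output="sos")
    return Recording(rec.sample_rate, sosfiltfilt(sos, rec.samples), rec.regime)


def detect_action_potentials(rec: Recording, cfg: PeakConfig = PeakConfig()) -> SpikeTimes:
    """Positive local maxima passing the relative height filter.

    A sample counts as a peak when it strictly exceeds ``local_points``
    neighbors on each side and its amplitude is at least
    ``height_fraction`` times the global maximum of the trace.
    """
    v = rec.samples
    if v.size == 0:
        raise ValueError("empty recording")
    k = cfg.local_points
    if v.size < 2 * k + 1:
        return SpikeTimes(np.empty(0))
    is_peak = np.ones(v.size - 2 * k, dtype=bool)
    center = v[k:v.size - k]
    for off in range(1, k + 1):
        is_peak &= center > v[k - off:v.size - k - off]
        is_peak &= center > v[k + off:v.size - k + off]
    idx = np.nonzero(is_peak)[0] + k
    if idx.size == 0:
        return SpikeTimes(np.empty(0))
    idx = idx[v[idx] >= cfg.height_fraction * v.max()]
    return SpikeTimes(idx / rec.sample_rate)


def periods_from_recording(rec: Recording, cfg: PeakConfig = PeakConfig()) -> ISISeries:
    """Full pipeline: low-pass filter -> peak detection -> periods (s)."""
    filtered = lowpass_filter(rec, cfg.lowpass_cutoff)
    spikes = detect_action_potentials(filtered, cfg)
    return isi_from_spike_times(spikes)


# --- synthetic two-regime generator -------------------------------------

#: hard period bounds (s) the generator respects
_PERIOD_MIN, _PERIOD_MAX = 1e-4, 8.8e-3


def _spike_template(sample_rate: float) -> np.ndarray:
    """Biphasic action-potential shape, ~1 ms support, unit amplitude."""
    t = np.arange(-0.5e-3, 0.5e-3, 1.0 / sample_rate)
    sigma = 0.12e-3
    w = -t / sigma * np.exp(0.5 - 0.5 * (t / sigma) ** 2)
    return w / np.abs(w).max()


def _rest_isis(rng: np.random.Generator, n: int) -> np.ndarray:
    # lognormal with high coefficient of variation: irregular firing
    isi = rng.lognormal(mean=np.log(1.6e-3), sigma=0.85, size=n)
    return np.clip(isi, _PERIOD_MIN, _PERIOD_MAX)


def _stim_isis(rng: np.random.Generator, duration: float) -> np.ndarray:
    # stimulated epochs (dense, near-regular firing) alternating with
    # quiet epochs that contribute a single long period each
    isis: list[np.ndarray] = []
    total = 0.0
    while total < 1.2 * duration:
        burst_len = rng.uniform(0.05, 0.15)
        n_burst = max(2, int(burst_len / 0.65e-3))
        burst = rng.normal(0.65e-3, 0.04e-3, size=n_burst)
        isis.append(np.clip(burst, _PERIOD_MIN, _PERIOD_MAX))
        gap = rng.uniform(3e-3, _PERIOD_MAX)
        isis.append(np.array([gap]))
        total += burst.sum() + gap
    return np.concatenate(isis)


def synth_recording(
    regime: Literal["rest", "stimulation"],
    duration: float,
    seed: int,
    sample_rate: float = 40_000.0,
    noise_std: float = 0.03,
) -> Recording:
    """Seeded synthetic voltage recording in one of the two regimes.

    Synthetic stand-in for extracellular nerve recordings: a unit-height
    biphasic spike template placed at generated spike times plus white
    noise.  Rest firing is sparser and more irregular than stimulation;
    all generated periods lie within [0.0001, 0.0088] s.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if regime not in ("rest", "stimulation"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    if regime == "rest":
        n_est = int(duration / 1.5e-3) + 50
        isi = _rest_isis(rng, n_est)
        while isi.sum() < 1.2 * duration:
            isi = np.concatenate([isi, _rest_isis(rng, n_est)])
    else:
        isi = _stim_isis(rng, duration)
    spike_times = np.cumsum(isi) + 2e-3
    spike_times = spike_times[spike_times < duration - 2e-3]

    n = int(duration * sample_rate)
    v = rng.normal(0.0, noise_std, size=n)
    template = _spike_template(sample_rate)
    half = template.size // 2
    amps = rng.uniform(0.85, 1.0, size=spike_times.size)
    for t_spk, amp in zip(spike_times, amps):
        i = int(round(t_spk * sample_rate))
        lo, hi = i - half, i - half + template.size
        if lo >= 0 and hi <= n:
            v[lo:hi] += amp * template
    return Recording(sample_rate, v, regime)
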