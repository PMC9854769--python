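"""Synthetic multichannel EEG with known spectral ground truth.

Trials emulate a 62-channel, 200 Hz emotion-recognition recording: each clean
channel is a sum of band-limited alpha/beta/gamma oscillations whose
amplitudes depend on the emotional state, on top of 1/f background noise,
50 Hz powerline contamination and low-frequency blink-like transients on the
frontal channels.  Corrupt (overshooting) channels carry an additional slow
millivolt-scale component, mimicking EMG/electrode-leakage artifacts whose
peak amplitudes span 0.6-10 mV against a 10-100 microvolt clean background —
so any QC threshold placed between ~200 and ~600 microvolts separates them
by construction.

All randomness flows from a single master seed; trial ``k`` draws from an
independent stream seeded by ``(master_seed, k)``, so any subset of a dataset
is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import SpecError
from .recordings_io import ESI62_LABELS, Recording, default_lobe_map

__all__ = ["SyntheticSpec", "simulate_trial", "simulate_dataset", "DEFAULT_STATES"]

DEFAULT_STATES: tuple[str, ...] = ("negative", "neutral", "positive")

#: Per-state oscillation amplitudes (microvolts).  Chosen so the three states
#: are strongly separated in alpha/beta/gamma band power while every clean
#: channel stays well below 200 uV peak.
DEFAULT_BAND_POWERS: dict[str, dict[str, float]] = {
    "negative": {"alpha": 22.0, "beta": 8.0, "gamma": 4.0},
    "neutral": {"alpha": 12.0, "beta": 12.0, "gamma": 7.0},
    "positive": {"alpha": 6.0, "beta": 18.0, "gamma": 11.0},
}

DEFAULT_BAND_CENTERS: dict[str, float] = {"alpha": 10.0, "beta": 20.0, "gamma": 35.0}


@dataclass
class SyntheticSpec:
    """Generator configuration.

    Amplitudes are in microvolts except ``corrupt_channels`` peaks, which are
    in millivolts (matching how overshooting channels are described in the
    EEG QC literature).  ``band_centers`` may be overridden per state via
    ``state_band_centers`` for frequency-coded (rather than power-coded)
    class structure.
    """

    n_channels: int = 62
    fs: float = 200.0
    duration: float = 20.0  # seconds per trial
    band_powers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_BAND_POWERS.items()})
    band_centers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_CENTERS))
    state_band_centers: dict[str, dict[str, float]] | None = None
    noise_model: str = "one_over_f"  # or "white"
    noise_scale: float = 4.0  # RMS microvolts
    powerline_amplitude: float = 8.0  # microvolts at 50 Hz
    blink_rate: float = 12.0  # events per minute
    blink_amplitude: float = 75.0  # microvolts, frontal channels only
    corrupt_channels: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration <= 0:
            raise SpecError("n_channels, fs and duration must be positive")
        if self.noise_model not in ("white", "one_over_f"):
            raise SpecError(f"unknown noise model {self.noise_model!r}")
        for amp in (self.noise_scale, self.powerline_amplitude,
                    self.blink_amplitude, self.blink_rate):
            if amp < 0:
                raise SpecError("amplitudes and rates must be non-negative")
        for state, bands in self.band_powers.items():
            for band, amp in bands.items():
                if amp < 0:
                    raise SpecError(f"negative amplitude for {state}/{band}")
        for band, f0 in self._all_centers():
            if not 0 < f0 < self.fs / 2:
                raise SpecError(
                    f"band center {band}={f0} Hz outside (0, fs/2={self.fs / 2})")
        for state, bands in self.band_powers.items():
            missing = set(bands) - set(self.centers_for(state))
            if missing:
                raise SpecError(f"no band center for {state}/{sorted(missing)}")
        self.corrupt_channels = [(int(i), float(a)) for i, a in self.corrupt_channels]
        for idx, peak_mv in self.corrupt_channels:
            if not 0 <= idx < self.n_channels:
                raise SpecError(f"corrupt channel index {idx} out of range")
            if peak_mv < 0.6:
                raise SpecError(
                    f"corrupt peak {peak_mv} mV below the 0.6 mV overshoot band")

    def _all_centers(self):
        for band, f0 in self.band_centers.items():
            yield band, f0
        if self.state_band_centers:
            for centers in self.state_band_centers.values():
                yield from centers.items()

    def centers_for(self, state: str) -> dict[str, float]:
        centers = dict(self.band_centers)
        if self.state_band_centers and state in self.state_band_centers:
            centers.update(self.state_band_centers[state])
        return centers

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def channel_labels(self) -> list[str]:
        if self.n_channels <= len(ESI62_LABELS):
            return list(ESI62_LABELS[: self.n_channels])
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["corrupt_channels"] = [tuple(c) for c in doc.get("corrupt_channels", [])]
        return cls(**doc)


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power spectrum ~ 1/f (exponent 1)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2  =>  power ~ 1/f
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _blink_train(rng, n: int, fs: float, rate_per_min: float, amp: float) -> np.ndarray:
    """Raised-cosine pulses of 0.3 s, Poisson-placed."""
    out = np.zeros(n)
    if rate_per_min <= 0 or amp <= 0:
        return out
    width = int(round(0.3 * fs))
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    pulse = amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    for start in rng.integers(0, max(1, n - width), size=n_events):
        out[start:start + width] += pulse[: n - start]
    return out


def simulate_trial(spec: SyntheticSpec, state_label: str,
                   trial_index: int = 0, subject_id: str | None = None) -> Recording:
    """Generate one labeled trial; deterministic given ``(spec.seed, trial_index)``."""
    if state_label not in spec.band_powers:
        raise SpecError(
            f"state {state_label!r} has no band-power entry "
            f"(known: {sorted(spec.band_powers)})")
    rng = np.random.default_rng([abs(int(spec.seed)), int(trial_index)])
    n, fs = spec.n_samples, spec.fs
    t = np.arange(n) / fs
    labels = spec.channel_labels
    data = np.zeros((spec.n_channels, n))

    centers = spec.centers_for(state_label)
    amps = spec.band_powers[state_label]
    for ch in range(spec.n_channels):
        for band, amp in amps.items():
            if amp <= 0:
                continue
            f0 = centers[band]
            phase = rng.uniform(0, 2 * np.pi)
            data[ch] += amp * np.cos(2 * np.pi * f0 * t + phase)
        if spec.noise_scale > 0:
            if spec.noise_model == "white":
                data[ch] += spec.noise_scale * rng.standard_normal(n)
            else:
                data[ch] += _one_over_f_noise(rng, n, fs, spec.noise_scale)

    if spec.powerline_amplitude > 0:
        # common-mode mains pickup: one shared phase across the montage
        phase = rng.uniform(0, 2 * np.pi)
        data += spec.powerline_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)

    if spec.blink_amplitude > 0 and spec.blink_rate > 0:
        lobe_map = default_lobe_map(labels)
        frontal = set(lobe_map.lobes["prefrontal"]) | set(lobe_map.lobes["frontal"])
        blink = _blink_train(rng, n, fs, spec.blink_rate, spec.blink_amplitude)
        for ch, lab in enumerate(labels):
            if lab in frontal:
                data[ch] += blink

    for idx, peak_mv in spec.corrupt_channels:
        # EMG/electrode-leakage artifact: slow 0.5 Hz drift plus broadband
        # muscle-like noise, rescaled so the component reaches the requested
        # millivolt peak.  The broadband part is what floods the 8-40 Hz
        # analysis band, as corrupt channels do in real recordings.
        phase = rng.uniform(0, 2 * np.pi)
        drift = np.sin(2 * np.pi * 0.5 * t + phase)
        drift /= np.abs(drift).max()
        artifact = drift + 0.3 * rng.standard_normal(n)
        artifact *= peak_mv * 1000.0 / np.abs(artifact).max()
        data[idx] += artifact

    return Recording(
        data=data, fs=fs, channel_labels=labels,
        subject_id=subject_id, trial_id=f"T{trial_index:03d}", state_label=state_label,
    )


def simulate_dataset(
    spec: SyntheticSpec,
    n_trials_per_state: int = 15,
    states: tuple[str, ...] | list[str] = DEFAULT_STATES,
    subject_id: str = "S01",
    corrupt_plan: dict[int, list[tuple[int, float]]] | None = None,
) -> list[Recording]:
    """Balanced labeled dataset; trial k uses the derived stream (seed, k).

    ``corrupt_plan`` optionally maps a global trial index to the corrupt
    channels to inject into that trial only, overriding
    ``spec.corrupt_channels`` (which otherwise applies to every trial).
    """
    if n_trials_per_state < 1:
        raise SpecError("n_trials_per_state must be >= 1")
    if not states:
        raise SpecError("states list must not be empty")
    from dataclasses import replace

    recordings: list[Recording] = []
    k = 0
    for state in states:
        for _ in range(n_trials_per_state):
            trial_spec = spec
            if corrupt_plan is not None:
                trial_spec = replace(spec, corrupt_channels=corrupt_plan.get(k, []))
            recordings.append(
                simulate_trial(trial_spec, state, trial_index=k, subject_id=subject_id))
            k += 1
    return recordings
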