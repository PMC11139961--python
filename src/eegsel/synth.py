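"""Synthetic two-class EEG cohorts with planted, channel-localized band-power effects.

The generator emulates the shape of a resting-state clinical EEG study —
a 19-channel 10-20 montage sampled at 256 Hz for ten minutes per subject,
with an MCI-like class and a healthy-control class — while making the class
contrast fully controllable: class-1 subjects carry extra (or reduced) band
power in a configurable frequency band on a configurable subset of channels.

Signal model per channel: a sum of band-limited filtered Gaussian noise
components, one per canonical EEG rhythm band (delta..gamma), plus broadband
Gaussian noise, all scaled by a per-subject lognormal gain.  The class effect
is applied by splitting the channel signal into its content inside the effect
band and the remainder, and multiplying the in-band part by
``sqrt(power_ratio)``, so the realized band-power ratio between classes
tracks ``power_ratio`` directly.  No claim of physiological realism is made:
the spectrum is controllable, the effect is planted, and that is the point —
every downstream stage (including channel recovery by the optimizer) can be
tested against known ground truth.

Reproducibility: each subject draws from a child of the master
``numpy.random.SeedSequence`` spawned by subject index, so cohorts are
bitwise reproducible for a fixed spec and subjects are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import CANONICAL_BANDS, STANDARD_1020, validate_montage
from .preprocess import Recording


@dataclass(frozen=True)
class EffectSpec:
    """Planted class contrast: band-power shift localized to named channels.

    Parameters
    ----------
    informative_channels
        Channel names carrying the effect; must be a subset of the montage.
    band
        Frequency interval in Hz where class-1 power is shifted.
    power_ratio
        Multiplicative band-power factor, class-1 relative to class-0 (> 0;
        1.0 means no effect, >1 means class-1 has more in-band power).
    noise_sd
        Standard deviation of the broadband background noise, signal units.
    """

    informative_channels: tuple[str, ...] = ("T5", "O1")
    band: tuple[float, float] = (4.0, 8.0)
    power_ratio: float = 3.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "informative_channels",
                           tuple(self.informative_channels))
        lo, hi = self.band
        if not (0.0 < lo < hi):
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.power_ratio <= 0:
            raise ValueError("power_ratio must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the spec plus a seed IS the cohort.

    ``effect`` may be a single EffectSpec or a sequence of them (each applied
    to its own channels/band), so opposite-signed contrasts — e.g. theta
    raised on one channel and lowered on another, the relative-band-power
    motif — can be planted.

    Two lognormal per-subject amplitude gains emulate inter-subject
    variability: ``subject_gain_sd`` is a GLOBAL factor shared by all of a
    subject's channels (electrode impedance / skull-thickness style
    differences — the confound that caps single-channel accuracy and makes
    segment-level cross-validation optimistically biased relative to
    leave-one-subject-out), and ``channel_gain_sd`` is an independent
    per-channel jitter on top.
    """

    n_class1: int = 11
    n_class0: int = 13
    duration_s: float = 600.0
    fs: float = 256.0
    montage: tuple[str, ...] = STANDARD_1020
    effect: "EffectSpec | tuple[EffectSpec, ...]" = field(default_factory=EffectSpec)
    seed: int = 0
    subject_gain_sd: float = 0.3
    channel_gain_sd: float = 0.1
    band_profile_sd: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "montage", validate_montage(self.montage))
        effects = (self.effect,) if isinstance(self.effect, EffectSpec) else tuple(self.effect)
        object.__setattr__(self, "effect", effects)
        if self.n_class1 < 0 or self.n_class0 < 0:
            raise ValueError("class counts must be non-negative")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        for eff in effects:
            lo, hi = eff.band
            if hi >= self.fs / 2:
                raise ValueError(
                    f"effect band {eff.band} must lie below Nyquist ({self.fs / 2} Hz)")
            unknown = set(eff.informative_channels) - set(self.montage)
            if unknown:
                raise ValueError(f"informative channels not in montage: {sorted(unknown)}")
        if min(self.subject_gain_sd, self.channel_gain_sd, self.band_profile_sd) < 0:
            raise ValueError("gain standard deviations must be >= 0")

    @property
    def effects(self) -> "tuple[EffectSpec, ...]":
        return self.effect  # normalized to a tuple in __post_init__

    @property
    def informative_channels(self) -> "tuple[str, ...]":
        seen: dict[str, None] = {}
        for eff in self.effects:
            for ch in eff.informative_channels:
                seen.setdefault(ch)
        return tuple(seen)


#: Relative amplitude of each canonical-band component (arbitrary units);
#: roughly mimics the 1/f-ish shape of resting EEG: strong slow rhythms,
#: prominent alpha, weak gamma.
_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 1.2,
    "beta": 0.5,
    "gamma": 0.25,
}


def _band_sos(low: float, high: float, fs: float):
    nyq = fs / 2
    high = min(high, 0.99 * nyq)
    return sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")


def _background(n_samples: int, fs: float, noise_sd: float,
                rng: np.random.Generator,
                band_factors: "dict[str, float] | None" = None) -> np.ndarray:
    """One channel of rhythm components plus broadband noise.

    ``band_factors`` are per-subject amplitude multipliers on the canonical
    rhythm components (shared across a subject's channels), emulating
    idiosyncratic spectral profiles.
    """
    x = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else np.zeros(n_samples)
    for name, (lo, hi) in CANONICAL_BANDS.items():
        if lo >= fs / 2:
            continue
        comp = sps.sosfiltfilt(_band_sos(lo, hi, fs),
                               rng.normal(0.0, 1.0, n_samples))
        amp = _BAND_AMPLITUDES[name] * (band_factors[name] if band_factors else 1.0)
        x = x + amp * comp
    return x


def _scale_band(x: np.ndarray, band: tuple[float, float], fs: float,
                power_ratio: float) -> np.ndarray:
    """Multiply the content of ``x`` inside ``band`` by sqrt(power_ratio)."""
    sos = _band_sos(band[0], band[1], fs)
    in_band = sps.sosfiltfilt(sos, x)
    return (x - in_band) + np.sqrt(power_ratio) * in_band


def generate_recording(spec: CohortSpec, subject_index: int, label: int,
                       subject_id: str) -> Recording:
    """Generate one subject deterministically from the master seed + index."""
    n_samples = int(round(spec.duration_s * spec.fs))
    child = np.random.SeedSequence(spec.seed, spawn_key=(subject_index,))
    rng = np.random.default_rng(child)
    global_gain = float(np.exp(rng.normal(0.0, spec.subject_gain_sd)))
    gains = global_gain * np.exp(
        rng.normal(0.0, spec.channel_gain_sd, len(spec.montage)))
    band_factors = {name: float(np.exp(rng.normal(0.0, spec.band_profile_sd)))
                    for name in CANONICAL_BANDS}
    data = np.empty((len(spec.montage), n_samples))
    for i, ch in enumerate(spec.montage):
        x = _background(n_samples, spec.fs, spec.effects[0].noise_sd, rng,
                        band_factors)
        if label == 1:
            for eff in spec.effects:
                if ch in eff.informative_channels:
                    x = _scale_band(x, eff.band, spec.fs, eff.power_ratio)
        data[i] = gains[i] * x
    return Recording(subject_id=subject_id, label=label,
                     montage=spec.montage, fs=spec.fs, data=data)


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``n_class1 + n_class0`` recordings (class-1 subjects first).

    Deterministic for a fixed spec (including seed); distinct subjects use
    independent child seeds spawned from the master seed by subject index.
    """
    recs: list[Recording] = []
    idx = 0
    for _ in range(spec.n_class1):
        recs.append(generate_recording(spec, idx, 1, f"mci{idx + 1:02d}"))
        idx += 1
    for _ in range(spec.n_class0):
        recs.append(generate_recording(spec, idx, 0, f"hc{idx + 1:02d}"))
        idx += 1
    return recs


def null_cohort_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with every planted effect removed (power_ratio = 1)."""
    return replace(spec, effect=tuple(replace(e, power_ratio=1.0)
                                      for e in spec.effects))
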