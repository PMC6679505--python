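"""Synthetic multi-lead ECG generator.

The generator produces labelled heartbeats with the statistical structure the
multi-lead filter-learning method relies on: every lead observes the *same*
latent P-QRS-T morphology (up to a per-lead scalar gain, possibly
sign-flipped, mimicking e.g. lead II vs V1 polarity), while baseline wander
and high-frequency noise are drawn *independently* per lead.  Cross-lead
correlation therefore lives entirely in the signal component, which is exactly
the premise that makes CCA-learned filters noise-suppressing.

The latent beat of each class is a sum of five Gaussian bumps (P, Q, R, S, T),
the standard synthetic-ECG construction.  Continuous records tile beats at a
fixed RR interval so that segmentation round-trips exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LEAD_NAMES = ("II", "V1", "V5")


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class WaveSpec:
    """One Gaussian wave component of a beat.

    center and width are fractions of the beat window; amplitude is in the
    dimensionless units of the latent beat (R wave of the normal class = 1).
    """

    center: float
    width: float
    amplitude: float


# P-QRS-T morphology presets.  Amplitudes differ markedly between presets so
# that classes are linearly separable at moderate noise; centers are shared so
# that the R fiducial point is class-independent.
_MORPHOLOGY_PRESETS: tuple[tuple[WaveSpec, ...], ...] = (
    # normal-like
    (WaveSpec(0.18, 0.040, 0.15), WaveSpec(0.42, 0.015, -0.12),
     WaveSpec(0.47, 0.018, 1.00), WaveSpec(0.52, 0.015, -0.20),
     WaveSpec(0.72, 0.070, 0.30)),
    # ventricular-like: absent P, wide low R, deep S, inverted T
    (WaveSpec(0.18, 0.040, 0.02), WaveSpec(0.42, 0.020, -0.05),
     WaveSpec(0.47, 0.060, 0.55), WaveSpec(0.56, 0.030, -0.35),
     WaveSpec(0.72, 0.070, -0.25)),
    # atrial-like: tall P, tall narrow R, flat T
    (WaveSpec(0.18, 0.040, 0.30), WaveSpec(0.42, 0.015, -0.08),
     WaveSpec(0.47, 0.014, 1.35), WaveSpec(0.52, 0.015, -0.10),
     WaveSpec(0.72, 0.070, 0.12)),
    # bundle-branch-like: broad notched R, large T
    (WaveSpec(0.18, 0.040, 0.10), WaveSpec(0.42, 0.025, -0.15),
     WaveSpec(0.47, 0.040, 0.80), WaveSpec(0.53, 0.025, -0.30),
     WaveSpec(0.72, 0.080, 0.50)),
    # low-voltage: small R, dominant T
    (WaveSpec(0.18, 0.040, 0.08), WaveSpec(0.42, 0.015, -0.05),
     WaveSpec(0.47, 0.018, 0.30), WaveSpec(0.52, 0.015, -0.08),
     WaveSpec(0.72, 0.070, 0.60)),
)


def default_wave_params(n_classes: int) -> list[tuple[WaveSpec, ...]]:
    """Per-class wave parameters: morphology presets, cycled with a gain bump
    beyond the preset count so classes never coincide."""
    out = []
    k = len(_MORPHOLOGY_PRESETS)
    for c in range(n_classes):
        preset = _MORPHOLOGY_PRESETS[c % k]
        scale = 1.0 + 0.25 * (c // k)
        if scale != 1.0:
            preset = tuple(replace(w, amplitude=w.amplitude * scale) for w in preset)
        out.append(preset)
    return out


def _default_lead_gains(n_leads: int) -> tuple[float, ...]:
    return ((1.0,), (1.0, -0.6), (1.0, -0.6, 0.8))[n_leads - 1]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic beat generator.

    Defaults describe a 3-class, 2-lead set of 150 beats per class with mild
    white noise (sd 0.05 against a unit R wave), light baseline wander and 5%
    multiplicative amplitude jitter.
    """

    n_classes: int = 3
    beats_per_class: int = 150
    n_leads: int = 2
    beat_length: int = 256
    sampling_rate: float = 257.0
    wave_params: list[tuple[WaveSpec, ...]] | None = None
    lead_gains: tuple[float, ...] | None = None
    jitter_sd: float = 0.05
    baseline_amp: float = 0.1
    baseline_freq: float = 0.35
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leads not in (1, 2, 3):
            raise ConfigError(f"n_leads must be 1, 2 or 3, got {self.n_leads}")
        if self.n_classes < 1:
            raise ConfigError(f"n_classes must be >= 1, got {self.n_classes}")
        if self.beats_per_class < 1:
            raise ConfigError(
                f"beats_per_class must be >= 1, got {self.beats_per_class}")
        if self.beat_length < 8:
            raise ConfigError(f"beat_length too small: {self.beat_length}")
        if self.wave_params is None:
            self.wave_params = default_wave_params(self.n_classes)
        if len(self.wave_params) != self.n_classes:
            raise ConfigError(
                f"wave_params has {len(self.wave_params)} entries for "
                f"{self.n_classes} classes")
        for c, waves in enumerate(self.wave_params):
            centers = [w.center for w in waves]
            if any(b <= a for a, b in zip(centers, centers[1:])):
                raise ConfigError(
                    f"wave_params[{c}]: wave centers must be strictly increasing")
            if any(w.width <= 0 for w in waves):
                raise ConfigError(f"wave_params[{c}]: wave widths must be > 0")
        if self.lead_gains is None:
            self.lead_gains = _default_lead_gains(self.n_leads)
        self.lead_gains = tuple(float(g) for g in self.lead_gains)
        if len(self.lead_gains) != self.n_leads:
            raise ConfigError(
                f"lead_gains has {len(self.lead_gains)} entries for "
                f"{self.n_leads} leads")
        for name, val in (("jitter_sd", self.jitter_sd),
                          ("baseline_amp", self.baseline_amp),
                          ("noise_sd", self.noise_sd)):
            if val < 0:
                raise ConfigError(f"{name} must be >= 0, got {val}")

    @property
    def n_beats(self) -> int:
        return self.n_classes * self.beats_per_class

    @property
    def lead_names(self) -> list[str]:
        return list(DEFAULT_LEAD_NAMES[: self.n_leads])

    def r_offset(self) -> int:
        """Sample index of the nominal R-wave center inside a beat window."""
        r_wave = self.wave_params[0][2]
        return int(round(r_wave.center * self.beat_length))


@dataclass
class LabeledBeatSet:
    """Lead-aligned heartbeats: beats[h, i] is beat i seen on lead h."""

    beats: np.ndarray  # (n_leads, N, beat_length) float64
    labels: np.ndarray  # (N,) int
    lead_names: list[str]

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.beats.ndim != 3:
            raise ValueError("beats must be (n_leads, N, beat_length)")
        if self.beats.shape[1] != self.labels.shape[0]:
            raise ValueError("labels length must match beat count")
        if len(self.lead_names) != self.beats.shape[0]:
            raise ValueError("lead_names length must match lead count")

    @property
    def n_leads(self) -> int:
        return self.beats.shape[0]

    @property
    def n_beats(self) -> int:
        return self.beats.shape[1]

    @property
    def beat_length(self) -> int:
        return self.beats.shape[2]


def latent_beat(waves: tuple[WaveSpec, ...], beat_length: int) -> np.ndarray:
    """Noise-free class template: sum of Gaussian bumps on the unit interval."""
    t = np.arange(beat_length) / beat_length
    out = np.zeros(beat_length)
    for w in waves:
        out += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
    return out


def _clean_multi_lead_beats(config: SynthConfig, rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Jittered, gain-scaled beats without baseline wander or white noise.

    Returns (beats (n_leads, N, L), labels (N,)), ordered by class.
    """
    templates = [latent_beat(w, config.beat_length) for w in config.wave_params]
    n = config.n_beats
    beats = np.empty((config.n_leads, n, config.beat_length))
    labels = np.repeat(np.arange(config.n_classes), config.beats_per_class)
    jitter = rng.normal(0.0, config.jitter_sd, size=n) if config.jitter_sd else np.zeros(n)
    for i, c in enumerate(labels):
        lat = templates[c] * (1.0 + jitter[i])
        for h, g in enumerate(config.lead_gains):
            beats[h, i] = g * lat
    return beats, labels


def synth_beats(config: SynthConfig) -> LabeledBeatSet:
    """Generate a labelled multi-lead beat set.

    Lead h observes ``gain_h * (latent_class * (1 + jitter_i))`` plus a
    baseline-wander sinusoid with lead- and beat-specific random phase and
    independent white Gaussian noise.  Identical config and seed reproduce the
    arrays bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    beats, labels = _clean_multi_lead_beats(config, rng)
    n, length = config.n_beats, config.beat_length
    if config.baseline_amp > 0:
        t = np.arange(length) / config.sampling_rate
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(config.n_leads, n))
        beats += config.baseline_amp * np.sin(
            2.0 * np.pi * config.baseline_freq * t[None, None, :]
            + phases[:, :, None])
    if config.noise_sd > 0:
        beats += rng.normal(0.0, config.noise_sd, size=beats.shape)
    return LabeledBeatSet(beats, labels, config.lead_names)


def synth_record(config: SynthConfig, n_beats: int, rr_interval: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tile beats into a continuous annotated record at a fixed RR interval.

    Returns ``(signal, r_peaks, labels)`` where ``signal`` is
    (n_leads, (n_beats-1)*rr_interval + beat_length), ``r_peaks`` holds the
    sample index of each beat's R-wave center and ``labels`` the class of each
    tiled beat.  Baseline wander and white noise are added over the whole
    record (per lead), so segmenting at the returned peaks recovers the clean
    tiled beats exactly only when both are disabled.
    """
    if n_beats < 1:
        raise ConfigError(f"n_beats must be >= 1, got {n_beats}")
    if rr_interval < config.beat_length:
        raise ConfigError(
            f"rr_interval ({rr_interval}) must be >= beat_length "
            f"({config.beat_length}); overlapping beats are unsupported")
    rng = np.random.default_rng(config.seed)
    templates = [latent_beat(w, config.beat_length) for w in config.wave_params]
    labels = rng.integers(0, config.n_classes, size=n_beats)
    jitter = (rng.normal(0.0, config.jitter_sd, size=n_beats)
              if config.jitter_sd else np.zeros(n_beats))
    total = (n_beats - 1) * rr_interval + config.beat_length
    signal = np.zeros((config.n_leads, total))
    r_off = config.r_offset()
    peaks = np.arange(n_beats) * rr_interval + r_off
    for i, c in enumerate(labels):
        lat = templates[c] * (1.0 + jitter[i])
        start = i * rr_interval
        for h, g in enumerate(config.lead_gains):
            signal[h, start:start + config.beat_length] += g * lat
    if config.baseline_amp > 0:
        t = np.arange(total) / config.sampling_rate
        phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_leads)
        signal += config.baseline_amp * np.sin(
            2.0 * np.pi * config.baseline_freq * t[None, :]
            + phases[:, None])
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=signal.shape)
    return signal, peaks, labels


# ---------------------------------------------------------------------------
# persistence

def save_beatset(beatset: LabeledBeatSet, path: str) -> None:
    """Save to a compressed array container (.npz)."""
    np.savez_compressed(path, beats=beatset.beats, labels=beatset.labels,
                        lead_names=np.array(beatset.lead_names))


def load_beatset(path: str) -> LabeledBeatSet:
    with np.load(path, allow_pickle=False) as f:
        return LabeledBeatSet(f["beats"], f["labels"],
                              [str(s) for s in f["lead_names"]])


def save_beats_csv(beatset: LabeledBeatSet, path: str) -> None:
    """Delimited text export: one row per (lead, beat) with label and samples."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lead", "beat", "label"]
                   + [f"s{j}" for j in range(beatset.beat_length)])
        for h in range(beatset.n_leads):
            for i in range(beatset.n_beats):
                w.writerow([beatset.lead_names[h], i, int(beatset.labels[i])]
                           + [repr(float(v)) for v in beatset.beats[h, i]])


def load_beats_csv(path: str) -> LabeledBeatSet:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header, body = rows[0], rows[1:]
    length = len(header) - 3
    lead_names = list(dict.fromkeys(r[0] for r in body))
    index = {name: h for h, name in enumerate(lead_names)}
    n = max(int(r[1]) for r in body) + 1
    beats = np.zeros((len(lead_names), n, length))
    labels = np.zeros(n, dtype=int)
    for r in body:
        h, i = index[r[0]], int(r[1])
        labels[i] = int(r[2])
        beats[h, i] = [float(v) for v in r[3:]]
    return LabeledBeatSet(beats, labels, lead_names)
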