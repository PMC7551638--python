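"""Seeded generation of class-labelled synthetic ECG sample streams.

The generator emulates a chest-worn single-lead pulse sensor sampling at
100 Hz and emitting raw unitless sensor values centred on a baseline of
350 (valid range 200-500).  Each heartbeat is modelled as three smooth
Gaussian bumps — P, QRS and T — placed at fixed phase fractions of the
R-R interval; this is deliberately minimal beat morphology, chosen
because only the spectral band structure of the window matters to the
downstream classifier, not clinical waveform fidelity.

Three classes are produced:

``normal``
    resting sinus rhythm, heart rate drawn from 60-100 bpm with a small
    R-R coefficient of variation (3 %).
``control``
    the patient group, realised as a seeded per-stream mixture of four
    pathologies: bradycardia (< 60 bpm), tachycardia (> 100 bpm),
    irregular rhythm (normal rate, 25 % R-R jitter), and attenuated QRS
    morphology.
``noise``
    a sensor in a vibration/motion-artifact state: strong broadband
    additive noise, Poisson motion-artifact bursts, and per-sample
    excursions outside the 200-500 valid range.

Identical configuration + seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cardiofreq.signal_io import DEFAULT_SAMPLE_RATE_HZ, EcgStream, write_stream_csv

CLASS_LABELS = ("normal", "control", "noise")

BASELINE = 350.0
#: per-wave default amplitudes in sensor units (P, QRS, T)
DEFAULT_AMPLITUDES = (25.0, 120.0, 40.0)
#: phase fraction of the R-R interval at which each wave is centred
WAVE_PHASES = (0.18, 0.32, 0.55)
#: Gaussian width of each wave in seconds.  The R deflection of a real QRS
#: is a ~25 ms spike — one to three samples at 100 Hz — whose spectrum is
#: spread across the whole analysed band; P and T are the slow rounded waves.
WAVE_SIGMAS_S = (0.022, 0.008, 0.045)

#: control-group pathology mixture, one chosen per stream
CONTROL_MODES = ("bradycardia", "tachycardia", "irregular", "low_qrs")


@dataclass(frozen=True)
class SynthConfig:
    """Class-conditional generator parameters.

    Defaults describe the resting-state acquisition the classifier is
    meant for: 100 Hz sampling, baseline 350 sensor units, normal heart
    rate 60-100 bpm with 3 % R-R jitter.  ``artifact_rate_hz`` and
    ``out_of_range_prob`` only act for the noise class.
    """

    class_label: str = "normal"
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    duration_s: float = 3.0
    baseline: float = BASELINE
    beat_amplitudes: tuple[float, float, float] = DEFAULT_AMPLITUDES
    hr_bpm_range: tuple[float, float] = (60.0, 100.0)
    rr_jitter_cv: float = 0.03
    noise_sd: float = 4.0
    artifact_rate_hz: float = 0.0
    out_of_range_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        lo, hi = self.hr_bpm_range
        if not (0 < lo <= hi < 300):
            raise ValueError(f"hr_bpm_range must lie within (0, 300), got {self.hr_bpm_range}")
        if not 0 <= self.out_of_range_prob <= 1:
            raise ValueError("out_of_range_prob must be in [0, 1]")
        if self.rr_jitter_cv < 0 or self.noise_sd < 0 or self.artifact_rate_hz < 0:
            raise ValueError("rr_jitter_cv, noise_sd and artifact_rate_hz must be non-negative")

    @staticmethod
    def for_class(class_label: str, seed: int, duration_s: float = 3.0) -> "SynthConfig":
        """Default study conditions for one of the three classes.

        The control class is heterogeneous; the concrete pathology is
        drawn per stream inside :func:`generate_stream` from the seeded
        RNG, so two control configs differing only in seed may realise
        different pathologies.
        """
        base = SynthConfig(class_label=class_label, seed=seed, duration_s=duration_s)
        if class_label == "noise":
            return replace(base, noise_sd=30.0, artifact_rate_hz=0.5, out_of_range_prob=0.05)
        return base


@dataclass(frozen=True)
class LabeledStream:
    """A generated stream together with its ground-truth class label."""

    stream: EcgStream
    label: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")


def generate_beat(
    amplitudes: Sequence[float],
    rr_interval_s: float,
    sample_rate_hz: float,
    baseline: float = BASELINE,
    sigmas_s: Sequence[float] = WAVE_SIGMAS_S,
) -> np.ndarray:
    """One heartbeat: P, QRS and T Gaussian bumps on the baseline.

    Returns ``round(rr_interval_s * sample_rate_hz)`` samples.  Wave
    centres sit at fixed phase fractions of the R-R interval; widths are
    fixed in seconds so a slow beat has the same absolute QRS sharpness
    as a fast one, which is what keeps the rhythm classes spectrally
    distinct rather than mere time-dilations of each other.
    """
    if rr_interval_s <= 0:
        raise ValueError(f"rr_interval_s must be positive, got {rr_interval_s}")
    if sample_rate_hz <= 0:
        raise ValueError(f"sample_rate_hz must be positive, got {sample_rate_hz}")
    amps = np.asarray(amplitudes, dtype=float)
    if amps.shape != (3,) or not np.all(np.isfinite(amps)):
        raise ValueError("amplitudes must be three finite numbers (P, QRS, T)")
    n = int(round(rr_interval_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    seg = np.full(n, float(baseline))
    for amp, phase, sigma in zip(amps, WAVE_PHASES, sigmas_s):
        seg += amp * np.exp(-0.5 * ((t - phase * rr_interval_s) / sigma) ** 2)
    # at very short R-R intervals wave tails overlap; keep the beat inside
    # the envelope set by the dominant (QRS) amplitude
    qrs = abs(amps[1])
    if qrs > 0:
        seg = np.clip(seg, baseline - qrs, baseline + qrs)
    return seg


def _draw_rr_intervals(rng: np.random.Generator, mean_hr_bpm: float, cv: float, total_s: float) -> np.ndarray:
    """R-R intervals (s) around 60/mean_hr with multiplicative Gaussian jitter, covering total_s."""
    mean_rr = 60.0 / mean_hr_bpm
    out: list[float] = []
    acc = 0.0
    while acc < total_s + mean_rr:
        rr = mean_rr * (1.0 + cv * rng.standard_normal())
        rr = max(rr, 0.25 * mean_rr)  # refractory floor: no physically impossible beats
        out.append(rr)
        acc += rr
    return np.asarray(out)


def generate_stream(config: SynthConfig) -> LabeledStream:
    """Generate one labelled stream of ``round(duration_s * sample_rate_hz)`` samples."""
    rng = np.random.default_rng(config.seed)
    n_target = int(round(config.duration_s * config.sample_rate_hz))

    hr_range = config.hr_bpm_range
    jitter = config.rr_jitter_cv
    amps = tuple(config.beat_amplitudes)

    sigmas = WAVE_SIGMAS_S
    ectopic_prob = 0.0
    if config.class_label == "control":
        mode = CONTROL_MODES[int(rng.integers(len(CONTROL_MODES)))]
        if mode == "bradycardia":
            # slow escape-type rhythm with the widened QRS of disturbed conduction
            hr_range = (35.0, 59.0)
            p, q, t = sigmas
            sigmas = (p, 0.035, t)
        elif mode == "tachycardia":
            hr_range = (101.0, 160.0)
        elif mode == "irregular":
            # premature-beat pattern: erratic R-R with interspersed ectopic beats
            jitter = 0.25
            ectopic_prob = 0.3
        else:  # low_qrs: attenuated ventricular depolarization amplitude
            p, qrs, t = amps
            amps = (p, 0.35 * qrs, 1.3 * t)

    mean_hr = rng.uniform(*hr_range)
    rr = _draw_rr_intervals(rng, mean_hr, jitter, config.duration_s)
    ectopic = rng.random(rr.size) < ectopic_prob
    beats = []
    for r, ect in zip(rr, ectopic):
        if ect:
            # PVC-like beat: no P wave, wide high QRS, blunted T
            p, qrs, t = config.beat_amplitudes
            beats.append(
                generate_beat(
                    (0.0, qrs, 0.5 * t), r, config.sample_rate_hz, config.baseline,
                    sigmas_s=(sigmas[0], 0.045, sigmas[2]),
                )
            )
        else:
            beats.append(generate_beat(amps, r, config.sample_rate_hz, config.baseline, sigmas_s=sigmas))
    values = np.concatenate(beats)[:n_target]

    values = values + config.noise_sd * rng.standard_normal(n_target)

    if config.artifact_rate_hz > 0:
        n_bursts = rng.poisson(config.artifact_rate_hz * config.duration_s)
        for _ in range(n_bursts):
            start = int(rng.integers(0, n_target))
            dur = int(rng.uniform(0.1, 0.4) * config.sample_rate_hz)
            stop = min(start + max(dur, 1), n_target)
            # motion artifact: large low-frequency swing plus broadband shake
            k = stop - start
            swing = rng.uniform(60.0, 140.0) * np.sin(
                2 * np.pi * rng.uniform(2.0, 8.0) * np.arange(k) / config.sample_rate_hz
            )
            values[start:stop] += swing + 25.0 * rng.standard_normal(k)

    if config.out_of_range_prob > 0:
        hit = rng.random(n_target) < config.out_of_range_prob
        n_hit = int(hit.sum())
        if n_hit:
            low_side = rng.random(n_hit) < 0.5
            excursions = np.where(
                low_side, rng.uniform(80.0, 195.0, n_hit), rng.uniform(505.0, 650.0, n_hit)
            )
            values[hit] = excursions

    stream = EcgStream(values, sample_rate_hz=config.sample_rate_hz)
    return LabeledStream(stream=stream, label=config.class_label, seed=config.seed)


def generate_dataset(
    counts: dict[str, int] | Sequence[int],
    base_seed: int = 0,
    duration_s: float = 3.0,
) -> list[LabeledStream]:
    """Generate ``counts`` labelled streams per class, seeded per stream.

    ``counts`` maps class label to stream count (or is a (normal,
    control, noise) triple).  Stream ``k`` overall uses seed
    ``base_seed + k``, so datasets are reproducible and per-stream
    regenerable.  The default 3 s duration yields exactly one complete
    256-sample window at 100 Hz with headroom for validity filtering.
    """
    if not isinstance(counts, dict):
        counts = dict(zip(CLASS_LABELS, counts))
    for label, n in counts.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if n < 0:
            raise ValueError(f"count for {label!r} must be >= 0")
    streams: list[LabeledStream] = []
    k = 0
    for label in CLASS_LABELS:
        for _ in range(counts.get(label, 0)):
            cfg = SynthConfig.for_class(label, seed=base_seed + k, duration_s=duration_s)
            streams.append(generate_stream(cfg))
            k += 1
    return streams


def write_dataset(streams: Sequence[LabeledStream], out_dir: str | Path) -> Path:
    """Write one CSV per stream plus a ``manifest.csv`` (stream_file, label, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ls in enumerate(streams):
        fname = f"stream_{i:05d}.csv"
        write_stream_csv(ls.stream, out_dir / fname)
        rows.append({"stream_file": fname, "label": ls.label, "seed": ls.seed})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["stream_file", "label", "seed"]).to_csv(
        manifest, index=False, lineterminator="\n"
    )
    return manifest
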