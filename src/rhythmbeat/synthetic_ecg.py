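"""Synthetic single-lead ECG records with known rhythm grammars.

The generator emulates the structure the classifier assumes about annotated
arrhythmia recordings: a continuous mV trace sampled at a fixed rate, one
annotated R peak per beat, and a per-beat AAMI label.  Beat morphologies are
parametric sums of Gaussian bumps (P, Q, R, S, T waves) with class-specific
centres, widths and amplitudes:

* N — P wave, narrow QRS, upright T;
* S — same QRS/T as N but premature, with an earlier and smaller P wave;
* V — wide QRS, absent P, inverted T;
* F — morphology intermediate between N and V (fusion beat);
* Q — pacing-spike-like morphology (very narrow, tall deflection).

Premature beat types (S, V) arrive after a shortened RR interval (default
0.7x the base interval) and are followed by a compensatory pause (1.3x),
so rhythm patterns such as bigeminy carry genuine inter-beat timing signal.

Noise is additive and has three components matching the classic ECG noise
sources: sinusoidal baseline wander, sinusoidal powerline interference, and
white Gaussian noise (muscle/EMG stand-in).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .aami import AAMIClass, as_class

__all__ = [
    "RhythmSpec",
    "NoiseSpec",
    "ECGRecord",
    "RHYTHM_UNITS",
    "generate_rhythm_labels",
    "generate_beat_waveform",
    "generate_record",
    "synthesize_noise",
    "make_benchmark",
]

#: Repeating label unit of each named rhythm.
RHYTHM_UNITS: dict[str, tuple[AAMIClass, ...]] = {
    "normal_sinus": (AAMIClass.N,),
    "ventricular_bigeminy": (AAMIClass.N, AAMIClass.V),
    "atrial_bigeminy": (AAMIClass.N, AAMIClass.S),
    "ventricular_trigeminy": (AAMIClass.N, AAMIClass.N, AAMIClass.V),
    "atrial_trigeminy": (AAMIClass.N, AAMIClass.N, AAMIClass.S),
    "ventricular_tachycardia": (AAMIClass.V,),
    "atrial_tachycardia": (AAMIClass.S,),
}

#: Representative annotation symbol written for each AAMI class.
CLASS_TO_SYMBOL = {
    AAMIClass.N: "N",
    AAMIClass.S: "A",
    AAMIClass.V: "V",
    AAMIClass.F: "F",
    AAMIClass.Q: "/",
}

#: Beat types that arrive prematurely (shortened preceding RR interval).
PREMATURE = frozenset({AAMIClass.S, AAMIClass.V})

#: RR-interval multipliers: premature beats come early, the beat after a
#: premature beat is delayed by a compensatory pause.
PREMATURE_FRACTION = 0.7
COMPENSATORY_FRACTION = 1.3


@dataclasses.dataclass(frozen=True)
class RhythmSpec:
    """A rhythm grammar: which labels repeat, how many beats, at what rate."""

    name: str = "normal_sinus"
    custom_pattern: Optional[Sequence] = None
    n_beats: int = 100
    heart_rate_bpm: float = 75.0
    rate_jitter_frac: float = 0.03

    def __post_init__(self):
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if not (0.0 <= self.rate_jitter_frac < 1.0):
            raise ValueError("rate_jitter_frac must be in [0, 1)")
        if self.name == "custom":
            if not self.custom_pattern:
                raise ValueError("custom rhythm requires a non-empty custom_pattern")
        elif self.name not in RHYTHM_UNITS:
            raise ValueError(f"unknown rhythm name: {self.name!r}")

    @property
    def unit(self) -> tuple[AAMIClass, ...]:
        if self.name == "custom":
            return tuple(as_class(c) for c in self.custom_pattern)
        return RHYTHM_UNITS[self.name]


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline wander + powerline + Gaussian, all in mV."""

    baseline_wander_amp: float = 0.1
    baseline_wander_freq: float = 0.3
    powerline_amp: float = 0.03
    powerline_freq: float = 50.0
    gaussian_sd: float = 0.05

    def __post_init__(self):
        for f in ("baseline_wander_amp", "powerline_amp", "gaussian_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(baseline_wander_amp=0.0, powerline_amp=0.0, gaussian_sd=0.0)


@dataclasses.dataclass
class ECGRecord:
    """One continuous single-lead trace with per-beat annotations.

    ``beat_labels[i]`` may be None for annotations that do not map to a beat
    class (e.g. rhythm-change markers read from external files).
    """

    signal: np.ndarray
    fs: float
    r_peaks: np.ndarray
    beat_labels: list
    symbols: Optional[list] = None
    record_id: str = "record"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if len(self.r_peaks) != len(self.beat_labels):
            raise ValueError("r_peaks and beat_labels must have equal length")
        if self.symbols is not None and len(self.symbols) != len(self.r_peaks):
            raise ValueError("symbols must align with r_peaks")
        if len(self.r_peaks) and (
            np.any(np.diff(self.r_peaks) <= 0)
            or self.r_peaks[0] < 0
            or self.r_peaks[-1] >= len(self.signal)
        ):
            raise ValueError("r_peaks must be strictly increasing and in range")


def generate_rhythm_labels(spec: RhythmSpec) -> list[AAMIClass]:
    """Deterministic repeating label sequence, truncating the final unit."""
    unit = spec.unit
    reps = -(-spec.n_beats // len(unit))
    return list(unit * reps)[: spec.n_beats]


# (centre s relative to R, amplitude mV, width s) per wave, per class.
_MORPHOLOGY: dict[AAMIClass, tuple[tuple[float, float, float], ...]] = {
    AAMIClass.N: (
        (-0.170, 0.15, 0.025),   # P
        (-0.040, -0.10, 0.010),  # Q
        (0.000, 1.00, 0.012),    # R
        (0.040, -0.15, 0.012),   # S
        (0.300, 0.30, 0.055),    # T
    ),
    AAMIClass.S: (
        (-0.200, 0.11, 0.022),   # early, smaller P
        (-0.040, -0.10, 0.010),
        (0.000, 1.00, 0.012),
        (0.040, -0.15, 0.012),
        (0.300, 0.30, 0.055),
    ),
    AAMIClass.V: (
        (-0.060, -0.25, 0.030),  # no P; broad initial negativity
        (0.000, 1.05, 0.034),    # wide R
        (0.065, -0.35, 0.035),   # wide S
        (0.300, -0.35, 0.080),   # inverted T
    ),
    AAMIClass.F: (
        (-0.170, 0.07, 0.025),   # attenuated P
        (-0.045, -0.17, 0.020),
        (0.000, 1.00, 0.023),    # intermediate QRS width
        (0.050, -0.25, 0.023),
        (0.300, 0.10, 0.068),
    ),
    AAMIClass.Q: (
        (0.000, 1.40, 0.006),    # pacing spike
        (0.020, -0.20, 0.015),
        (0.280, 0.12, 0.090),    # broad low-amplitude repolarisation
    ),
}


def window_bounds(fs: float) -> tuple[int, int, int]:
    """(pre, post, length) of the beat window: 0.25 s before and 0.4 s after R."""
    pre = int(round(0.25 * fs))
    post = int(round(0.4 * fs))
    return pre, post, pre + 1 + post


def generate_beat_waveform(label, fs: float, rng: np.random.Generator) -> np.ndarray:
    """One beat window (``round(0.25 fs)+1+round(0.4 fs)`` samples, R at index pre).

    Deterministic given (label, fs, rng state); per-wave amplitude/width/centre
    jitter is drawn from ``rng`` so repeated beats of the same class vary.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    label = as_class(label)
    pre, post, length = window_bounds(fs)
    t = (np.arange(length) - pre) / fs
    wave = np.zeros(length)
    for centre, amp, width in _MORPHOLOGY[label]:
        a = amp * (1.0 + 0.06 * rng.standard_normal())
        w = width * (1.0 + 0.04 * rng.standard_normal())
        c = centre if centre == 0.0 else centre + 0.004 * rng.standard_normal()
        wave += a * np.exp(-0.5 * ((t - c) / max(w, 1e-4)) ** 2)
    return wave


def synthesize_noise(n_samples: int, fs: float, noise: NoiseSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """The additive noise trace alone (baseline wander + powerline + Gaussian)."""
    t = np.arange(n_samples) / fs
    phase_bw = rng.uniform(0, 2 * np.pi)
    phase_pl = rng.uniform(0, 2 * np.pi)
    out = noise.baseline_wander_amp * np.sin(
        2 * np.pi * noise.baseline_wander_freq * t + phase_bw
    )
    out += noise.powerline_amp * np.sin(
        2 * np.pi * noise.powerline_freq * t + phase_pl
    )
    if noise.gaussian_sd > 0:
        out += noise.gaussian_sd * rng.standard_normal(n_samples)
    else:
        rng.standard_normal(n_samples)  # keep the draw count seed-stable
    return out


def _beat_intervals(labels, base: float, jitter: float,
                    rng: np.random.Generator) -> np.ndarray:
    """RR interval (samples, float) preceding each beat k>=1."""
    gaps = np.empty(len(labels) - 1)
    for k in range(1, len(labels)):
        if labels[k] in PREMATURE:
            frac = PREMATURE_FRACTION
        elif labels[k - 1] in PREMATURE:
            frac = COMPENSATORY_FRACTION
        else:
            frac = 1.0
        g = base * frac
        if jitter > 0:
            g *= 1.0 + jitter * rng.uniform(-1.0, 1.0)
        gaps[k - 1] = g
    return gaps


def generate_record(rhythm: RhythmSpec, noise: NoiseSpec, fs: float = 360.0,
                    seed: int = 0, record_id: Optional[str] = None) -> ECGRecord:
    """Assemble a full record: beats at rhythm-driven RR intervals plus noise.

    Fully reproducible from ``seed``; beat morphology, interval jitter and
    noise use three independent child streams, so the same seed with
    ``NoiseSpec.zero()`` yields the identical clean assembly.
    """
    ss = np.random.SeedSequence(seed)
    rng_beat, rng_int, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    labels = generate_rhythm_labels(rhythm)
    pre, post, length = window_bounds(fs)
    base = fs * 60.0 / rhythm.heart_rate_bpm

    r_peaks = [pre]
    if len(labels) > 1:
        gaps = _beat_intervals(labels, base, rhythm.rate_jitter_frac, rng_int)
        for g in gaps:
            r_peaks.append(r_peaks[-1] + int(round(g)))
    r_peaks = np.asarray(r_peaks, dtype=int)

    n_samples = int(r_peaks[-1]) + post + 1
    signal = np.zeros(n_samples)
    for r, lab in zip(r_peaks, labels):
        signal[r - pre: r + post + 1] += generate_beat_waveform(lab, fs, rng_beat)

    signal += synthesize_noise(n_samples, fs, noise, rng_noise)
    symbols = [CLASS_TO_SYMBOL[lab] for lab in labels]
    rid = record_id or f"{rhythm.name}-{seed}"
    return ECGRecord(signal=signal, fs=fs, r_peaks=r_peaks,
                     beat_labels=labels, symbols=symbols, record_id=rid)


#: One cycle of the standard benchmark mix: (rhythm name or custom pattern,
#: beats in the record).  Class shares per cycle: N ~66%, V ~13%, S ~12%,
#: Q ~8%, F ~0.6% — a strongly imbalanced mix echoing clinical Holter data.
_BENCHMARK_RECIPE: tuple[tuple[object, int], ...] = (
    ("normal_sinus", 40),
    ("ventricular_bigeminy", 30),
    ("atrial_bigeminy", 30),
    ("normal_sinus", 40),
    ("ventricular_trigeminy", 30),
    ("atrial_trigeminy", 30),
    ("normal_sinus", 40),
    # ventricular tachycardia run ending in a fusion beat and sinus capture
    (("N",) * 6 + ("V", "V", "V", "F") + ("N",) * 5, 30),
    (("Q",), 25),
    ("ventricular_tachycardia", 12),
    ("atrial_tachycardia", 12),
)


def make_benchmark(n_beats: int = 10000, fs: float = 360.0, seed: int = 0,
                   noise: Optional[NoiseSpec] = None) -> list[ECGRecord]:
    """The standard synthetic benchmark: a seed-deterministic mix of rhythms.

    Cycles through short records of sinus rhythm, ventricular/atrial bigeminy
    and trigeminy, tachycardia runs, a paced record and a fusion-bearing
    tachycardia pattern until ``n_beats`` beats have been produced.  Heart
    rate varies per record in 60-90 bpm.
    """
    if noise is None:
        noise = NoiseSpec()
    master = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    total = 0
    i = 0
    while total < n_beats:
        entry, nb = _BENCHMARK_RECIPE[i % len(_BENCHMARK_RECIPE)]
        nb = min(nb, n_beats - total)
        hr = master.uniform(60.0, 90.0)
        rec_seed = int(master.integers(0, 2**31 - 1))
        if isinstance(entry, str):
            spec = RhythmSpec(name=entry, n_beats=nb, heart_rate_bpm=hr)
        else:
            spec = RhythmSpec(name="custom", custom_pattern=entry, n_beats=nb,
                              heart_rate_bpm=hr)
        records.append(generate_record(spec, noise, fs=fs, seed=rec_seed,
                                       record_id=f"syn{i:04d}"))
        total += nb
        i += 1
    return records
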