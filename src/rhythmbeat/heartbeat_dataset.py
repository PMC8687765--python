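"""From annotated records to fixed-length beats, segments, and splits.

A beat window spans 0.25 s before to 0.4 s after its annotated R peak
(inclusive): ``round(0.25 fs)`` samples before, the peak sample, and
``round(0.4 fs)`` after — 90 + 1 + 144 = 235 samples at 360 Hz, with the
R peak at 0-based window index 90.

Consecutive beats of one record are grouped into non-overlapping segments
of ``t`` beats (the network timestep); each beat keeps its own label, so a
segment is a sequence-labelling example that exposes inter-beat rhythm
(bigeminy, trigeminy, tachycardia runs) to the classifier.  A trailing
partial segment is kept and flagged rather than discarded.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np

from .aami import AAMIClass, as_class

logger = logging.getLogger(__name__)

__all__ = [
    "AAMIClass",
    "AAMI_SYMBOL_MAP",
    "Beat",
    "BeatSegment",
    "SplitConfig",
    "BeatWindowError",
    "map_annotation_to_aami",
    "window_bounds",
    "segment_beat",
    "build_beats",
    "assemble_segments",
    "split_dataset",
]

#: MIT-BIH-style annotation symbol -> AAMI class.  Any symbol not listed
#: (rhythm markers '+', noise '~', etc.) is excluded from beat building.
AAMI_SYMBOL_MAP: dict[str, AAMIClass] = {
    "N": AAMIClass.N, "L": AAMIClass.N, "R": AAMIClass.N,
    "j": AAMIClass.N, "e": AAMIClass.N,
    "a": AAMIClass.S, "J": AAMIClass.S, "A": AAMIClass.S, "S": AAMIClass.S,
    "V": AAMIClass.V, "E": AAMIClass.V,
    "F": AAMIClass.F,
    "/": AAMIClass.Q, "Q": AAMIClass.Q, "f": AAMIClass.Q,
}


class BeatWindowError(ValueError):
    """The beat window would cross a record boundary."""


def map_annotation_to_aami(symbol: str) -> Optional[AAMIClass]:
    """AAMI class for a beat annotation symbol, or None if excluded."""
    return AAMI_SYMBOL_MAP.get(symbol)


def window_bounds(fs: float) -> tuple[int, int, int]:
    """(samples before R, samples after R, total window length)."""
    pre = int(round(0.25 * fs))
    post = int(round(0.4 * fs))
    return pre, post, pre + 1 + post


@dataclasses.dataclass
class Beat:
    """One fixed-length beat window with a single AAMI label."""

    samples: np.ndarray
    label: AAMIClass
    r_index_in_window: int
    source_record: str = "record"
    position_in_record: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.label = as_class(self.label)


@dataclasses.dataclass
class BeatSegment:
    """An ordered run of record-contiguous beats; ``t`` is the target length.

    ``len(beats) < t`` marks a trailing partial segment.
    """

    beats: list
    t: int

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not self.beats or len(self.beats) > self.t:
            raise ValueError("a segment holds between 1 and t beats")
        recs = {b.source_record for b in self.beats}
        if len(recs) != 1:
            raise ValueError("segment beats must come from one record")
        pos = [b.position_in_record for b in self.beats]
        if any(b - a != 1 for a, b in zip(pos, pos[1:])):
            raise ValueError("segment beats must be consecutive in their record")

    @property
    def labels(self) -> list[AAMIClass]:
        return [b.label for b in self.beats]

    @property
    def is_partial(self) -> bool:
        return len(self.beats) < self.t

    def feature_matrix(self) -> np.ndarray:
        """(len(beats), window_length) input matrix for the network."""
        return np.stack([b.samples for b in self.beats])


@dataclasses.dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.9
    seed: int = 0
    unit: str = "segment"

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.unit != "segment":
            raise ValueError("only segment-level splitting is supported")


def segment_beat(signal, r_index: int, fs: float) -> np.ndarray:
    """Extract the inclusive window ``[r - round(0.25 fs), r + round(0.4 fs)]``."""
    signal = np.asarray(signal)
    pre, post, _ = window_bounds(fs)
    if r_index - pre < 0 or r_index + post >= len(signal):
        raise BeatWindowError(
            f"window [{r_index - pre}, {r_index + post}] outside record of "
            f"length {len(signal)}"
        )
    return np.array(signal[r_index - pre: r_index + post + 1], dtype=float)


def build_beats(record, signal: Optional[np.ndarray] = None) -> list[Beat]:
    """One Beat per annotated peak that maps to an AAMI class and fits in-record.

    ``signal`` overrides the record's own trace (e.g. a denoised copy).
    Boundary-dropped and excluded-symbol counts are logged.
    """
    sig = record.signal if signal is None else np.asarray(signal, dtype=float)
    pre, _, _ = window_bounds(record.fs)
    beats: list[Beat] = []
    n_excluded = 0
    n_boundary = 0
    for pos, (r, lab) in enumerate(zip(record.r_peaks, record.beat_labels)):
        if lab is None:
            n_excluded += 1
            continue
        try:
            window = segment_beat(sig, int(r), record.fs)
        except BeatWindowError:
            n_boundary += 1
            continue
        beats.append(Beat(samples=window, label=lab, r_index_in_window=pre,
                          source_record=getattr(record, "record_id", "record"),
                          position_in_record=pos))
    if n_excluded or n_boundary:
        logger.info("build_beats(%s): %d beats, %d excluded symbols, "
                    "%d boundary-dropped",
                    getattr(record, "record_id", "record"),
                    len(beats), n_excluded, n_boundary)
    return beats


def assemble_segments(beats: list[Beat], t: int) -> list[BeatSegment]:
    """Non-overlapping runs of ``t`` consecutive beats per record.

    Runs restart wherever record identity changes or positions are not
    consecutive (e.g. around dropped beats).  The final partial run of each
    record is kept; every beat appears in exactly one segment.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    segments: list[BeatSegment] = []
    run: list[Beat] = []
    prev = None
    for beat in beats:
        contiguous = (
            prev is not None
            and beat.source_record == prev.source_record
            and beat.position_in_record == prev.position_in_record + 1
        )
        if run and (not contiguous or len(run) == t):
            segments.append(BeatSegment(beats=run, t=t))
            run = []
        run.append(beat)
        prev = beat
    if run:
        segments.append(BeatSegment(beats=run, t=t))
    return segments


def split_dataset(segments: list[BeatSegment],
                  cfg: SplitConfig) -> tuple[list[BeatSegment], list[BeatSegment]]:
    """Seed-deterministic disjoint random partition at the segment level."""
    n = len(segments)
    if n < 2:
        raise ValueError("need at least 2 segments to split")
    n_train = int(round(cfg.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(cfg.seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return ([segments[i] for i in train_idx], [segments[i] for i in test_idx])
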