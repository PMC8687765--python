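"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pytest

from rhythmbeat import heartbeat_dataset as hbd
from rhythmbeat import synthetic_ecg


@pytest.fixture(scope="session")
def bench_beats():
    """~1500 mixed-rhythm beats from the standard benchmark generator."""
    records = synthetic_ecg.make_benchmark(1500, seed=11)
    return [b for r in records for b in hbd.build_beats(r)]


@pytest.fixture(scope="session")
def bench_segments_t5(bench_beats):
    return hbd.assemble_segments(bench_beats, 5)


@pytest.fixture()
def clean_record():
    """A noise-free sinus record (seed-fixed)."""
    spec = synthetic_ecg.RhythmSpec(name="normal_sinus", n_beats=40,
                                    heart_rate_bpm=72, rate_jitter_frac=0.0)
    return synthetic_ecg.generate_record(spec, synthetic_ecg.NoiseSpec.zero(),
                                         fs=360.0, seed=5)


def make_dummy_segments(n, t=1, dim=3, seed=0):
    """Lightweight segments for split/partition tests."""
    rng = np.random.default_rng(seed)
    beats = [hbd.Beat(samples=rng.standard_normal(dim), label=hbd.AAMIClass.N,
                      r_index_in_window=0, source_record=f"r{i}",
                      position_in_record=0)
             for i in range(n)]
    return [hbd.BeatSegment(beats=[b], t=t) for b in beats]
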