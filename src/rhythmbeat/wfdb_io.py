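"""Minimal WFDB-compatible record I/O, written in-package.

Supports the subset of the PhysioNet waveform-database format family this
tool needs: a single-signal format-16 record (``.hea`` text header +
``.dat`` little-endian int16 samples) and the MIT annotation format
(``.atr``: 16-bit words of ``(code << 10) | time-increment``, with the SKIP
escape for increments above 1023).  A plain-text fallback is also provided:
``.csv`` (columns ``sample,mV``) plus a JSON sidecar with R peaks and
labels.

Amplitudes are stored as ``round(gain * mV)`` ADC units, so a write/read
round trip is exact up to half an ADC step (default gain 1000 / mV).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .heartbeat_dataset import map_annotation_to_aami
from .synthetic_ecg import ECGRecord

__all__ = [
    "write_wfdb", "read_wfdb_record",
    "write_csv_record", "read_csv_record",
]

# MIT annotation code <-> symbol (beat codes plus common non-beat codes).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 28: "+", 34: "e", 37: "x",
    38: "f",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP = 59


def write_wfdb(record: ECGRecord, directory, name: str | None = None,
               gain: int = 1000) -> Path:
    """Write ``name.hea``, ``name.dat`` and ``name.atr``; returns the prefix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or record.record_id
    fs = record.fs
    fs_str = f"{fs:g}"
    n = len(record.signal)
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    header = (f"{name} 1 {fs_str} {n}\n"
              f"{name}.dat 16 {gain} 16 0 {int(adc[0]) if n else 0} 0 0 ch1\n")
    (directory / f"{name}.hea").write_text(header)

    words = bytearray()
    prev = 0
    symbols = record.symbols or ["N"] * len(record.r_peaks)
    for t, sym in zip(record.r_peaks.tolist(), symbols):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"no MIT annotation code for symbol {sym!r}")
        delta = t - prev
        if delta > 1023:
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<H", (delta >> 16) & 0xFFFF)
            words += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        words += struct.pack("<H", (code << 10) | (delta & 0x3FF))
        prev = t
    words += struct.pack("<H", 0)
    (directory / f"{name}.atr").write_bytes(bytes(words))
    return directory / name


def _read_annotations(path: Path) -> tuple[np.ndarray, list[str]]:
    data = path.read_bytes()
    samples: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 2 <= len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        if word == 0:
            break
        code = word >> 10
        delta = word & 0x3FF
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code in _CODE_TO_SYMBOL:
            t += pending_skip + delta
            pending_skip = 0
            samples.append(t)
            symbols.append(_CODE_TO_SYMBOL[code])
        # other codes (NUM/SUB/CHN/AUX) are not produced by our writer
    return np.asarray(samples, dtype=int), symbols


def read_wfdb_record(path) -> ECGRecord:
    """Read a record written by :func:`write_wfdb` (or a compatible one).

    ``path`` is the record prefix (with or without the ``.hea`` suffix).
    The first signal is used; annotation symbols are mapped to AAMI classes
    where possible (None for non-beat symbols).
    """
    prefix = Path(str(path).removesuffix(".hea"))
    hea = prefix.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file: {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"unreadable header: {hea}")
    fs = float(head[2].split("/")[0])
    sig = lines[1].split()
    fname, fmt = sig[0], sig[1]
    if fmt.split("x")[0] != "16":
        raise ValueError(f"unsupported signal format {fmt!r} (only 16)")
    gain_field = sig[2] if len(sig) > 2 else "200"
    baseline = 0
    if "(" in gain_field:
        gain_str, rest = gain_field.split("(", 1)
        baseline = int(rest.split(")")[0])
    else:
        gain_str = gain_field
    gain = float(gain_str.split("/")[0]) or 200.0
    adczero = int(sig[4]) if len(sig) > 4 else 0

    dat = prefix.parent / fname
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file: {dat}")
    adc = np.frombuffer(dat.read_bytes(), dtype="<i2").astype(float)
    signal = (adc - (baseline or adczero)) / gain

    atr = prefix.with_suffix(".atr")
    if not atr.exists():
        raise FileNotFoundError(f"missing annotation file: {atr}")
    r_peaks, symbols = _read_annotations(atr)
    labels = [map_annotation_to_aami(s) for s in symbols]
    return ECGRecord(signal=signal, fs=fs, r_peaks=r_peaks,
                     beat_labels=labels, symbols=symbols,
                     record_id=prefix.name)


def write_csv_record(record: ECGRecord, csv_path, sidecar_path=None) -> None:
    """Plain-text fallback: ``sample,mV`` CSV + JSON annotation sidecar."""
    csv_path = Path(csv_path)
    lines = ["sample,mV"]
    lines += [f"{i},{v:.6f}" for i, v in enumerate(record.signal)]
    csv_path.write_text("\n".join(lines) + "\n")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "fs": record.fs,
        "record_id": record.record_id,
        "r_peaks": record.r_peaks.tolist(),
        "symbols": record.symbols,
        "labels": [lab.name if lab is not None else None
                   for lab in record.beat_labels],
    }))


def read_csv_record(csv_path, sidecar_path=None) -> ECGRecord:
    from .aami import AAMIClass

    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(f"missing CSV file: {csv_path}")
    rows = csv_path.read_text().strip().splitlines()[1:]
    signal = np.array([float(r.split(",")[1]) for r in rows])
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    labels = [AAMIClass[v] if v is not None else None for v in meta["labels"]]
    return ECGRecord(signal=signal, fs=meta["fs"],
                     r_peaks=np.asarray(meta["r_peaks"], dtype=int),
                     beat_labels=labels, symbols=meta.get("symbols"),
                     record_id=meta.get("record_id", csv_path.stem))
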