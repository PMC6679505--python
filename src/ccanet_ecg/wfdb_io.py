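"""Minimal WFDB (PhysioNet) record and annotation adapter.

Reads the subset of the WFDB format family needed for the MIT-BIH and INCART
arrhythmia databases: ``.hea`` headers, ``.dat`` signals in format 16
(little-endian int16) and format 212 (packed 12-bit pairs), and MIT-format
beat annotations (``.atr``).  Writing is supported for format 16 and MIT
annotations so synthetic records can round-trip through the adapter.

Signals are returned in physical units: ``(adc - baseline) / gain``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

# Annotation code <-> symbol table (MIT annotation codes; beat labels only
# need a subset, but the full printable set keeps real records readable).
CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "x", 33: "[", 34: "]", 35: "f",
    36: "n", 37: "r", 38: "e",
}
SYMBOL_TO_CODE: dict[str, int] = {s: c for c, s in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalInfo:
    file_name: str
    fmt: int
    gain: float = 200.0
    baseline: int = 0
    units: str = "mV"
    description: str = ""


@dataclass
class RecordHeader:
    name: str
    n_sig: int
    fs: float
    n_samp: int
    signals: list[SignalInfo] = field(default_factory=list)


def read_header(path: str) -> RecordHeader:
    """Parse a ``.hea`` file (comment lines starting with '#' are skipped)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    name = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samp = int(first[3]) if len(first) > 3 else 0
    hdr = RecordHeader(name, n_sig, fs, n_samp)
    for ln in lines[1: 1 + n_sig]:
        parts = ln.split()
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        info = SignalInfo(file_name=parts[0], fmt=fmt)
        explicit_baseline = False
        if len(parts) > 2:
            gain_spec = parts[2]
            if "/" in gain_spec:
                gain_spec, info.units = gain_spec.split("/", 1)
            if "(" in gain_spec:
                gain_spec, base = gain_spec[:-1].split("(")
                info.baseline = int(base)
                explicit_baseline = True
            info.gain = float(gain_spec) or 200.0
        if len(parts) > 4 and not explicit_baseline:
            # without an explicit (baseline), the ADC zero (field 5) is used
            info.baseline = int(parts[4])
        if len(parts) > 8:
            info.description = " ".join(parts[8:])
        hdr.signals.append(info)
    return hdr


def _read_fmt16(data: bytes, n_sig: int) -> np.ndarray:
    flat = np.frombuffer(data, dtype="<i2")
    flat = flat[: (flat.size // n_sig) * n_sig]
    return flat.reshape(-1, n_sig).T.astype(np.int32)


def _read_fmt212(data: bytes, n_sig: int) -> np.ndarray:
    raw = np.frombuffer(data, dtype=np.uint8)
    raw = raw[: (raw.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
    s1 = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
    s0[s0 > 2047] -= 4096
    s1[s1 > 2047] -= 4096
    flat = np.empty(raw.shape[0] * 2, dtype=np.int32)
    flat[0::2], flat[1::2] = s0, s1
    flat = flat[: (flat.size // n_sig) * n_sig]
    return flat.reshape(-1, n_sig).T


def read_record(path_prefix: str) -> tuple[np.ndarray, RecordHeader]:
    """Read ``<prefix>.hea`` + its ``.dat``; returns (physical (n_sig, T), header)."""
    hdr = read_header(path_prefix + ".hea")
    base_dir = os.path.dirname(path_prefix)
    by_file: dict[str, list[int]] = {}
    for idx, s in enumerate(hdr.signals):
        by_file.setdefault(s.file_name, []).append(idx)
    out = [np.empty(0)] * hdr.n_sig
    for fname, idxs in by_file.items():
        fmt = hdr.signals[idxs[0]].fmt
        with open(os.path.join(base_dir, fname), "rb") as fh:
            data = fh.read()
        if fmt == 16:
            digital = _read_fmt16(data, len(idxs))
        elif fmt == 212:
            digital = _read_fmt212(data, len(idxs))
        else:
            raise ValueError(f"unsupported WFDB signal format {fmt}")
        for k, idx in enumerate(idxs):
            s = hdr.signals[idx]
            out[idx] = (digital[k].astype(float) - s.baseline) / s.gain
    n = min(sig.size for sig in out)
    if hdr.n_samp:
        n = min(n, hdr.n_samp)
    return np.stack([sig[:n] for sig in out]), hdr


def write_record(directory: str, name: str, signal: np.ndarray, fs: float,
                 units: str = "mV", gain: float = 200.0,
                 lead_names: list[str] | None = None) -> str:
    """Write a format-16 record ``<directory>/<name>.hea/.dat``.

    ``signal`` is physical-valued (n_sig, T); samples are quantized with the
    given gain and clipped to the int16 range.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n_sig, n_samp = signal.shape
    digital = np.clip(np.round(signal * gain), -32768, 32767).astype("<i2")
    dat_name = f"{name}.dat"
    with open(os.path.join(directory, dat_name), "wb") as fh:
        fh.write(digital.T.reshape(-1).tobytes())
    lead_names = lead_names or [f"sig{i}" for i in range(n_sig)]
    lines = [f"{name} {n_sig} {fs:g} {n_samp}"]
    for i in range(n_sig):
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/{units} 16 0 0 0 0 {lead_names[i]}")
    path = os.path.join(directory, f"{name}.hea")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def read_annotations(path: str) -> tuple[np.ndarray, list[str]]:
    """Decode a MIT-format annotation file into (sample indices, symbols).

    Only beat-type annotations (codes 1..49) are returned; NUM/SUB/CHN/AUX
    modifiers are consumed and discarded.
    """
    with open(path, "rb") as fh:
        words = np.frombuffer(fh.read(), dtype="<u2")
    samples: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    while i < words.size:
        w = int(words[i])
        code, interval = w >> 10, w & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            t += (int(words[i + 1]) << 16) | int(words[i + 2])
            i += 3
            continue
        if code == _AUX:
            i += 1 + (interval + 1) // 2
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        t += interval
        if 1 <= code < 50:
            samples.append(t)
            symbols.append(CODE_TO_SYMBOL.get(code, "Q"))
        i += 1
    return np.asarray(samples, dtype=int), symbols


def write_annotations(path: str, samples: np.ndarray, symbols: list[str]) -> None:
    """Encode beat annotations in MIT format (inverse of :func:`read_annotations`)."""
    samples = np.asarray(samples, dtype=int)
    if samples.size and np.any(np.diff(samples) < 0):
        raise ValueError("annotation samples must be sorted ascending")
    if samples.size != len(symbols):
        raise ValueError("samples and symbols must have equal length")
    words: list[int] = []
    t = 0
    for s, sym in zip(samples, symbols):
        delta = int(s) - t
        code = SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"unknown annotation symbol {sym!r}")
        if delta >= 1024:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        t = int(s)
    words.append(0)  # EOF
    with open(path, "wb") as fh:
        fh.write(np.asarray(words, dtype="<u2").tobytes())
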