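"""Beat segmentation, per-beat min-max normalization, and matrix reshaping.

A heartbeat is the window of ``S1`` samples left and ``S2`` samples right of
an annotated R peak (360 samples at 360 Hz for the MIT-BIH protocol, 256 at
257 Hz for the INCART protocol).  Each beat of each lead is independently
mapped to [0, 1] by min-max scaling and then reshaped into an m x n matrix so
the 2-D convolutional cascade can consume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Segmentation constants of the two supported evaluation protocols.
MITDB_SPEC_ARGS = (160, 200)   # 360 samples at 360 Hz
INCART_SPEC_ARGS = (120, 136)  # 256 samples at 257 Hz


@dataclass(frozen=True)
class SegmentationSpec:
    """Window bounds around the R fiducial point, in samples."""

    s1: int
    s2: int

    def __post_init__(self) -> None:
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError(f"S1 and S2 must be > 0, got {self.s1}, {self.s2}")

    @property
    def beat_length(self) -> int:
        return self.s1 + self.s2


def segment_beats(signals: np.ndarray | Sequence[np.ndarray],
                  r_peaks: Sequence[int],
                  spec: SegmentationSpec,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Cut lead-aligned beat windows ``[p - S1, p + S2)`` around each R peak.

    Peaks too close to either record boundary are dropped from *all* leads so
    beat i of every lead always comes from the same peak.

    Returns ``(beats, kept)`` where ``beats`` has shape
    (n_leads, n_kept, S1+S2) and ``kept`` are the indices (into ``r_peaks``)
    of the peaks that produced a beat.
    """
    sigs = [np.asarray(s, dtype=float) for s in signals]
    lengths = {s.shape[-1] for s in sigs}
    if any(s.ndim != 1 for s in sigs) or not sigs:
        raise ValueError("signals must be a non-empty set of 1-D per-lead arrays")
    if len(lengths) != 1:
        raise ValueError(f"all leads must have the same length, got {sorted(lengths)}")
    total = lengths.pop()
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size and np.any(np.diff(r_peaks) < 0):
        raise ValueError("r_peaks must be sorted ascending")
    kept = np.flatnonzero((r_peaks >= spec.s1) & (r_peaks + spec.s2 <= total))
    beats = np.empty((len(sigs), kept.size, spec.beat_length))
    for h, sig in enumerate(sigs):
        for j, idx in enumerate(kept):
            p = r_peaks[idx]
            beats[h, j] = sig[p - spec.s1: p + spec.s2]
    return beats, kept


def normalize_beat(beat: np.ndarray) -> np.ndarray:
    """Min-max scale one beat to [0, 1]; a flat beat maps to all zeros."""
    beat = np.asarray(beat, dtype=float)
    if beat.size == 0:
        raise ValueError("beat must be non-empty")
    lo, hi = beat.min(), beat.max()
    if hi == lo:
        logger.warning("flat beat (max == min == %g): normalized to zeros", lo)
        return np.zeros_like(beat)
    return (beat - lo) / (hi - lo)


def normalize_beats(beats: np.ndarray) -> np.ndarray:
    """Vectorized per-beat, per-lead normalization of a (..., L) beat array."""
    beats = np.asarray(beats, dtype=float)
    lo = beats.min(axis=-1, keepdims=True)
    hi = beats.max(axis=-1, keepdims=True)
    span = hi - lo
    flat = span == 0
    if np.any(flat):
        logger.warning("%d flat beat(s) normalized to zeros", int(flat.sum()))
    span = np.where(flat, 1.0, span)
    out = (beats - lo) / span
    return np.where(flat, 0.0, out)


def beat_to_matrix(beat: np.ndarray, m: int, n: int, order: str = "C"
                   ) -> np.ndarray:
    """Reshape a beat vector into an m x n ECG matrix in the given fill order."""
    beat = np.asarray(beat)
    if m * n != beat.size:
        raise ValueError(
            f"matrix shape {m}x{n} = {m * n} does not match beat length {beat.size}")
    return beat.reshape(m, n, order=order)


def matrix_to_beat(matrix: np.ndarray, order: str = "C") -> np.ndarray:
    """Inverse of :func:`beat_to_matrix` (same fill order)."""
    return np.asarray(matrix).reshape(-1, order=order)


def default_matrix_shape(beat_length: int) -> tuple[int, int]:
    """Near-square factorization of the beat length (360 -> 18x20, 256 -> 16x16).

    A near-square matrix minimizes the share of patch windows that straddle
    the zero-padded border.  Of all factor pairs m <= n the one with the
    smallest aspect gap is returned.
    """
    best = (1, beat_length)
    for m in range(1, int(np.sqrt(beat_length)) + 1):
        if beat_length % m == 0:
            best = (m, beat_length // m)
    return best


# ---------------------------------------------------------------------------
# annotation-symbol mapping (WFDB adapter support)

def load_symbol_map(path: str) -> dict[str, str]:
    """Read a user-editable two-column text file: annotation symbol -> class.

    Lines starting with '#' are comments.  Columns are whitespace-separated;
    a symbol may be any single token (e.g. ``!`` or ``/``).
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'symbol class', got {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def map_symbols(symbols: Iterable[str], mapping: Mapping[str, str]
                ) -> tuple[list[str], np.ndarray]:
    """Map annotation symbols to class codes, dropping unmapped symbols.

    Returns ``(labels, kept_mask)``; beats whose symbol is outside the
    configured class set are skipped (mask False), mirroring class-inventory
    selection on the real databases.
    """
    labels, mask = [], []
    for s in symbols:
        hit = s in mapping
        mask.append(hit)
        if hit:
            labels.append(mapping[s])
    return labels, np.asarray(mask, dtype=bool)
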