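"""The cascaded two-stage convolutional hashing network.

Pipeline per beat (per lead h, with m x n ECG matrices):

1. layer 1: convolve with each of the lead's L1 filters -> preliminary
   feature blocks (PFBs);
2. layer 2: convolve each PFB with each of the lead's L2 filters;
3. for each layer-1 filter index l, horizontally concatenate the per-lead
   layer-2 maps into one m x (n_leads*n) map per layer-2 index, binarize at
   zero, and combine the L2 binary maps bitwise into a decimal map T_l with
   values in [0, 2^L2 - 1];
4. block-wise histograms of each T_l (u1 x u2 blocks, overlap ratio R) are
   concatenated into the final feature vector of length 2^L2 * L1 * B.

Filter banks are learned by CCA across leads (two-lead and three-lead
variants with a cyclic lead-pairing schedule), or per lead by PCA / random
draws for the single-view baselines.  Convolution means zero-padded,
same-size cross-correlation, consistent with the patch order used during
filter learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import scipy.ndimage

from ccanet_ecg.filters import (
    FilterBank,
    build_pending_matrix,
    cca_filter_pair,
    im2col_batch,
    pca_filter_bank,
    random_filter_bank,
    DEFAULT_RIDGE,
)

MODES = ("cca", "pca", "rand")


@dataclass(frozen=True)
class NetworkParams:
    """Architecture hyperparameters.

    Defaults are the published operating point: 7x7 patches, 9 filters per
    layer, 7x7 histogram blocks at overlap ratio 0.5.  ``m`` x ``n`` is the
    ECG-matrix shape (16x16 suits 256-sample beats, 18x20 suits 360-sample
    beats).
    """

    n_leads: int = 2
    t1: int = 7
    t2: int = 7
    L1: int = 9
    L2: int = 9
    u1: int = 7
    u2: int = 7
    R: float = 0.5
    m: int = 16
    n: int = 16
    mode: str = "cca"
    ridge: float = DEFAULT_RIDGE
    rand_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "cca" and self.n_leads not in (2, 3):
            raise ValueError("CCA filter learning needs 2 or 3 leads, got "
                             f"{self.n_leads}")
        if self.n_leads < 1:
            raise ValueError(f"n_leads must be >= 1, got {self.n_leads}")
        if self.t1 % 2 == 0 or self.t2 % 2 == 0:
            raise ValueError(f"patch size must be odd, got {self.t1}x{self.t2}")
        if not 0.0 < self.R < 1.0:
            raise ValueError(f"overlap ratio R must be in (0, 1), got {self.R}")
        for name, L in (("L1", self.L1), ("L2", self.L2)):
            if not 1 <= L <= self.t1 * self.t2:
                raise ValueError(
                    f"{name}={L} outside 1..t1*t2={self.t1 * self.t2}")
        if self.t1 > self.m or self.t2 > self.n:
            raise ValueError(f"patch {self.t1}x{self.t2} exceeds matrix "
                             f"{self.m}x{self.n}")
        if self.u1 > self.m or self.u2 > self.n_leads * self.n:
            raise ValueError(
                f"block {self.u1}x{self.u2} exceeds decimal-map shape "
                f"{self.m}x{self.n_leads * self.n}")

    @property
    def decimal_shape(self) -> tuple[int, int]:
        """Shape of each decimal map (leads concatenated horizontally)."""
        return self.m, self.n_leads * self.n


@dataclass
class CCANetModel:
    """Fitted network: per-lead layer-1 and layer-2 filter banks."""

    params: NetworkParams
    layer1_banks: list[FilterBank]
    layer2_banks: list[FilterBank]

    def __post_init__(self) -> None:
        p = self.params
        if len(self.layer1_banks) != p.n_leads or len(self.layer2_banks) != p.n_leads:
            raise ValueError("one filter bank per lead and layer required")
        for bank, L in ((self.layer1_banks, p.L1), (self.layer2_banks, p.L2)):
            if any(b.n_filters != L for b in bank):
                raise ValueError("filter counts do not match params")


def convolve_same(mat: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Zero-padded, centered cross-correlation; output shape = input shape."""
    mat = np.asarray(mat, dtype=float)
    filt = np.asarray(filt, dtype=float)
    if filt.shape[0] % 2 == 0 or filt.shape[1] % 2 == 0:
        raise ValueError(f"filter dimensions must be odd, got {filt.shape}")
    if filt.shape[0] > mat.shape[0] or filt.shape[1] > mat.shape[1]:
        raise ValueError(
            f"filter {filt.shape} larger than map {mat.shape}")
    return scipy.ndimage.correlate(mat, filt, mode="constant", cval=0.0)


def _conv_bank_batch(maps: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Correlate a (B, m, n) stack with every filter: returns (B, L, m, n).

    Uses the same patch-matrix product that defines the filters, which is
    numerically identical to per-map :func:`convolve_same`.
    """
    b, m, n = maps.shape
    k1, k2 = bank.shape
    cols = im2col_batch(maps, k1, k2, center=False)  # (k1k2, B*m*n)
    flat = bank.filters.reshape(bank.n_filters, k1 * k2)
    out = flat @ cols  # (L, B*m*n)
    return out.reshape(bank.n_filters, b, m, n).transpose(1, 0, 2, 3)


def binarize(mat: np.ndarray) -> np.ndarray:
    """Heaviside hash: 1 where value > 0, else 0 (exact zeros map to 0)."""
    return (np.asarray(mat) > 0).astype(np.int64)


def decimal_encode(sfb_maps: np.ndarray) -> np.ndarray:
    """Bitwise-combine L2 binary maps: ``T = sum_l 2^(l-1) * map_l``.

    ``sfb_maps`` is (L2, rows, cols) in layer-2 filter order; entry values
    land in [0, 2^L2 - 1].
    """
    maps = np.asarray(sfb_maps)
    if maps.ndim != 3:
        raise ValueError("expected a (L2, rows, cols) stack of binary maps")
    weights = 1 << np.arange(maps.shape[0], dtype=np.int64)
    return np.tensordot(weights, maps.astype(np.int64), axes=1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def block_starts(size: int, u: int, R: float) -> np.ndarray:
    """Start offsets of fully-contained blocks at overlap ratio R.

    Stride = max(1, round_half_up(u * (1 - R))); partial border blocks are
    dropped so each block holds exactly u values along this axis.
    """
    stride = max(1, _round_half_up(u * (1.0 - R)))
    return np.arange(0, size - u + 1, stride)


def block_count(rows: int, cols: int, u1: int, u2: int, R: float) -> int:
    """Number of histogram blocks B for a rows x cols decimal map."""
    if u1 > rows or u2 > cols:
        raise ValueError(f"block {u1}x{u2} larger than map {rows}x{cols}")
    return len(block_starts(rows, u1, R)) * len(block_starts(cols, u2, R))


def block_histogram(T: np.ndarray, u1: int, u2: int, R: float, L2: int
                    ) -> np.ndarray:
    """Concatenated per-block count histograms of one decimal map.

    Blocks are scanned in row-major order; each contributes a 2^L2-bin count
    histogram over the values 0 .. 2^L2 - 1.  Output length: 2^L2 * B.
    """
    T = np.asarray(T)
    rows, cols = T.shape
    if u1 > rows or u2 > cols:
        raise ValueError(f"block {u1}x{u2} larger than map {rows}x{cols}")
    n_bins = 1 << L2
    if T.min() < 0 or T.max() >= n_bins:
        raise ValueError("decimal map values outside [0, 2^L2 - 1]")
    r_starts = block_starts(rows, u1, R)
    c_starts = block_starts(cols, u2, R)
    out = np.empty(n_bins * len(r_starts) * len(c_starts), dtype=np.int64)
    k = 0
    for r in r_starts:
        for c in c_starts:
            block = T[r:r + u1, c:c + u2]
            out[k:k + n_bins] = np.bincount(block.ravel(), minlength=n_bins)
            k += n_bins
    return out


def feature_length(params: NetworkParams) -> int:
    """``2^L2 * L1 * B`` for the configured architecture."""
    rows, cols = params.decimal_shape
    B = block_count(rows, cols, params.u1, params.u2, params.R)
    return (1 << params.L2) * params.L1 * B


# ---------------------------------------------------------------------------
# fitting

def _as_lead_stacks(beats_by_lead) -> np.ndarray:
    arr = np.asarray(beats_by_lead, dtype=float)
    if arr.ndim != 4:
        raise ValueError("beats_by_lead must be (n_leads, N, m, n)")
    return arr


def fit(beats_by_lead, params: NetworkParams) -> CCANetModel:
    """Learn per-lead layer-1 and layer-2 filter banks.

    ``beats_by_lead`` is (n_leads, N, m, n): the same N beats, lead-aligned,
    already normalized and reshaped.  In ``cca`` mode the two-lead variant
    runs one CCA per layer (first view -> lead-1 bank, second -> lead-2); the
    three-lead variant uses the cyclic schedules: layer 1 pairs
    (X1,X2), (X2,X3), (X3,X1), keeping the *first* view's vectors for leads
    1..3; layer 2 pairs (Y3,Y1), (Y1,Y2), (Y2,Y3), keeping the *second*
    view's vectors.  ``pca`` and ``rand`` modes build per-lead banks from the
    same pending matrices.
    """
    beats = _as_lead_stacks(beats_by_lead)
    n_leads, N, m, n = beats.shape
    p = params
    if n_leads != p.n_leads:
        raise ValueError(f"params expect {p.n_leads} leads, data has {n_leads}")
    if (m, n) != (p.m, p.n):
        raise ValueError(f"params expect {p.m}x{p.n} matrices, got {m}x{n}")
    if N < 2:
        raise ValueError("at least 2 beats are required for filter learning")

    X = [build_pending_matrix(beats[h], p.t1, p.t2, lead_id=h)
         for h in range(n_leads)]
    layer1 = _learn_banks(X, p, layer=1, L=p.L1)

    # preliminary feature blocks feed the layer-2 pending matrices
    pfbs = [_conv_bank_batch(beats[h], layer1[h]) for h in range(n_leads)]
    # (N, L1, m, n) -> filter-major stack (L1*N, m, n)
    Y = [build_pending_matrix(
            pfbs[h].transpose(1, 0, 2, 3).reshape(p.L1 * N, m, n),
            p.t1, p.t2, lead_id=h)
         for h in range(n_leads)]
    layer2 = _learn_banks(Y, p, layer=2, L=p.L2)
    return CCANetModel(p, layer1, layer2)


def _learn_banks(views, p: NetworkParams, layer: int, L: int
                 ) -> list[FilterBank]:
    n_leads = len(views)
    if p.mode == "pca":
        return [pca_filter_bank(v, L, layer=layer) for v in views]
    if p.mode == "rand":
        return [random_filter_bank(p.t1, p.t2, L,
                                   seed=p.rand_seed + 1000 * layer + h,
                                   layer=layer, lead_id=h)
                for h, v in enumerate(views)]
    if n_leads == 2:
        b1, b2 = cca_filter_pair(views[0], views[1], L, p.ridge, layer=layer)
        return [b1, b2]
    banks: list[FilterBank] = []
    for h in range(3):
        if layer == 1:
            first, _ = cca_filter_pair(views[h], views[(h + 1) % 3], L,
                                       p.ridge, layer=layer)
            banks.append(first)
        else:
            _, second = cca_filter_pair(views[(h - 1) % 3], views[h], L,
                                        p.ridge, layer=layer)
            banks.append(second)
    return banks


# ---------------------------------------------------------------------------
# feature extraction

def transform(model: CCANetModel, beat_by_lead) -> np.ndarray:
    """Feature vector of one beat given as (n_leads, m, n) matrices."""
    beat = np.asarray(beat_by_lead, dtype=float)
    if beat.ndim != 3:
        raise ValueError("beat_by_lead must be (n_leads, m, n)")
    return transform_many(model, beat[:, None])[0]


def transform_many(model: CCANetModel, beats_by_lead) -> np.ndarray:
    """Feature matrix (N, 2^L2 * L1 * B) for lead-aligned beats.

    For each layer-1 filter index l, each lead's l-th PFB is convolved with
    that lead's layer-2 filters; per layer-2 index the n_leads maps are
    horizontally concatenated, binarized and bit-packed into a decimal map,
    whose block histograms are concatenated over l.
    """
    beats = _as_lead_stacks(beats_by_lead)
    p = model.params
    n_leads, N, m, n = beats.shape
    if n_leads != p.n_leads or (m, n) != (p.m, p.n):
        raise ValueError(
            f"model expects (n_leads, N, {p.m}, {p.n}) with "
            f"{p.n_leads} leads, got {beats.shape}")
    n_bins = 1 << p.L2
    weights = (1 << np.arange(p.L2, dtype=np.int64))[:, None, None]
    rows, cols = p.decimal_shape
    B = block_count(rows, cols, p.u1, p.u2, p.R)
    out = np.empty((N, n_bins * p.L1 * B), dtype=np.int64)
    seg = n_bins * B
    for i in range(N):
        pfb = [_conv_bank_batch(beats[h, i][None], model.layer1_banks[h])[0]
               for h in range(n_leads)]  # per lead: (L1, m, n)
        sfb = [_conv_bank_batch(pfb[h], model.layer2_banks[h])
               for h in range(n_leads)]  # per lead: (L1, L2, m, n)
        for l in range(p.L1):
            concat = np.concatenate([sfb[h][l] for h in range(n_leads)],
                                    axis=2)  # (L2, m, n_leads*n)
            T = ((concat > 0).astype(np.int64) * weights).sum(axis=0)
            out[i, l * seg:(l + 1) * seg] = block_histogram(
                T, p.u1, p.u2, p.R, p.L2)
    return out


# ---------------------------------------------------------------------------
# persistence

def save_model(model: CCANetModel, path: str) -> None:
    """Serialize a fitted model to an array container with a JSON header."""
    arrays: dict[str, np.ndarray] = {
        "params_json": np.frombuffer(
            json.dumps(asdict(model.params)).encode(), dtype=np.uint8)}
    for layer, banks in ((1, model.layer1_banks), (2, model.layer2_banks)):
        for h, bank in enumerate(banks):
            arrays[f"l{layer}_h{h}_filters"] = bank.filters
            arrays[f"l{layer}_h{h}_corr"] = bank.correlations
    np.savez_compressed(path, **arrays)


def load_model(path: str) -> CCANetModel:
    with np.load(path, allow_pickle=False) as f:
        params = NetworkParams(**json.loads(bytes(f["params_json"]).decode()))
        banks: dict[int, list[FilterBank]] = {1: [], 2: []}
        for layer in (1, 2):
            for h in range(params.n_leads):
                banks[layer].append(FilterBank(
                    f[f"l{layer}_h{h}_filters"], layer, h, params.mode,
                    f[f"l{layer}_h{h}_corr"]))
    return CCANetModel(params, banks[1], banks[2])


def save_features(features: np.ndarray, path: str) -> None:
    """Dense array container (.npz) or sparse triplet text (.txt) export."""
    features = np.asarray(features)
    if path.endswith(".txt"):
        rows, cols = np.nonzero(features)
        with open(path, "w") as fh:
            fh.write(f"# shape {features.shape[0]} {features.shape[1]}\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r} {c} {features[r, c]}\n")
    else:
        np.savez_compressed(path, features=features)


def load_features(path: str) -> np.ndarray:
    if path.endswith(".txt"):
        with open(path) as fh:
            header = fh.readline().split()
            shape = (int(header[2]), int(header[3]))
            out = np.zeros(shape, dtype=np.int64)
            for line in fh:
                r, c, v = line.split()
                out[int(r), int(c)] = int(v)
        return out
    with np.load(path, allow_pickle=False) as f:
        return f["features"]
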