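"""Convolutional filter-bank learning from patch ("pending") matrices.

A pending matrix collects, column by column, every t1 x t2 patch (centered on
each pixel, zero-padded at the borders) of every input map of one lead, with
the patch mean removed.  Filters are then learned from these columns:

* **CCA filters** - for a pair of leads, the top-L canonical vector pairs of
  the two pending matrices, each reshaped back onto the patch grid.  The
  canonical pair (a_l, b_l) maximizes ``a' S12 b`` subject to the unit-variance
  constraints ``a' S11 a = 1``, ``b' S22 b = 1`` and S-orthogonality to earlier
  pairs, with ``Sij = Xi Xj'``.  Solved here via the symmetric whitened
  eigenproblem for ``a``; ``b`` follows as ``S22^{-1} S21 a``, renormalized.
* **PCA filters** - top-L eigenvectors of ``X X'`` (single-view baseline).
* **Random filters** - unit-norm i.i.d. Gaussian kernels (baseline).

Covariances get a small ridge (relative to their mean diagonal) before
inversion; flat-patch regions otherwise make them singular.  Every canonical
or principal vector is sign-fixed so its largest-magnitude component is
positive, which makes learned filters reproducible: the objective is invariant
to jointly flipping a pair, so some convention is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

#: relative ridge added to each view's covariance diagonal before inversion
DEFAULT_RIDGE = 1e-8


@dataclass
class PendingMatrix:
    """Zero-centered vectorized patches: ``data`` is (t1*t2, n_patches)."""

    data: np.ndarray
    t1: int
    t2: int
    lead_id: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.t1 * self.t2:
            raise ValueError(
                f"pending matrix must be ({self.t1 * self.t2}, N), "
                f"got {self.data.shape}")

    @property
    def dim(self) -> int:
        return self.data.shape[0]

    @property
    def column_count(self) -> int:
        return self.data.shape[1]


@dataclass
class FilterBank:
    """Ordered bank of L convolution kernels of size k1 x k2.

    ``correlations`` holds the canonical correlation of each filter (sorted
    descending) in CCA mode and is empty for PCA/random banks.
    """

    filters: np.ndarray  # (L, k1, k2)
    layer: int
    lead_id: int | None = None
    mode: str = "cca"
    correlations: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.filters.ndim != 3:
            raise ValueError("filters must be (L, k1, k2)")
        L, k1, k2 = self.filters.shape
        if L > k1 * k2:
            raise ValueError(f"filter count {L} exceeds patch size {k1 * k2}")
        if self.correlations.size:
            if self.correlations.size != L:
                raise ValueError("one correlation per filter required")
            if np.any(np.diff(self.correlations) > 1e-12):
                raise ValueError("correlations must be sorted descending")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.filters.shape[1], self.filters.shape[2]


def _check_patch(t1: int, t2: int, m: int, n: int) -> None:
    if t1 % 2 == 0 or t2 % 2 == 0:
        raise ValueError(f"patch size must be odd, got {t1}x{t2}")
    if t1 > m or t2 > n:
        raise ValueError(f"patch {t1}x{t2} exceeds map size {m}x{n}")


def im2col(mat: np.ndarray, t1: int, t2: int, center: bool = False
           ) -> np.ndarray:
    """All t1 x t2 patches of ``mat`` centered on each pixel, as columns.

    The map is zero-padded by the half patch so an m x n input yields exactly
    m*n patches.  Each patch is vectorized row-major; with ``center=True`` its
    mean is subtracted first.  Output shape: (t1*t2, m*n); column order is the
    row-major pixel order.
    """
    mat = np.asarray(mat, dtype=float)
    m, n = mat.shape
    _check_patch(t1, t2, m, n)
    padded = np.pad(mat, ((t1 // 2,), (t2 // 2,)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (t1, t2))
    cols = win.reshape(m * n, t1 * t2).T.copy()
    if center:
        cols -= cols.mean(axis=0, keepdims=True)
    return cols


def im2col_batch(maps: np.ndarray, t1: int, t2: int, center: bool = False
                 ) -> np.ndarray:
    """:func:`im2col` over a (B, m, n) stack; columns concatenated per map."""
    maps = np.asarray(maps, dtype=float)
    b, m, n = maps.shape
    _check_patch(t1, t2, m, n)
    padded = np.pad(maps, ((0,), (t1 // 2,), (t2 // 2,)))
    win = np.lib.stride_tricks.sliding_window_view(padded, (t1, t2), axis=(1, 2))
    cols = win.reshape(b * m * n, t1 * t2).T.copy()
    if center:
        cols -= cols.mean(axis=0, keepdims=True)
    return cols


def build_pending_matrix(matrices, t1: int, t2: int,
                         lead_id: int | None = None) -> PendingMatrix:
    """Assemble the pending matrix of one lead from its maps.

    ``matrices`` is a sequence of equally-shaped 2-D maps (ECG matrices or
    feature maps) or a (B, m, n) array.  N maps of size m x n give N*m*n
    zero-centered patch columns.
    """
    maps = np.asarray(matrices, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    if maps.ndim != 3:
        raise ValueError("matrices must be 2-D maps or a (B, m, n) stack")
    return PendingMatrix(im2col_batch(maps, t1, t2, center=True), t1, t2, lead_id)


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude component is positive."""
    vectors = vectors.copy()
    idx = np.argmax(np.abs(vectors), axis=0)
    flip = vectors[idx, np.arange(vectors.shape[1])] < 0
    vectors[:, flip] *= -1.0
    return vectors


def _ridge_chol(S: np.ndarray, ridge: float, view: str) -> np.ndarray:
    d = S.shape[0]
    S = S + np.eye(d) * (ridge * np.trace(S) / d)
    try:
        return scipy.linalg.cholesky(S, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance of {view} is rank-deficient even after ridge "
            f"regularization") from exc


def cca_core(X1: np.ndarray, X2: np.ndarray, L: int,
             ridge: float = DEFAULT_RIDGE
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-L canonical vector pairs of two views with matching columns.

    Returns ``(A, B, rho)`` with A, B of shape (dim, L) and the canonical
    correlations ``rho`` sorted descending.  Normalizations: ``a' S11 a = 1``,
    ``b' S22 b = 1`` with ``Sij = Xi Xj'`` (unnormalized second moments; the
    canonical directions are scale-invariant).
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("views must have the same number of columns")
    if L > X1.shape[0] or L > X2.shape[0]:
        raise ValueError(f"L={L} exceeds view dimension "
                         f"{min(X1.shape[0], X2.shape[0])}")
    S11 = X1 @ X1.T
    S22 = X2 @ X2.T
    S12 = X1 @ X2.T
    L11 = _ridge_chol(S11, ridge, "view 1")
    L22 = _ridge_chol(S22, ridge, "view 2")
    # whitened symmetric form of S11^-1 S12 S22^-1 S21 a = rho^2 a
    G = scipy.linalg.solve_triangular(L11, S12, lower=True)
    H = scipy.linalg.solve_triangular(L22, G.T, lower=True)  # L22^-1 S21 L11^-T
    M = H.T @ H
    evals, evecs = scipy.linalg.eigh(M)
    order = np.argsort(evals)[::-1][:L]
    rho = np.sqrt(np.clip(evals[order], 0.0, None))
    U = evecs[:, order]
    A = scipy.linalg.solve_triangular(L11, U, lower=True, trans="T")
    # pair b with a through the stationarity condition S21 a = lambda S22 b
    S21A = S12.T @ A
    B = scipy.linalg.cho_solve((L22, True), S21A)
    norms = np.sqrt(np.einsum("ij,ij->j", B, S22 @ B))
    norms[norms == 0] = 1.0
    B /= norms
    return _fix_sign(A), _fix_sign(B), rho


def cca_filter_pair(X1: PendingMatrix, X2: PendingMatrix, L: int,
                    ridge: float = DEFAULT_RIDGE, layer: int = 1
                    ) -> tuple[FilterBank, FilterBank]:
    """Learn paired CCA filter banks for two leads' pending matrices.

    Each canonical vector (length t1*t2) is reshaped row-major to the t1 x t2
    patch grid - the same pixel order used when patches were vectorized.
    """
    if (X1.t1, X1.t2) != (X2.t1, X2.t2):
        raise ValueError("views must share the patch size")
    A, B, rho = cca_core(X1.data, X2.data, L, ridge)
    k1, k2 = X1.t1, X1.t2
    bank1 = FilterBank(A.T.reshape(L, k1, k2), layer, X1.lead_id, "cca", rho)
    bank2 = FilterBank(B.T.reshape(L, k1, k2), layer, X2.lead_id, "cca", rho)
    return bank1, bank2


def pca_filter_bank(X: PendingMatrix, L: int, layer: int = 1) -> FilterBank:
    """Top-L principal directions of one lead's pending matrix as filters."""
    if L > X.dim:
        raise ValueError(f"L={L} exceeds patch dimension {X.dim}")
    S = X.data @ X.data.T
    evals, evecs = scipy.linalg.eigh(S)
    order = np.argsort(evals)[::-1][:L]
    U = _fix_sign(evecs[:, order])
    return FilterBank(U.T.reshape(L, X.t1, X.t2), layer, X.lead_id, "pca")


def random_filter_bank(k1: int, k2: int, L: int, seed: int = 0,
                       layer: int = 1, lead_id: int | None = None
                       ) -> FilterBank:
    """Seed-deterministic unit-norm Gaussian filters (RandNet baseline)."""
    if L > k1 * k2:
        raise ValueError(f"L={L} exceeds patch size {k1 * k2}")
    rng = np.random.default_rng(seed)
    flat = rng.standard_normal((L, k1 * k2))
    flat /= np.linalg.norm(flat, axis=1, keepdims=True)
    return FilterBank(flat.reshape(L, k1, k2), layer, lead_id, "rand")


# ---------------------------------------------------------------------------
# persistence

def save_filter_bank(bank: FilterBank, path: str) -> None:
    np.savez_compressed(
        path, filters=bank.filters, correlations=bank.correlations,
        layer=bank.layer, mode=bank.mode,
        lead_id=-1 if bank.lead_id is None else bank.lead_id)


def load_filter_bank(path: str) -> FilterBank:
    with np.load(path, allow_pickle=False) as f:
        lead = int(f["lead_id"])
        return FilterBank(f["filters"], int(f["layer"]),
                          None if lead < 0 else lead, str(f["mode"]),
                          f["correlations"])
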