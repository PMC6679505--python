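"""Independent reference implementations used only to cross-check results.

These deliberately take different computational routes than the package:
CCA via explicit whitening and one SVD (the package whitens one view and
solves a symmetric eigenproblem); block positions by brute-force enumeration.
"""

import numpy as np
import scipy.linalg


def cca_svd_oracle(X1, X2, L, ridge=1e-8):
    """Canonical correlations/vectors via inverse-sqrt whitening + SVD."""

    def inv_sqrt(S):
        S = S + np.eye(S.shape[0]) * (ridge * np.trace(S) / S.shape[0])
        evals, evecs = np.linalg.eigh(S)
        return evecs @ np.diag(evals ** -0.5) @ evecs.T

    S11 = X1 @ X1.T
    S22 = X2 @ X2.T
    S12 = X1 @ X2.T
    W1, W2 = inv_sqrt(S11), inv_sqrt(S22)
    U, sig, Vt = np.linalg.svd(W1 @ S12 @ W2)
    A = W1 @ U[:, :L]
    B = W2 @ Vt.T[:, :L]
    return A, B, sig[:L]


def enumerate_blocks(rows, cols, u1, u2, R):
    """Brute-force list of all fully-contained block positions (row-major)."""
    s1 = int(np.floor(u1 * (1.0 - R) + 0.5)) or 1
    s2 = int(np.floor(u2 * (1.0 - R) + 0.5)) or 1
    s1, s2 = max(1, s1), max(1, s2)
    positions = []
    r = 0
    while r + u1 <= rows:
        c = 0
        while c + u2 <= cols:
            positions.append((r, c))
            c += s2
        r += s1
    return positions
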