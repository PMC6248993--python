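"""Least squares with linear inequality constraints (LSI), via NNLS.

Classic Lawson-Hanson reduction: LSI -> LDP -> NNLS.  Solves

    minimize ||A x - b||_2  subject to  G x >= h

for a full-column-rank A (callers append a small ridge block to guarantee
rank). Used to break ties among L1-optimal consensus configurations by
re-minimizing squared residuals over the optimal face.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls


class LsiInfeasible(RuntimeError):
    pass


def ldp(G: np.ndarray, h: np.ndarray, maxiter: int | None = None) -> np.ndarray:
    """Least distance programming: min ||z|| s.t. G z >= h (Lawson-Hanson)."""
    m, n = G.shape
    E = np.vstack([G.T, h[np.newaxis, :]])  # (n+1) x m
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u, rnorm = nnls(E, f, maxiter=maxiter)
    r = E @ u - f
    if abs(r[-1]) < 1e-12:
        raise LsiInfeasible("LDP constraints are incompatible")
    return -r[:-1] / r[-1]


def lsi(
    A: np.ndarray,
    b: np.ndarray,
    G: np.ndarray,
    h: np.ndarray,
    maxiter: int | None = None,
) -> np.ndarray:
    """Solve min ||A x - b|| s.t. G x >= h. A must have full column rank."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[-1] <= s[0] * 1e-12:
        raise LsiInfeasible("A is rank deficient; add a ridge block")
    c = U.T @ b
    # x = V diag(1/s) (z + c)
    GV = (G @ Vt.T) / s[np.newaxis, :]
    z = ldp(GV, h - GV @ c, maxiter=maxiter)
    return Vt.T @ ((z + c) / s)
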