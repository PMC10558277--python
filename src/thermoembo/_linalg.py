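"""Shared sparse linear solver: preconditioned Krylov with direct fallback.

The implicit systems here are diagonally dominant M-matrices, and time
stepping supplies excellent initial guesses, so a Jacobi-preconditioned
BiCGStab usually converges in a handful of iterations; a sparse direct
solve is the fallback. The convergence contract is a relative residual
below 1e-10.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

RTOL = 1e-10


def solve(M: sp.csr_matrix, b: np.ndarray, x0: np.ndarray | None = None):
    """Solve ``M x = b`` to relative residual 1e-10."""
    if x0 is not None:
        d = M.diagonal()
        if np.all(d > 0):
            precond = spla.LinearOperator(M.shape, matvec=lambda v: v / d)
            x, info = spla.bicgstab(
                M, b, x0=x0, rtol=RTOL, atol=0.0, maxiter=500, M=precond
            )
            if info == 0:
                return x
    return spla.spsolve(M, b)
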