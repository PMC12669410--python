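"""Array-algebra kernels for tensor-product smoothing on a grid.

These routines evaluate the linear predictor and the weighted
normal-equation blocks of the Kronecker model matrix ``B = Bs kron Bu``
without ever forming it (generalized linear array model algorithms).  The
row-tensor trick: with ``G_x`` the row-wise self-Kronecker of ``B_x``,

    B' diag(vec W) B  ==  reorder( G_u' W G_s )

which costs O(n c^2) instead of O(n^2 c^2).  All vectorizations are
column-major ('F'), matching ``vec(Bu A Bs') = (Bs kron Bu) vec(A)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _row_tensor(B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker of B with itself: shape (n, c*c), C-ordered pairs."""
    n, c = B.shape
    return (B[:, :, None] * B[:, None, :]).reshape(n, c * c)


@dataclass
class ArrayModelWorkspace:
    """Caches the row-tensor products of the two marginal bases."""

    Bu: np.ndarray
    Bs: np.ndarray
    Gu: np.ndarray = field(init=False)
    Gs: np.ndarray = field(init=False)

    def __post_init__(self):
        self.Gu = _row_tensor(self.Bu)
        self.Gs = _row_tensor(self.Bs)

    @property
    def dims(self):
        return self.Bu.shape + self.Bs.shape  # (n_u, c_u, n_s, c_s)


def glam_eta(Bu: np.ndarray, Bs: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Linear predictor surface ``E = Bu A Bs'`` on the grid."""
    if A.shape != (Bu.shape[1], Bs.shape[1]):
        raise ValueError(
            f"A has shape {A.shape}, expected {(Bu.shape[1], Bs.shape[1])}"
        )
    return Bu @ A @ Bs.T


def glam_inner(ws: ArrayModelWorkspace, W: np.ndarray) -> np.ndarray:
    """Weighted inner product ``B' diag(vec W) B`` with ``B = Bs kron Bu``.

    W is the n_u x n_s weight surface (elementwise >= 0).  Returns the
    symmetric PSD (c_u c_s) x (c_u c_s) matrix.
    """
    n_u, c_u, n_s, c_s = ws.dims
    if W.shape != (n_u, n_s):
        raise ValueError(f"W has shape {W.shape}, expected {(n_u, n_s)}")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    T = ws.Gu.T @ W @ ws.Gs  # (c_u^2, c_s^2)
    T4 = T.reshape(c_u, c_u, c_s, c_s)  # [l, l', m, m']
    # row index of (l, m) in F-order vec is l + c_u*m -> axis order (m, l)
    M = T4.transpose(2, 0, 3, 1).reshape(c_u * c_s, c_u * c_s)
    return (M + M.T) / 2.0


def glam_rhs(ws: ArrayModelWorkspace, W: np.ndarray, Z: np.ndarray
             ) -> np.ndarray:
    """Weighted right-hand side ``B' diag(vec W) vec(Z)``.

    Computed as ``Bu' (W * Z) Bs`` then vectorized column-major.
    """
    n_u, c_u, n_s, c_s = ws.dims
    if W.shape != (n_u, n_s) or Z.shape != (n_u, n_s):
        raise ValueError("W and Z must both match the grid shape")
    return (ws.Bu.T @ (W * Z) @ ws.Bs).ravel(order="F")


def kron_design(Bu: np.ndarray, Bs: np.ndarray) -> np.ndarray:
    """Dense Kronecker model matrix ``Bs kron Bu``.

    Rows follow column-major grid order (u fastest).  Retained as the
    reference path for tests and for tiny problems; the array kernels above
    are the default.
    """
    return np.kron(Bs, Bu)
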