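"""Discretized selective scan (S6) primitives.

The continuous state-space system  h' = A h + B v,  y = C h + D v  is
discretized with the zeroth-order hold rule,

    A_bar = exp(dt * A),        B_bar = (exp(dt*A) - I) A^{-1} B  ~  dt * B,

the B_bar approximation being first order in dt.  The recurrence

    h_k = A_bar_k h_{k-1} + B_bar_k v_k,     y_k = C_k h_k + D v_k

runs once per channel with a diagonal state matrix and token-dependent
(dt, B, C), which is what makes the scan *selective*.  The inner loops are
numba-compiled; the custom autodiff op below wires the hand-derived adjoint
recurrence into the tape.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.linalg import expm

from .autodiff import Tensor, _make


def s6_discretize(A: np.ndarray, B: np.ndarray, delta: float | np.ndarray):
    """Zeroth-order-hold discretization of a state matrix.

    Parameters
    ----------
    A : (N, N) array or (N,) diagonal
        Stable state matrix (negative real parts for a decaying state).
    B : array
        Input projection; returned scaled by ``delta`` (first-order
        approximation of the exact ZOH input matrix).
    delta : positive scalar or array broadcastable with A's diagonal
        Step size.

    Returns
    -------
    (A_bar, B_bar)
        ``A_bar = exp(delta*A)`` (matrix exponential for square A,
        elementwise for a diagonal vector), ``B_bar = delta * B``.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if np.any(np.asarray(delta) <= 0):
        raise ValueError("delta must be positive")
    if A.ndim == 2:
        if A.shape[0] != A.shape[1]:
            raise ValueError("square state matrix required")
        A_bar = expm(np.asarray(delta) * A)
    else:
        A_bar = np.exp(np.asarray(delta) * A)
    return A_bar, np.asarray(delta) * B


@njit(cache=True)
def _scan_fwd(u, delta, A, B, C, D):  # pragma: no cover - jitted
    L, E = u.shape
    N = A.shape[1]
    H = np.zeros((L, E, N))
    y = np.empty((L, E))
    h = np.zeros((E, N))
    for k in range(L):
        for c in range(E):
            acc = 0.0
            for n in range(N):
                h[c, n] = np.exp(delta[k, c] * A[c, n]) * h[c, n] \
                    + delta[k, c] * B[k, n] * u[k, c]
                H[k, c, n] = h[c, n]
                acc += C[k, n] * h[c, n]
            y[k, c] = acc + D[c] * u[k, c]
    return y, H


@njit(cache=True)
def _scan_bwd(u, delta, A, B, C, D, H, gy):  # pragma: no cover - jitted
    L, E = u.shape
    N = A.shape[1]
    gu = np.zeros((L, E))
    gdelta = np.zeros((L, E))
    gA = np.zeros((E, N))
    gB = np.zeros((L, N))
    gC = np.zeros((L, N))
    gD = np.zeros(E)
    gh = np.zeros((E, N))
    for k in range(L - 1, -1, -1):
        for c in range(E):
            gyk = gy[k, c]
            gD[c] += gyk * u[k, c]
            gu[k, c] += gyk * D[c]
            for n in range(N):
                gh[c, n] += gyk * C[k, n]
                gC[k, n] += gyk * H[k, c, n]
            for n in range(N):
                hprev = H[k - 1, c, n] if k > 0 else 0.0
                a_bar = np.exp(delta[k, c] * A[c, n])
                g = gh[c, n]
                gdelta[k, c] += g * (hprev * a_bar * A[c, n] + B[k, n] * u[k, c])
                gA[c, n] += g * hprev * a_bar * delta[k, c]
                gB[k, n] += g * delta[k, c] * u[k, c]
                gu[k, c] += g * delta[k, c] * B[k, n]
                gh[c, n] = g * a_bar
    return gu, gdelta, gA, gB, gC, gD


def selective_scan_reference(u, delta, A, B, C, D):
    """Naive loop-unrolled recurrence; the oracle for the jitted scan."""
    u = np.asarray(u, float)
    delta = np.asarray(delta, float)
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    C = np.asarray(C, float)
    D = np.asarray(D, float)
    L, E = u.shape
    N = A.shape[1]
    y = np.zeros((L, E))
    for c in range(E):
        h = np.zeros(N)
        for k in range(L):
            A_bar, B_bar = s6_discretize(A[c], B[k], float(delta[k, c]))
            h = A_bar * h + B_bar * u[k, c]
            y[k, c] = C[k] @ h + D[c] * u[k, c]
    return y


def selective_scan(u: Tensor, delta: Tensor, A: Tensor, B: Tensor,
                   C: Tensor, D: Tensor) -> Tensor:
    """Differentiable S6 scan over a token sequence.

    Shapes: u, delta (L, E); A (E, N) diagonal per channel; B, C (L, N);
    D (E,).  Returns y of shape (L, E).  h_0 = 0.
    """
    L = u.shape[0]
    if L == 0:
        return Tensor(np.zeros_like(u.data))
    y, H = _scan_fwd(u.data, delta.data, A.data, B.data, C.data, D.data)

    def backward(gy):
        gu, gdelta, gA, gB, gC, gD = _scan_bwd(
            u.data, delta.data, A.data, B.data, C.data, D.data, H, gy)
        u._accum(gu)
        delta._accum(gdelta)
        A._accum(gA)
        B._accum(gB)
        C._accum(gC)
        D._accum(gD)

    return _make(y, (u, delta, A, B, C, D), backward)
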