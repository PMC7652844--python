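"""Spherical-spline scalp interpolation (Perrin-style).

The spline kernel is

    g(x) = (1 / 4pi) * sum_{n=1}^{N} (2n + 1) / (n (n + 1))^m * P_n(x)

with stiffness order ``m`` and Legendre polynomials ``P_n`` evaluated at the
cosine of the angle between electrode positions. Interpolation solves the
regularized system

    [G + lam*I  1] [c]   [v]
    [1^T        0] [d] = [0]

and evaluates ``v* = G* c + d`` at the target positions. Constants are
reproduced exactly through the ``d`` term.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg

DEFAULT_STIFFNESS = 4
DEFAULT_N_TERMS = 50
DEFAULT_REGULARIZATION = 1e-5


def _g_kernel(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coefs = np.zeros(n_terms + 1)
    coefs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coefs) / (4.0 * np.pi)


def interpolation_matrix(
    source_pos: np.ndarray,
    target_pos: np.ndarray,
    m: int = DEFAULT_STIFFNESS,
    n_terms: int = DEFAULT_N_TERMS,
    reg: float = DEFAULT_REGULARIZATION,
) -> np.ndarray:
    """Linear operator mapping source-electrode values to target-electrode values.

    Parameters
    ----------
    source_pos : (n_src, 3) unit vectors of the electrodes carrying data.
    target_pos : (n_tgt, 3) unit vectors where the field is evaluated.

    Returns
    -------
    (n_tgt, n_src) matrix ``A`` such that ``A @ v`` interpolates values ``v``.
    """
    src = np.asarray(source_pos, float)
    tgt = np.asarray(target_pos, float)
    n_src = src.shape[0]
    if n_src < 4:
        raise ValueError("spherical spline needs at least 4 source electrodes")
    G = _g_kernel(src @ src.T, m, n_terms)
    Gt = _g_kernel(tgt @ src.T, m, n_terms)
    # bordered system with ridge on the kernel block
    A = np.zeros((n_src + 1, n_src + 1))
    A[:n_src, :n_src] = G + reg * np.eye(n_src)
    A[:n_src, n_src] = 1.0
    A[n_src, :n_src] = 1.0
    Ainv = np.linalg.solve(A, np.eye(n_src + 1))
    # rows of [Gt 1] @ Ainv[:, :n_src] give the value-space operator
    B = np.hstack([Gt, np.ones((tgt.shape[0], 1))])
    return B @ Ainv[:, :n_src]


_LOO_CACHE: dict[tuple, np.ndarray] = {}


def leave_one_out_operator(
    positions: np.ndarray,
    m: int = DEFAULT_STIFFNESS,
    n_terms: int = DEFAULT_N_TERMS,
    reg: float = DEFAULT_REGULARIZATION,
) -> np.ndarray:
    """Matrix ``R`` (zero diagonal) predicting each channel from all others.

    ``(R @ data)[i]`` is the spherical-spline estimate of channel ``i`` computed
    without channel ``i``. Used by correlation-based channel rejection.
    """
    pos = np.asarray(positions, float)
    key = (pos.tobytes(), m, n_terms, reg)
    cached = _LOO_CACHE.get(key)
    if cached is not None:
        return cached
    n = pos.shape[0]
    R = np.zeros((n, n))
    for i in range(n):
        others = [j for j in range(n) if j != i]
        row = interpolation_matrix(pos[others], pos[i : i + 1], m, n_terms, reg)
        R[i, others] = row[0]
    if len(_LOO_CACHE) > 64:
        _LOO_CACHE.clear()
    _LOO_CACHE[key] = R
    return R
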