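"""Spherical spline interpolation of scalp potentials (Perrin et al., 1989).

Reconstructs the potential at bad sensor positions from the remaining good
sensors, assuming the scalp field is a smooth function on the unit sphere.
The spline kernel is

    g(cos_angle) = 1/(4*pi) * sum_{n=1}^{N} (2n+1) / (n^m (n+1)^m) P_n(cos_angle)

with stiffness m = 4 and the series truncated at N terms; P_n are Legendre
polynomials.  The interpolation solves the standard constrained linear system
(spline coefficients sum to zero, plus a constant offset term) on the good
electrodes and evaluates the spline at the bad positions.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre as npleg


def _g_kernel(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coeffs = (2 * n + 1) / (n ** stiffness * (n + 1.0) ** stiffness)
    full = np.zeros(n_terms + 1)
    full[1:] = coeffs
    return npleg.legval(np.clip(cosang, -1.0, 1.0), full) / (4 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    stiffness: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> np.ndarray:
    """Matrix M with ``bad_values = M @ good_values``.

    Positions must be unit vectors.  ``reg`` is a small ridge on the kernel
    Gram matrix for numerical stability with near-coincident electrodes.
    """
    good_pos = np.asarray(good_pos, float)
    bad_pos = np.asarray(bad_pos, float)
    n_good = len(good_pos)
    if n_good < 4:
        raise ValueError("need at least 4 good channels for spherical spline")

    G = _g_kernel(good_pos @ good_pos.T, stiffness, n_terms)
    G = G + reg * np.eye(n_good)
    # Constrained system: [[G, 1], [1^T, 0]] [c; c0] = [z; 0]
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    A_inv = np.linalg.pinv(A)

    G_bad = _g_kernel(bad_pos @ good_pos.T, stiffness, n_terms)
    # value at bad position = c0 + G_bad @ c, where [c; c0] = A_inv @ [z; 0]
    ext = np.hstack([G_bad, np.ones((len(bad_pos), 1))])
    return ext @ A_inv[:, :n_good]


def interpolate(
    data: np.ndarray, layout: np.ndarray, bad_indices, **kw
) -> np.ndarray:
    """Replace rows ``bad_indices`` of channels x samples ``data`` in place-free copy."""
    bad = sorted(set(int(i) for i in bad_indices))
    if not bad:
        return data
    n_ch = data.shape[0]
    good = [i for i in range(n_ch) if i not in bad]
    if not good:
        raise ValueError("all channels bad: nothing to interpolate from")
    M = interpolation_matrix(layout[good], layout[bad], **kw)
    out = data.copy()
    out[bad] = M @ data[good]
    return out
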