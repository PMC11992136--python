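"""Spherical-spline surface Laplacian (current source density).

Scalp potentials are interpolated with spherical splines and the
surface Laplacian of the interpolant is evaluated at the electrodes,
yielding a reference-free, spatially sharpened signal.  The spline
kernels are Legendre series over the cosine of the inter-electrode
angle:

    g(x) = 1/(4 pi) * sum_{n=1}^{N} (2n+1) / (n(n+1))^m     * P_n(x)
    h(x) = 1/(4 pi) * sum_{n=1}^{N} (2n+1) / (n(n+1))^(m-1) * P_n(x)

with flexibility order m (default 4), truncation N (default 50) and a
small ridge lambda (default 1e-5) on the diagonal of the g-matrix.
The head is a unit sphere, so the absolute CSD scale is arbitrary but
consistent; every downstream statistic is scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .types import Montage, Epochs


@dataclass(frozen=True)
class CsdParams:
    m: int = 4
    lam: float = 1e-5
    n_terms: int = 50

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("spline order m must be >= 2")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_terms < 20:
            raise ValueError("need >= 20 Legendre terms")


def _legendre_series(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    coeffs = np.concatenate([[0.0], weights])  # P_0 term absent
    return legendre.legval(np.clip(x, -1.0, 1.0), coeffs)


def spline_g(x, m: int = 4, n_terms: int = 50):
    """Interpolation kernel g(cos theta)."""
    n = np.arange(1, n_terms + 1, dtype=float)
    w = (2 * n + 1) / (n * (n + 1)) ** m / (4 * np.pi)
    return _legendre_series(np.asarray(x, dtype=float), w)


def spline_h(x, m: int = 4, n_terms: int = 50):
    """Laplacian kernel h(cos theta)."""
    n = np.arange(1, n_terms + 1, dtype=float)
    w = (2 * n + 1) / (n * (n + 1)) ** (m - 1) / (4 * np.pi)
    return _legendre_series(np.asarray(x, dtype=float), w)


def csd_matrices(montage: Montage, params: CsdParams = CsdParams()):
    """Regularized (G, H) kernel matrices for a montage.

    G carries the ridge ``lambda`` on its diagonal; both matrices are
    symmetric.  Raises for coincident electrode positions.
    """
    if montage.n_channels < 16:
        raise ValueError("CSD needs >= 16 channels")
    pos = montage.positions
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    off = ~np.eye(len(cosang), dtype=bool)
    if np.any(cosang[off] > 1.0 - 1e-12):
        raise ValueError("coincident electrode positions in montage")
    G = spline_g(cosang, params.m, params.n_terms)
    H = spline_h(cosang, params.m, params.n_terms)
    G = G + params.lam * np.eye(len(G))
    return G, H


def _csd_operator(montage: Montage, params: CsdParams) -> np.ndarray:
    """Dense linear operator mapping potentials to CSD values.

    Solves the constrained spline system (coefficients sum to zero,
    free constant absorbed) and composes with the Laplacian kernel:
    for data v, d = G^-1 v, c = d - T (1' d)/(1' T) with T = G^-1 1,
    CSD = H c.  The constant-mode projection makes the operator exactly
    reference-invariant.
    """
    G, H = csd_matrices(montage, params)
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular regularized spline system; increase lambda"
        ) from e
    T = Ginv.sum(axis=1)
    sgi = T.sum()
    if abs(sgi) < 1e-300:
        raise np.linalg.LinAlgError(
            "degenerate spline system; increase lambda"
        )
    P = Ginv - np.outer(T, T) / sgi  # coefficient solve + zero-sum constraint
    return H @ P


def apply_csd(
    epochs: Epochs, montage: Montage | None = None, params: CsdParams = CsdParams()
) -> Epochs:
    """CSD-transform epoched data (units uV/m^2 up to the sphere radius).

    Linear in the input and invariant to adding any constant across
    channels (the recording reference).
    """
    montage = montage or epochs.montage
    if montage.n_channels != epochs.data.shape[1]:
        raise ValueError("montage does not match epoch channel count")
    L = _csd_operator(montage, params)
    out = epochs.copy_with()
    out.data = np.einsum("ij,ejs->eis", L, epochs.data)
    return out


def apply_csd_array(data: np.ndarray, montage: Montage, params: CsdParams = CsdParams()):
    """CSD transform of a channels x samples array (same operator)."""
    return _csd_operator(montage, params) @ data


def spline_interpolation_weights(
    good_pos: np.ndarray, bad_pos: np.ndarray, m: int = 4, n_terms: int = 50,
    lam: float = 1e-5,
) -> np.ndarray:
    """Spherical-spline weights reconstructing bad channels from good ones.

    Solves the interpolation system with a free constant term on the
    good sensors and evaluates the spline at the bad sensor positions;
    returns a (n_bad, n_good) matrix W with x_bad ~= W @ x_good.
    """
    good_pos = np.asarray(good_pos, float)
    bad_pos = np.asarray(bad_pos, float)
    ng = len(good_pos)
    Ggg = spline_g(good_pos @ good_pos.T, m, n_terms) + lam * np.eye(ng)
    Gbg = spline_g(bad_pos @ good_pos.T, m, n_terms)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = Ggg
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    B = np.concatenate([Gbg, np.ones((len(bad_pos), 1))], axis=1)
    return B @ np.linalg.solve(A, np.eye(ng + 1)[:, :ng])
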