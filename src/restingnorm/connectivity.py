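"""Weighted phase-lag-index (wPLI) functional connectivity.

For two analytic signals with cross-term X_t = a_i(t) * conj(a_j(t)),

    wPLI_ij = | mean_t Im(X_t) |  /  mean_t |Im(X_t)|

which measures the asymmetry of the phase-difference distribution and
is insensitive to zero-lag (volume-conducted) coupling.  The index is
computed per 2-s epoch within each frequency band, averaged over
epochs, and Fisher-transformed (arctanh) before statistics; the
per-subject summary is the mean transformed value over all channel
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BandScheme
from .types import Epochs

EDGE_FRACTION = 0.05  # analytic-signal samples excluded at each epoch edge


@dataclass
class ConnectivityTensor:
    band: str
    wpli: np.ndarray  # channels x channels, symmetric, in [0, 1], diag 0
    fisher_z: np.ndarray  # arctanh-transformed copy (clipped below 1)
    n_epochs_used: int


def band_analytic_signal(epochs: Epochs, band: tuple, order: int = 4) -> np.ndarray:
    """Band-passed analytic signal of the kept epochs.

    Zero-phase Butterworth band-pass per epoch followed by the Hilbert
    transform.  Returns a complex array (kept epochs x channels x
    samples); callers should drop ``EDGE_FRACTION`` of samples at each
    edge where the transform is unreliable.
    """
    lo, hi = band
    nyq = epochs.rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    df = 1.0 / epochs.epoch_length  # frequency resolution of one epoch
    if hi - lo < 2 * df:
        raise ValueError(
            f"band [{lo}, {hi}] narrower than twice the epoch resolution {df} Hz"
        )
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    kept = epochs.kept_data
    filtered = sps.sosfiltfilt(sos, kept, axis=2)
    return sps.hilbert(filtered, axis=2)


def _trim(analytic: np.ndarray) -> np.ndarray:
    n = analytic.shape[-1]
    edge = int(np.floor(EDGE_FRACTION * n))
    return analytic[..., edge : n - edge] if edge else analytic


def wpli_epoch(analytic_epoch: np.ndarray) -> np.ndarray:
    """wPLI matrix of one epoch (channels x samples complex input).

    Pairs whose imaginary cross-term is identically zero (identical or
    exactly zero-lag signals) get 0 by convention.
    """
    a = np.asarray(analytic_epoch)
    if a.shape[1] < 50:
        raise ValueError("need >= 50 valid time samples per epoch")
    # Im(a_i conj(a_j)) pooled over time, accumulated in chunks to keep
    # the (channels x channels x time) intermediate small
    n_ch, n_t = a.shape
    im_sum = np.zeros((n_ch, n_ch))
    abs_sum = np.zeros((n_ch, n_ch))
    for start in range(0, n_t, 256):
        chunk = a[:, start : start + 256]
        im = np.einsum("it,jt->ijt", chunk, chunk.conj()).imag
        im_sum += im.sum(axis=2)
        abs_sum += np.abs(im).sum(axis=2)
    num = np.abs(im_sum) / n_t
    den = abs_sum / n_t
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 1.0)


def wpli_subject(epochs: Epochs, band: tuple, band_name: str = "") -> ConnectivityTensor:
    """Epoch-averaged, Fisher-transformed wPLI for one band."""
    if epochs.n_kept < 4:
        raise ValueError("need >= 4 kept epochs")
    analytic = _trim(band_analytic_signal(epochs, band))
    mats = [wpli_epoch(a) for a in analytic]
    avg = np.mean(mats, axis=0)
    z = np.arctanh(np.minimum(avg, 1.0 - 1e-10))
    return ConnectivityTensor(
        band=band_name, wpli=avg, fisher_z=z, n_epochs_used=len(mats)
    )


def global_connectivity(tensor: ConnectivityTensor) -> float:
    """Mean Fisher-z wPLI over all unordered off-diagonal channel pairs."""
    n = tensor.fisher_z.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(tensor.fisher_z[iu].mean())


def subject_connectivity_features(
    epochs: Epochs, bands: BandScheme = BandScheme()
) -> dict:
    """Global wPLI per band: ``{"wpli_<band>": value}``."""
    return {
        f"wpli_{name}": global_connectivity(wpli_subject(epochs, edges, name))
        for name, edges in bands
    }
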