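"""Welch spectra and their aperiodic/periodic parameterization.

The power spectrum of resting EEG is modeled in log10 space as a
1/f-like aperiodic component plus Gaussian oscillatory peaks:

    log10 P(f) = b - chi * log10(f) + sum_k PW_k exp(-(f - CF_k)^2 / (2 s_k^2))

where b is the offset (log10 uV^2/Hz), chi the aperiodic exponent,
and each peak has center frequency CF (Hz), power above the aperiodic
fit PW (log10 units) and bandwidth BW = 2 s (Hz).

Fitting proceeds as in the standard spectral-parameterization scheme:
a robust initial aperiodic fit, iterative detection and subtraction of
candidate peaks from the flattened spectrum, a joint Gaussian refit, a
final aperiodic refit on the peak-removed spectrum, and goodness-of-fit
(R^2, MAE) of the full model.  Spectra with R^2 < 0.9 or MAE > 0.1 are
flagged invalid and excluded from channel averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .bands import BandScheme, FMIN, FMAX, PEAK_SEARCH_BANDS
from .types import Epochs

GRID_STEP = 0.5


@dataclass
class SpectrumSet:
    """Per-channel log10 power spectra on the analysis grid."""

    freqs: np.ndarray  # Hz, 2.5 .. 45 step 0.5
    log_power: np.ndarray  # channels x freqs, log10(uV^2/Hz)
    averaging: str = "median"

    def __post_init__(self):
        if not np.all(np.isfinite(self.log_power)):
            raise ValueError("non-finite values in spectrum")


@dataclass(frozen=True)
class SpecParamSettings:
    peak_width_limits: tuple = (1.0, 8.0)  # Hz, on BW = 2*sigma
    max_n_peaks: int = 6
    min_peak_height: float = 0.1  # log10 units above the aperiodic fit
    peak_threshold: float = 2.0  # in SDs of the flattened spectrum
    aperiodic_mode: str = "fixed"


@dataclass
class AperiodicFit:
    offset: float  # b, log10 power units
    exponent: float  # chi, dimensionless
    r_squared: float = np.nan
    mae: float = np.nan

    @property
    def valid(self) -> bool:
        return bool(self.r_squared >= 0.9 and self.mae <= 0.1)


@dataclass
class SpectralPeak:
    cf: float  # center frequency, Hz
    pw: float  # power above aperiodic, log10 units
    bw: float  # bandwidth, Hz (2 * Gaussian SD)


@dataclass
class SpecParamFit:
    """Full parameterization of one channel spectrum."""

    aperiodic: AperiodicFit
    peaks: list = field(default_factory=list)
    model: np.ndarray = None  # modeled log-spectrum on the grid
    flattened: np.ndarray = None  # input minus final aperiodic (periodic power)


# ---------------------------------------------------------------------------
# Welch estimation


def welch_psd(epochs: Epochs, fmin: float = FMIN, fmax: float = FMAX) -> SpectrumSet:
    """Median-averaged Welch log-spectra of the kept epochs.

    2-s Hamming-tapered segments sliding with 50% overlap across the
    concatenated kept epochs, median-averaged per channel (with the
    standard median bias correction), log10-transformed, on the 0.5 Hz
    grid from 2.5 to 45 Hz.
    """
    if epochs.n_kept < 4:
        raise ValueError("need >= 4 kept epochs for a stable spectrum")
    if abs(epochs.epoch_length - 2.0) > 1e-9:
        raise ValueError("Welch window equals the epoch length; epochs must be 2 s")
    rate = epochs.rate
    nper = int(round(2.0 * rate))
    kept = epochs.kept_data
    x = kept.transpose(1, 0, 2).reshape(kept.shape[1], -1)
    freqs, psd = sps.welch(
        x,
        fs=rate,
        window="hamming",
        nperseg=nper,
        noverlap=nper // 2,
        average="median",
        detrend="constant",
        axis=1,
    )
    sel = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    grid = freqs[sel]
    expected = np.arange(fmin, fmax + GRID_STEP / 2, GRID_STEP)
    if len(grid) != len(expected) or not np.allclose(grid, expected):
        raise ValueError("sampling rate incompatible with the 0.5 Hz analysis grid")
    power = np.maximum(psd[:, sel], 1e-30)
    return SpectrumSet(freqs=grid, log_power=np.log10(power))


# ---------------------------------------------------------------------------
# Spectral parameterization


def _aperiodic(logf: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    return offset - exponent * logf


def _fit_line(logf, y, mask=None):
    if mask is not None:
        logf, y = logf[mask], y[mask]
    slope, intercept = np.polyfit(logf, y, 1)
    return float(intercept), float(-slope)  # (offset, exponent)


def _robust_aperiodic(logf, y, keep_quantile=60.0, n_iter=2):
    """Line fit down-weighting peak regions.

    After an initial full fit, refit on the points whose residual lies
    below the ``keep_quantile`` percentile; oscillatory peaks produce
    large positive residuals and drop out.
    """
    b, chi = _fit_line(logf, y)
    for _ in range(n_iter):
        resid = y - _aperiodic(logf, b, chi)
        thresh = np.percentile(resid, keep_quantile)
        mask = resid <= thresh
        if mask.sum() < 3:
            break
        b, chi = _fit_line(logf, y, mask)
    return b, chi


def _gaussians(freqs: np.ndarray, *params) -> np.ndarray:
    out = np.zeros_like(freqs, dtype=float)
    for k in range(0, len(params), 3):
        cf, pw, sd = params[k : k + 3]
        out += pw * np.exp(-((freqs - cf) ** 2) / (2 * sd**2))
    return out


def _guess_sigma(freqs, flat, idx, limits):
    """Half-prominence width around a detected maximum -> Gaussian SD guess."""
    half = flat[idx] / 2.0
    lo = idx
    while lo > 0 and flat[lo] > half:
        lo -= 1
    hi = idx
    while hi < len(flat) - 1 and flat[hi] > half:
        hi += 1
    fwhm = max(freqs[hi] - freqs[lo], GRID_STEP)
    sd = fwhm / 2.355
    return float(np.clip(sd, limits[0] / 2.0, limits[1] / 2.0))


def fit_specparam(
    freqs: np.ndarray,
    log_power: np.ndarray,
    settings: SpecParamSettings = SpecParamSettings(),
) -> SpecParamFit:
    """Parameterize one channel's log10 spectrum.

    Returns the aperiodic fit (offset, exponent, R^2, MAE), the fitted
    Gaussian peaks (CF/PW/BW), the modeled spectrum and the flattened
    (periodic-only) spectrum.  Peaks that fail their joint refit or end
    below the minimum height are dropped.
    """
    if settings.aperiodic_mode != "fixed":
        raise ValueError("only the fixed (no-knee) aperiodic mode is supported")
    freqs = np.asarray(freqs, float)
    y = np.asarray(log_power, float)
    logf = np.log10(freqs)
    wlo, whi = settings.peak_width_limits

    b0, chi0 = _robust_aperiodic(logf, y)
    flat = y - _aperiodic(logf, b0, chi0)

    guesses = []
    work = flat.copy()
    for _ in range(settings.max_n_peaks):
        idx = int(np.argmax(work))
        height = work[idx]
        if height < max(settings.min_peak_height,
                        settings.peak_threshold * np.std(work)):
            break
        sd = _guess_sigma(freqs, work, idx, (wlo, whi))
        guesses.append((float(freqs[idx]), float(height), sd))
        work = work - _gaussians(freqs, freqs[idx], height, sd)

    peaks: list = []
    if guesses:
        p0, lo, hi = [], [], []
        for cf, pw, sd in guesses:
            p0 += [cf, pw, sd]
            lo += [max(freqs[0], cf - 2 * sd * 2), 0.0, wlo / 2.0]
            hi += [min(freqs[-1], cf + 2 * sd * 2), np.inf, whi / 2.0]
        try:
            popt, _ = curve_fit(
                _gaussians, freqs, flat, p0=p0, bounds=(lo, hi), maxfev=5000
            )
            for k in range(0, len(popt), 3):
                cf, pw, sd = popt[k : k + 3]
                if pw >= settings.min_peak_height:
                    peaks.append(SpectralPeak(cf=float(cf), pw=float(pw),
                                              bw=float(2 * sd)))
        except RuntimeError:
            # joint refit failed to converge; fall back to the guesses
            for cf, pw, sd in guesses:
                if pw >= settings.min_peak_height:
                    peaks.append(SpectralPeak(cf=cf, pw=pw, bw=2 * sd))
    peaks.sort(key=lambda p: p.cf)

    peak_model = _gaussians(freqs, *(v for p in peaks for v in (p.cf, p.pw, p.bw / 2)))
    b, chi = _fit_line(logf, y - peak_model)
    model = _aperiodic(logf, b, chi) + peak_model
    resid = y - model
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    ap = AperiodicFit(
        offset=b, exponent=chi, r_squared=r2, mae=float(np.mean(np.abs(resid)))
    )
    return SpecParamFit(
        aperiodic=ap, peaks=peaks, model=model,
        flattened=y - _aperiodic(logf, b, chi),
    )


def parameterize_spectra(
    spectra: SpectrumSet, settings: SpecParamSettings = SpecParamSettings()
) -> list:
    return [fit_specparam(spectra.freqs, ch, settings) for ch in spectra.log_power]


def exclude_poor_fits(fits) -> np.ndarray:
    """Validity mask: R^2 >= 0.9 and MAE <= 0.1 (boundaries retained)."""
    return np.array([f.aperiodic.valid for f in fits], dtype=bool)


# ---------------------------------------------------------------------------
# Feature aggregation


def band_aggregate(
    values: np.ndarray, band_mask: np.ndarray, valid_channels: np.ndarray
) -> float:
    """Mean over band bins, then mean over valid channels.

    ``values`` is channels x freqs (log power, total or periodic-only);
    returns NaN when no channel is valid (missing, never zero).
    """
    valid_channels = np.asarray(valid_channels, dtype=bool)
    if not valid_channels.any() or not np.asarray(band_mask).any():
        return float("nan")
    per_channel = values[valid_channels][:, band_mask].mean(axis=1)
    return float(per_channel.mean())


def find_peak_frequency(
    freqs: np.ndarray, periodic: np.ndarray, band: tuple
) -> float:
    """Grid frequency of maximal periodic power within a search window.

    Ties break toward the lower frequency; a window with no positive
    periodic power yields NaN (missing).
    """
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        return float("nan")
    vals = np.asarray(periodic)[mask]
    if np.max(vals) <= 0:
        return float("nan")
    return float(freqs[mask][int(np.argmax(vals))])


def subject_spectral_features(
    spectra: SpectrumSet,
    settings: SpecParamSettings = SpecParamSettings(),
    bands: BandScheme = BandScheme(),
    peak_bands: dict = PEAK_SEARCH_BANDS,
) -> dict:
    """All spectral features for one subject.

    Returns ``{feature_name: value}`` with features ``psd_<band>``,
    ``periodic_<band>``, ``exponent``, ``offset``, ``alpha_peak``,
    ``beta_peak``.  Channel averaging uses only channels whose
    parameterization passed the fit-quality rule.
    """
    fits = parameterize_spectra(spectra, settings)
    valid = exclude_poor_fits(fits)
    out = {}
    for name, _ in bands:
        mask = bands.bin_mask(spectra.freqs, name)
        out[f"psd_{name}"] = band_aggregate(spectra.log_power, mask, valid)
    periodic = np.array([f.flattened for f in fits])
    for name, _ in bands:
        mask = bands.bin_mask(spectra.freqs, name)
        out[f"periodic_{name}"] = band_aggregate(periodic, mask, valid)
    if valid.any():
        out["exponent"] = float(np.mean([f.aperiodic.exponent
                                         for f, v in zip(fits, valid) if v]))
        out["offset"] = float(np.mean([f.aperiodic.offset
                                       for f, v in zip(fits, valid) if v]))
        mean_periodic = periodic[valid].mean(axis=0)
        for pname, window in peak_bands.items():
            out[f"{pname}_peak"] = find_peak_frequency(
                spectra.freqs, mean_periodic, window
            )
    else:
        out["exponent"] = out["offset"] = float("nan")
        for pname in peak_bands:
            out[f"{pname}_peak"] = float("nan")
    return out
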