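"""Automatic preprocessing of raw resting-state EEG.

Eight-step chain from a continuous recording to artifact-reduced 2-s
epochs:

1. remove flat channels (log-SD more than 3 SD below the channel mean),
2. zero-phase 0.1 Hz high-pass + 60 Hz comb notch (in-band harmonics),
3. bipolar EOG derivation (E8 - E9) for eye-artifact tracking,
4. segmentation into 2-s non-overlapping epochs,
5. adaptive epoch rejection (per-epoch max peak-to-peak > median + 5 MAD),
6. average re-referencing,
7. removal of ICA components correlated with the bipolar EOG,
8. per-epoch rejection + spherical-spline interpolation of residual
   bad channels.

The fraction of epochs rejected at step 5 becomes the data-quality
covariate of the normative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .types import Montage, Recording, Epochs, EOG_PAIR
from .csd import spline_interpolation_weights


@dataclass
class PreprocReport:
    subject_id: str = ""
    flat_channels: list = field(default_factory=list)
    filter_settings: dict = field(default_factory=dict)
    n_epochs_total: int = 0
    n_epochs_kept: int = 0
    ica_components_removed: int = 0
    interpolated_per_epoch: list = field(default_factory=list)
    dropped_epochs_step8: int = 0
    warnings: list = field(default_factory=list)

    @property
    def quality_ratio(self) -> float:
        if self.n_epochs_total == 0:
            return 0.0
        return 1.0 - self.n_epochs_kept / self.n_epochs_total

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "flat_channels": list(self.flat_channels),
            "filter_settings": self.filter_settings,
            "n_epochs_total": self.n_epochs_total,
            "n_epochs_kept": self.n_epochs_kept,
            "quality_ratio": self.quality_ratio,
            "ica_components_removed": self.ica_components_removed,
            "interpolated_per_epoch": list(map(int, self.interpolated_per_epoch)),
            "dropped_epochs_step8": self.dropped_epochs_step8,
            "warnings": list(self.warnings),
        }


# -- step 1 ------------------------------------------------------------------


def detect_flat_channels(recording: Recording, z_threshold: float = 3.0) -> list:
    """Channels whose log standard deviation is an extreme low outlier.

    A channel is flat when log10(SD) falls more than ``z_threshold``
    robust-SDs below the across-channel mean of log-SDs; zero-variance
    channels are always flagged.  (A threshold on raw SD would be
    ill-posed: SDs are strictly positive and right-skewed.)
    """
    if recording.n_channels < 8:
        raise ValueError("flat-channel detection needs >= 8 channels")
    sds = recording.data.std(axis=1)
    zero = sds <= 0
    with np.errstate(divide="ignore"):
        log_sd = np.log10(np.where(zero, np.nan, sds))
    ok = np.isfinite(log_sd)
    mu, sd = np.nanmean(log_sd[ok]), np.nanstd(log_sd[ok])
    flagged = zero.copy()
    if sd > 0:
        flagged |= np.where(ok, log_sd < mu - z_threshold * sd, True)
    if flagged.all():
        raise ValueError("all channels flagged flat; recording unusable")
    return [recording.montage.labels[i] for i in np.flatnonzero(flagged)]


def drop_channels(recording: Recording, labels) -> Recording:
    keep = [l for l in recording.montage.labels if l not in set(labels)]
    idx = [recording.montage.index_of(l) for l in keep]
    return Recording(
        data=recording.data[idx],
        rate=recording.rate,
        montage=recording.montage.subset(keep),
        subject_id=recording.subject_id,
    )


# -- step 2 ------------------------------------------------------------------


def apply_filters(
    recording: Recording,
    highpass_hz: float = 0.1,
    line_hz: float = 60.0,
    n_harmonics: int = 4,
    notch_q: float = 30.0,
    report: PreprocReport | None = None,
) -> Recording:
    """Zero-phase 0.1 Hz high-pass and comb notch at 60 Hz + harmonics.

    Harmonics at or above Nyquist are silently skipped.  Filtering is
    applied with ``filtfilt`` so the passband (2.5-45 Hz) is phase- and
    gain-neutral.
    """
    nyq = recording.rate / 2.0
    data = recording.data
    settings = {"highpass_hz": highpass_hz, "notch_hz": [], "notch_q": notch_q}
    if recording.duration < 10.0 / highpass_hz and report is not None:
        report.warnings.append(
            f"duration {recording.duration:.0f}s < 10 time-constants of the "
            f"{highpass_hz} Hz high-pass"
        )
    sos = sps.butter(2, highpass_hz / nyq, btype="highpass", output="sos")
    data = sps.sosfiltfilt(sos, data, axis=1)
    for k in range(1, n_harmonics + 1):
        f0 = line_hz * k
        if f0 >= nyq:
            break
        b, a = sps.iirnotch(f0 / nyq, notch_q)
        data = sps.filtfilt(b, a, data, axis=1)
        settings["notch_hz"].append(f0)
    if report is not None:
        report.filter_settings = settings
    return recording.copy_with(data=data)


# -- step 3 ------------------------------------------------------------------


def make_bipolar_eog(
    recording: Recording, anode_label: str = EOG_PAIR[0], cathode_label: str = EOG_PAIR[1]
) -> np.ndarray:
    """Bipolar eye-artifact reference: anode minus cathode series."""
    ia = recording.montage.index_of(anode_label)
    ic = recording.montage.index_of(cathode_label)
    return recording.data[ia] - recording.data[ic]


# -- step 4 ------------------------------------------------------------------


def epoch_signal(recording: Recording, length_s: float = 2.0) -> Epochs:
    """Cut into non-overlapping fixed-length epochs; trailing remainder dropped."""
    n_per = int(round(length_s * recording.rate))
    n_epochs = recording.data.shape[1] // n_per
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    data = recording.data[:, : n_epochs * n_per]
    data = data.reshape(recording.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return Epochs(
        data=data.copy(),
        rate=recording.rate,
        epoch_length=length_s,
        montage=recording.montage,
        subject_id=recording.subject_id,
    )


def epoch_series(series: np.ndarray, rate: float, length_s: float = 2.0) -> np.ndarray:
    """Segment a single-channel series the same way as epoch_signal."""
    n_per = int(round(length_s * rate))
    n_epochs = len(series) // n_per
    return series[: n_epochs * n_per].reshape(n_epochs, n_per)


# -- step 5 ------------------------------------------------------------------


def reject_epochs_adaptive(epochs: Epochs, k: float = 5.0) -> Epochs:
    """Reject epochs whose worst-channel peak-to-peak is a robust outlier.

    Score per epoch = max over channels of peak-to-peak amplitude;
    epochs scoring above median + k*MAD are rejected.  With MAD = 0
    (identical epochs) nothing is rejected.
    """
    if epochs.n_epochs < 10:
        raise ValueError("adaptive rejection needs >= 10 epochs")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # epochs x channels
    score = ptp.max(axis=1)
    med = np.median(score)
    mad = np.median(np.abs(score - med))
    if mad > 0:
        keep = score <= med + k * mad
    else:
        keep = np.ones_like(score, dtype=bool)
    if not keep.any():
        raise ValueError("all epochs rejected")
    out = epochs.copy_with()
    out.kept_mask = epochs.kept_mask & keep
    return out


# -- step 6 ------------------------------------------------------------------


def rereference_average(epochs: Epochs) -> Epochs:
    """Subtract the across-channel mean at every sample (average reference)."""
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference needs >= 2 channels")
    out = epochs.copy_with()
    out.data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return out


# -- step 7 ------------------------------------------------------------------


def remove_eog_ica(
    epochs: Epochs,
    eog_series: np.ndarray,
    corr_threshold: float = 0.7,
    max_remove: int = 2,
    seed: int = 0,
    report: PreprocReport | None = None,
):
    """Zero ICA components tracking the bipolar EOG, then reconstruct.

    The decomposition runs on kept epochs concatenated in time;
    ``eog_series`` must be epoched/masked identically (one value per
    concatenated sample).  Components whose time course correlates with
    the EOG above ``corr_threshold`` in absolute value are removed, at
    most ``max_remove`` of them.  Returns ``(epochs, n_removed)``.
    """
    kept = epochs.kept_data
    n_ep, n_ch, n_samp = kept.shape
    x = kept.transpose(1, 0, 2).reshape(n_ch, n_ep * n_samp)
    if x.shape[1] <= n_ch:
        raise ValueError("need more samples than channels for ICA")
    if len(eog_series) != x.shape[1]:
        raise ValueError("eog_series length must match concatenated kept epochs")
    # average-referenced data has rank n_ch - 1; keep ICA well-posed
    n_comp = min(n_ch - 1, n_ch)
    ica = FastICA(n_components=n_comp, random_state=seed, max_iter=1000, tol=1e-4)
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            sources = ica.fit_transform(x.T).T  # components x samples
    except Exception as e:  # non-convergence: pass through unchanged
        if report is not None:
            report.warnings.append(f"ICA failed ({e}); step skipped")
        return epochs.copy_with(), 0
    eog = eog_series - eog_series.mean()
    denom = np.std(eog)
    if denom == 0:
        return epochs.copy_with(), 0
    corrs = np.array(
        [
            abs(np.corrcoef(s, eog)[0, 1]) if np.std(s) > 0 else 0.0
            for s in sources
        ]
    )
    order = np.argsort(-corrs)
    remove = [i for i in order[:max_remove] if corrs[i] > corr_threshold]
    if remove:
        sources[remove] = 0.0
        clean = (ica.mixing_ @ sources) + ica.mean_[:, None]
        out = epochs.copy_with()
        out.data[epochs.kept_mask] = clean.reshape(n_ch, n_ep, n_samp).transpose(
            1, 0, 2
        )
    else:
        out = epochs.copy_with()
    if report is not None:
        report.ica_components_removed = len(remove)
    return out, len(remove)


# -- step 8 ------------------------------------------------------------------


def interpolate_bad_channels_per_epoch(
    epochs: Epochs,
    montage: Montage | None = None,
    k: float = 8.0,
    max_bad_fraction: float = 0.3,
    report: PreprocReport | None = None,
) -> Epochs:
    """Per epoch, spherical-spline-interpolate channels with residual artifacts.

    Channels whose within-epoch peak-to-peak exceeds median + k*MAD
    (across channels of that epoch) are replaced by a spherical-spline
    estimate from the remaining channels.  If more than
    ``max_bad_fraction`` of channels are bad the epoch is dropped instead.
    """
    montage = montage or epochs.montage
    out = epochs.copy_with()
    counts = []
    dropped = 0
    for e in np.flatnonzero(epochs.kept_mask):
        ep = out.data[e]
        ptp = ep.max(axis=1) - ep.min(axis=1)
        med = np.median(ptp)
        mad = np.median(np.abs(ptp - med))
        if mad <= 0:
            counts.append(0)
            continue
        bad = np.flatnonzero(ptp > med + k * mad)
        if len(bad) == 0:
            counts.append(0)
            continue
        if len(bad) > max_bad_fraction * len(ptp):
            out.kept_mask[e] = False
            dropped += 1
            continue
        good = np.setdiff1d(np.arange(len(ptp)), bad)
        w = spline_interpolation_weights(
            montage.positions[good], montage.positions[bad]
        )
        ep[bad] = w @ ep[good]
        counts.append(len(bad))
    if report is not None:
        report.interpolated_per_epoch = counts
        report.dropped_epochs_step8 = dropped
    return out


# -- full chain --------------------------------------------------------------


def preprocess(
    recording: Recording,
    epoch_length_s: float = 2.0,
    reject_k: float = 5.0,
    interp_k: float = 8.0,
    ica_corr_threshold: float = 0.7,
    ica_max_remove: int = 2,
    seed: int = 0,
    eog_pair=EOG_PAIR,
):
    """Run steps (1)-(8) in order; returns ``(Epochs, PreprocReport)``.

    The quality ratio in the report counts all epochs rejected by
    steps 5 and 8 against the total number of epochs cut at step 4.
    """
    report = PreprocReport(subject_id=recording.subject_id)
    flat = detect_flat_channels(recording)
    report.flat_channels = flat
    rec = drop_channels(recording, flat) if flat else recording
    rec = apply_filters(rec, report=report)
    have_eog = all(l in rec.montage.labels for l in eog_pair)
    eog = make_bipolar_eog(rec, *eog_pair) if have_eog else None
    epochs = epoch_signal(rec, epoch_length_s)
    report.n_epochs_total = epochs.n_epochs
    epochs = reject_epochs_adaptive(epochs, k=reject_k)
    epochs = rereference_average(epochs)
    if eog is not None:
        eog_ep = epoch_series(eog, rec.rate, epoch_length_s)
        eog_concat = eog_ep[epochs.kept_mask].reshape(-1)
        epochs, _ = remove_eog_ica(
            epochs,
            eog_concat,
            corr_threshold=ica_corr_threshold,
            max_remove=ica_max_remove,
            seed=seed,
            report=report,
        )
    else:
        report.warnings.append("EOG pair absent; ICA step skipped")
    epochs = interpolate_bad_channels_per_epoch(epochs, k=interp_k, report=report)
    report.n_epochs_kept = epochs.n_kept
    return epochs, report
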