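"""Synthetic resting-state EEG cohorts with known ground truth.

Emulates the study conditions the pipeline is built for: children aged
3-17 in three groups (CTRL, DEL, DUP), ~100-channel recordings of a few
minutes at 500-1000 Hz, a 1/f^chi aperiodic background with Gaussian
(in log-power) oscillatory peaks, band-limited inter-channel phase
coupling, and stereotyped artifacts (eye blinks, flat channels,
high-amplitude epochs).  Group effects are injected as additive shifts
on the generative parameters, expressed in pooled-SD units so the
injected standardized effect size is known exactly.

Spectral shaping is done in the frequency domain: each channel is white
noise whose rFFT amplitudes are scaled to the target one-sided PSD

    log10 S(f) = b - chi * log10(f) + sum_k PW_k * exp(-(f-CF_k)^2 / (2 sigma_k^2))

with sigma_k = BW_k / 2, so the spectrum the estimator assumes is the
spectrum the data actually has (in expectation).  Parameter recovery
then tests the estimator, not model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Montage, Recording, EOG_PAIR

AGE_RANGE = (3.0, 17.0)

# Baseline generative distributions (value at age 10, change per year, SD).
# Exponent and offset decline slowly through childhood; the alpha rhythm
# accelerates with age.
PARAM_BASE = {
    "exponent": (1.80, -0.030, 0.25),
    "offset": (0.80, -0.020, 0.25),
    "alpha_cf": (9.00, 0.200, 0.80),
    "alpha_pw": (0.50, 0.000, 0.12),
    "alpha_bw": (2.20, 0.000, 0.40),
    "beta_cf": (20.0, 0.000, 1.50),
    "beta_pw": (0.25, 0.000, 0.05),
    "beta_bw": (3.00, 0.000, 0.50),
    "coupling": (0.45, 0.000, 0.10),
}

_CLIPS = {
    "exponent": (0.2, 3.5),
    "alpha_cf": (4.0, 14.0),
    "alpha_pw": (0.15, 1.5),
    "alpha_bw": (1.2, 6.0),
    "beta_cf": (16.0, 28.0),
    "beta_pw": (0.12, 0.8),
    "beta_bw": (1.2, 6.0),
    "coupling": (0.0, 0.95),
}


@dataclass(frozen=True)
class ArtifactSpec:
    n_flat_channels: int = 1
    blink_rate: float = 10.0  # per minute
    bad_epoch_fraction: float = 0.30

    def clean(self) -> "ArtifactSpec":
        return ArtifactSpec(0, 0.0, 0.0)


CLEAN_ARTIFACTS = ArtifactSpec(0, 0.0, 0.0)


@dataclass(frozen=True)
class EffectConfig:
    """Per-group parameter shifts in pooled-SD units (optionally x age).

    ``shifts[param][group] = (a, b)`` applies ``(a + b*age) * SD_param``
    additively to that group's draws.  The defaults mirror the
    carrier-like deviations the pipeline should detect: a ~0.5-SD
    exponent reduction in both carrier groups, a slowed alpha peak, and
    group-dependent alpha coupling changes.
    """

    shifts: dict = field(
        default_factory=lambda: {
            "exponent": {"DEL": (-0.53, 0.0), "DUP": (-0.43, 0.0)},
            "alpha_cf": {"DEL": (-0.88, 0.0), "DUP": (-0.49, 0.0)},
            "alpha_pw": {"DEL": (-0.54, 0.0), "DUP": (-0.21, 0.0)},
            "coupling": {"DEL": (0.02, 0.0), "DUP": (-0.50, 0.0)},
        }
    )
    p_male: float = 0.56
    p_site1_ctrl: float = 0.875  # fraction of controls recorded at site 1
    artifacts: ArtifactSpec = CLEAN_ARTIFACTS
    n_coupled_pairs: int = 6
    coupling_band: tuple = (8.0, 12.0)
    seed: int = 0

    @classmethod
    def null(cls, **kw) -> "EffectConfig":
        """Zero-effect configuration (all groups identical in law)."""
        return cls(shifts={}, **kw)

    def shift_for(self, param: str, group: str, age: float) -> float:
        a, b = self.shifts.get(param, {}).get(group, (0.0, 0.0))
        return (a + b * age) * PARAM_BASE[param][2]


@dataclass
class SyntheticTruth:
    """Per-subject generative parameters (the recovery-test ground truth)."""

    subject_id: str
    group: str
    age: float
    sex: str
    site: int
    exponent: float
    offset: float
    peaks: list  # [(CF Hz, PW log10 units, BW Hz), ...]
    coupling: list  # [((label_i, label_j), lag radians, coefficient), ...]
    artifact_spec: ArtifactSpec
    seed: int

    def as_row(self) -> dict:
        alpha = self.peaks[0] if self.peaks else (np.nan,) * 3
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "site": self.site,
            "exponent": self.exponent,
            "offset": self.offset,
            "alpha_cf": alpha[0],
            "alpha_pw": alpha[1],
            "alpha_bw": alpha[2],
            "mean_coupling": float(np.mean([c for _, _, c in self.coupling]))
            if self.coupling
            else 0.0,
        }


def _draw(rng, param, age, group, cfg):
    base, slope, sd = PARAM_BASE[param]
    v = base + slope * (age - 10.0) + sd * rng.standard_normal()
    v += cfg.shift_for(param, group, age)
    lo, hi = _CLIPS.get(param, (-np.inf, np.inf))
    return float(np.clip(v, lo, hi))


def sample_cohort(
    n_ctrl: int,
    n_del: int,
    n_dup: int,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    coupled_pairs: list | None = None,
):
    """Draw a cohort table and per-subject ground-truth parameters.

    Ages are uniform on [3, 17]; carriers are recorded at site 0 and
    controls mostly at site 1, matching the study's site structure.
    Fully reproducible from ``seed``.

    Returns
    -------
    (cohort, truths) : (pandas.DataFrame, list of SyntheticTruth)
    """
    if min(n_ctrl, n_del, n_dup) < 0:
        raise ValueError("group counts must be non-negative")
    cfg = effect_config if effect_config is not None else EffectConfig()
    rng = np.random.default_rng(seed)
    rows, truths = [], []
    sid = 0
    for group, n in (("CTRL", n_ctrl), ("DEL", n_del), ("DUP", n_dup)):
        for _ in range(n):
            sid += 1
            subject_id = f"S{sid:04d}"
            age = float(rng.uniform(*AGE_RANGE))
            sex = "M" if rng.random() < cfg.p_male else "F"
            site = int(rng.random() < cfg.p_site1_ctrl) if group == "CTRL" else 0
            peaks = [
                (
                    _draw(rng, "alpha_cf", age, group, cfg),
                    _draw(rng, "alpha_pw", age, group, cfg),
                    _draw(rng, "alpha_bw", age, group, cfg),
                ),
                (
                    _draw(rng, "beta_cf", age, group, cfg),
                    _draw(rng, "beta_pw", age, group, cfg),
                    _draw(rng, "beta_bw", age, group, cfg),
                ),
            ]
            coupling = []
            if coupled_pairs:
                for pair in coupled_pairs[: cfg.n_coupled_pairs]:
                    coupling.append(
                        (
                            tuple(pair),
                            float(rng.uniform(np.pi / 8, 3 * np.pi / 8)),
                            _draw(rng, "coupling", age, group, cfg),
                        )
                    )
            truth = SyntheticTruth(
                subject_id=subject_id,
                group=group,
                age=age,
                sex=sex,
                site=site,
                exponent=_draw(rng, "exponent", age, group, cfg),
                offset=_draw(rng, "offset", age, group, cfg),
                peaks=peaks,
                coupling=coupling,
                artifact_spec=cfg.artifacts,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            truths.append(truth)
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "site": site,
                    "quality_ratio": cfg.artifacts.bad_epoch_fraction,
                }
            )
    return pd.DataFrame(rows), truths


# ---------------------------------------------------------------------------
# Signal synthesis


def _target_log_psd(freqs: np.ndarray, offset, exponent, peaks) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logf = np.log10(np.where(freqs > 0, freqs, np.nan))
    lp = offset - exponent * logf
    for cf, pw, bw in peaks:
        lp = lp + pw * np.exp(-((freqs - cf) ** 2) / (2 * (bw / 2.0) ** 2))
    lp[~np.isfinite(lp)] = -np.inf
    return lp


def _shaped_noise(rng, n, rate, log_psd_fn) -> np.ndarray:
    """White noise amplitude-shaped to a target one-sided PSD (uV^2/Hz)."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    lp = log_psd_fn(freqs)
    s = np.where(np.isfinite(lp), 10.0**lp, 0.0)
    # E[one-sided periodogram] = S  <=>  E|X_k|^2 = S * rate * n / 2
    amp = np.sqrt(s * rate * n / 2.0)
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(amp * z / np.sqrt(2.0), n)
    return x


def _blink_template(rate: float, duration_s: float = 0.4, amp_uv: float = 150.0):
    n = int(round(duration_s * rate))
    t = np.arange(n) / n
    return amp_uv * 0.5 * (1 - np.cos(2 * np.pi * t))


def frontal_channels(montage: Montage, threshold: float = 0.55) -> list:
    """Labels of face-ward sensors (+x hemisphere front) that catch blinks."""
    out = [
        l
        for l, p in zip(montage.labels, montage.positions)
        if p[0] > threshold and l not in EOG_PAIR
    ]
    return out


def synthesize_recording(
    truth: SyntheticTruth,
    montage: Montage,
    duration_s: float = 240.0,
    rate: float = 500.0,
) -> Recording:
    """Render one subject's multichannel recording from its ground truth.

    Every channel is an independent shaped-noise realization of the
    subject's target spectrum; coupled pairs additionally share a
    band-limited source injected with the specified phase lag and
    coupling coefficient; artifacts are added per ``truth.artifact_spec``.
    Deterministic given ``truth.seed``.
    """
    if rate < 2 * 45.0:
        raise ValueError("sampling rate below Nyquist for the 45 Hz analysis band")
    if duration_s < 30.0:
        raise ValueError("duration under 30 s gives unstable spectra")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration_s * rate))
    n_ch = montage.n_channels
    data = np.empty((n_ch, n))
    for c in range(n_ch):
        data[c] = _shaped_noise(
            rng, n, rate,
            lambda f: _target_log_psd(f, truth.offset, truth.exponent, truth.peaks),
        )

    # in-band RMS of the base signal, for scaling the coupled source
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    for (li, lj), lag, coeff in truth.coupling:
        i, j = montage.index_of(li), montage.index_of(lj)
        lo, hi = 8.0, 12.0
        band_mask = (freqs >= lo) & (freqs <= hi)
        lp = _target_log_psd(freqs, truth.offset, truth.exponent, truth.peaks)
        band_power = np.trapezoid(
            np.where(band_mask & np.isfinite(lp), 10.0**lp, 0.0), freqs
        )
        sigma_b = np.sqrt(max(band_power, 1e-12))
        src_spec = np.zeros(len(freqs), complex)
        z = rng.standard_normal(band_mask.sum()) + 1j * rng.standard_normal(
            band_mask.sum()
        )
        src_spec[band_mask] = z
        src = np.fft.irfft(src_spec, n)
        src *= 1.0 / max(np.std(src), 1e-12)
        lagged = np.fft.irfft(src_spec * np.exp(-1j * lag), n)
        lagged *= 1.0 / max(np.std(lagged), 1e-12)
        c = min(coeff, 0.97)
        lam = sigma_b * c / np.sqrt(1 - c**2)
        data[i] += lam * src
        data[j] += lam * lagged

    spec = truth.artifact_spec
    # eye blinks: raised-cosine transients on frontal sensors, mirrored
    # polarity on the EOG pair so the bipolar derivation isolates them
    if spec.blink_rate > 0:
        template = _blink_template(rate)
        n_blinks = rng.poisson(spec.blink_rate * duration_s / 60.0)
        frontal = frontal_channels(montage)
        weights = {l: rng.uniform(0.5, 1.0) for l in frontal}
        for _ in range(n_blinks):
            start = rng.integers(0, max(n - len(template), 1))
            sl = slice(start, start + len(template))
            for l in frontal:
                data[montage.index_of(l), sl] += weights[l] * template
            for l, sign in zip(EOG_PAIR, (1.0, -1.0)):
                if l in montage.labels:
                    data[montage.index_of(l), sl] += sign * template
    # high-amplitude epochs (2-s segments blown up by a low-frequency burst)
    if spec.bad_epoch_fraction > 0:
        epoch_samples = int(round(2.0 * rate))
        n_epochs = n // epoch_samples
        n_bad = int(round(spec.bad_epoch_fraction * n_epochs))
        bad = rng.choice(n_epochs, size=min(n_bad, n_epochs), replace=False)
        t = np.arange(epoch_samples) / rate
        for e in bad:
            burst = 400.0 * np.sin(2 * np.pi * rng.uniform(1.0, 3.0) * t)
            sl = slice(e * epoch_samples, (e + 1) * epoch_samples)
            data[:, sl] += burst * rng.uniform(0.5, 1.5, size=(n_ch, 1))

    # flat channels
    if spec.n_flat_channels > 0:
        candidates = [
            k for k, l in enumerate(montage.labels) if l not in EOG_PAIR
        ]
        flat = rng.choice(candidates, size=spec.n_flat_channels, replace=False)
        data[flat] *= 1e-5

    np.clip(data, -2000.0, 2000.0, out=data)
    return Recording(data=data, rate=rate, montage=montage, subject_id=truth.subject_id)


def default_coupled_pairs(montage: Montage, n_pairs: int = 6) -> list:
    """Posterior channel pairs (lowest +x, upper hemisphere) for alpha coupling."""
    labels = [l for l in montage.analysis_labels]
    pos = {l: montage.positions[montage.index_of(l)] for l in labels}
    posterior = sorted(labels, key=lambda l: pos[l][0])[: 2 * n_pairs]
    return [(posterior[2 * k], posterior[2 * k + 1]) for k in range(n_pairs)]


def truths_to_frame(truths) -> pd.DataFrame:
    return pd.DataFrame([t.as_row() for t in truths])
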