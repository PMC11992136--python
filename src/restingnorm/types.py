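"""Core containers for multichannel resting-state EEG.

The pipeline operates on three in-memory objects: a :class:`Montage`
(channel names + unit-sphere sensor positions), a :class:`Recording`
(continuous channels x samples signal in microvolts) and :class:`Epochs`
(fixed-length non-overlapping segments with a per-epoch keep mask).
All spatial math downstream (surface Laplacian, spline interpolation)
needs only unit-sphere coordinates, so positions are projected onto the
unit sphere at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with head-centered unit-sphere positions.

    Parameters
    ----------
    labels : tuple of str
        Unique channel names, in recording order.
    positions : ndarray, shape (n_channels, 3)
        Sensor coordinates; normalized to unit norm in ``__post_init__``.
    exclusion_set : frozenset of str
        Face/neck channels excluded from analysis (muscular artifacts).
    """

    labels: tuple
    positions: np.ndarray
    exclusion_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(labels)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0) or not np.all(np.isfinite(norms)):
            raise ValueError("positions must be finite and nonzero")
        object.__setattr__(self, "positions", pos / norms[:, None])
        excl = frozenset(self.exclusion_set)
        unknown = excl - set(labels)
        if unknown:
            raise ValueError(f"exclusion_set names not in montage: {sorted(unknown)}")
        object.__setattr__(self, "exclusion_set", excl)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def analysis_labels(self) -> tuple:
        """Labels retained for analysis, original order preserved."""
        return tuple(l for l in self.labels if l not in self.exclusion_set)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def subset(self, labels) -> "Montage":
        """Montage restricted to `labels`, in the given order."""
        idx = [self.index_of(l) for l in labels]
        keep = set(labels)
        return Montage(
            labels=tuple(labels),
            positions=self.positions[idx],
            exclusion_set=frozenset(l for l in self.exclusion_set if l in keep),
        )


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    rate: float  # Hz
    montage: Montage
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} data rows but montage has "
                f"{self.montage.n_channels} labels"
            )
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class Epochs:
    """Fixed-length non-overlapping segments of a recording.

    ``kept_mask`` marks epochs surviving artifact rejection;
    ``quality_ratio`` is the fraction rejected (forwarded to the
    normative model as the data-quality covariate).
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    rate: float
    epoch_length: float  # seconds
    montage: Montage
    kept_mask: np.ndarray = None
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be epochs x channels x samples")
        n_samp = int(round(self.epoch_length * self.rate))
        if self.data.shape[2] != n_samp:
            raise ValueError(
                f"epoch length {self.epoch_length}s x rate {self.rate} != "
                f"{self.data.shape[2]} samples"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (self.data.shape[0],):
                raise ValueError("kept_mask length must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def quality_ratio(self) -> float:
        """Fraction of epochs rejected, in [0, 1]."""
        if self.n_epochs == 0:
            return 0.0
        return 1.0 - self.n_kept / self.n_epochs

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.kept_mask]

    def copy_with(self, **kw) -> "Epochs":
        out = replace(self, **kw)
        out.data = np.array(out.data)
        out.kept_mask = np.array(out.kept_mask)
        return out


def _spiral_points(n: int, z_top: float = 0.995, z_bottom: float = -0.35) -> np.ndarray:
    """Evenly spread points on a spherical cap via a golden-angle spiral.

    Emulates the coverage of a high-density geodesic sensor net: the cap
    runs from the vertex down past the ears toward the face/neck.
    """
    i = np.arange(n)
    z = z_top - (z_top - z_bottom) * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_montage(n_channels: int = 128, n_excluded: int = 28) -> Montage:
    """Synthetic 128-channel geodesic-style montage.

    Channel names are ``E1``..``E{n}``.  The two most anterior-inferior
    sensors (peri-ocular, largest +x among the lowest ring) are named
    ``E8`` and ``E9`` so the conventional bipolar EOG derivation applies.
    The default exclusion set is the ``n_excluded`` lowest sensors
    (face/neck ring), leaving 100 analysis channels for the default sizes.
    """
    pos = _spiral_points(n_channels)
    # assign labels so that E8/E9 land on the two most face-ward low sensors
    order = np.arange(n_channels)
    low = np.argsort(pos[:, 2])[: max(n_excluded, 2)]
    eog = low[np.argsort(-pos[low, 0])[:2]]
    names = [f"E{k + 1}" for k in range(n_channels)]
    # swap so indices eog[0], eog[1] carry names E8, E9
    for want, idx in zip(("E8", "E9"), eog):
        cur = names.index(want)
        names[cur], names[idx] = names[idx], names[cur]
    labels = tuple(names)
    excl_idx = np.argsort(pos[:, 2])[:n_excluded]
    exclusion = frozenset(labels[i] for i in excl_idx)
    return Montage(labels=labels, positions=pos[order], exclusion_set=exclusion)


EOG_PAIR = ("E8", "E9")
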