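"""Frequency-band scheme used across spectral and connectivity features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Band edges in Hz; "whole" spans the full analyzed spectrum.
DEFAULT_BANDS = {
    "delta": (2.5, 4.0),
    "theta": (4.0, 8.0),
    "low_alpha": (8.0, 10.0),
    "high_alpha": (10.0, 12.0),
    "low_beta": (12.0, 20.0),
    "high_beta": (20.0, 30.0),
    "gamma": (30.0, 45.0),
    "whole": (2.5, 45.0),
}

FMIN, FMAX = 2.5, 45.0

# Peak-frequency search windows (subject-level argmax of periodic power).
# The alpha window deliberately reaches down into theta/delta so that
# slowed alpha rhythms in children are still captured.
PEAK_SEARCH_BANDS = {"alpha": (2.5, 14.5), "beta": (15.0, 37.0)}


@dataclass(frozen=True)
class BandScheme:
    """Named frequency intervals, all within the analyzed range [2.5, 45] Hz."""

    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self):
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name}: low {lo} must be < high {hi}")
            if lo < FMIN or hi > FMAX:
                raise ValueError(f"band {name}: [{lo}, {hi}] outside [{FMIN}, {FMAX}]")

    def __iter__(self):
        return iter(self.bands.items())

    def __getitem__(self, name):
        return self.bands[name]

    @property
    def names(self):
        return tuple(self.bands)

    def bin_mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        """Boolean mask of grid bins in a band.

        Half-open convention [low, high) so adjacent bands never share a
        bin; the whole-spectrum band closes at the top edge (45 Hz).
        """
        lo, hi = self.bands[name]
        freqs = np.asarray(freqs)
        mask = (freqs >= lo) & (freqs < hi)
        if hi >= FMAX:
            mask |= np.isclose(freqs, hi)
        return mask
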