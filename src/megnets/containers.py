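"""Core data containers shared across the pipeline.

The atomic input is a :class:`ParcelTimeSeries`: one subject's parcel-level
source time courses (parcels x samples) with its sampling rate and the
subject metadata needed downstream (group label and confounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class BandDefinition(NamedTuple):
    """A named frequency band, half-open ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float


#: The six canonical bands used throughout: delta, theta, alpha, beta,
#: low-gamma and high-gamma.  The 48-52 Hz mains gap is deliberately excluded
#: from every band.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 7.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("low_gamma", 30.0, 48.0),
    BandDefinition("high_gamma", 52.0, 80.0),
)

GROUPS: tuple[str, ...] = ("HC", "symALS", "aC9", "aSOD")


@dataclass
class ParcelTimeSeries:
    """One subject's parcel time courses.

    Parameters
    ----------
    data:
        ``(P, T)`` array, parcels by samples.
    fs:
        Sampling rate in Hz.
    subject_id, group:
        Identification labels; ``group`` is one of HC / symALS / aC9 / aSOD
        for simulated cohorts but is not restricted here.
    confounds:
        Mapping with the per-subject covariates used in group inference
        (age, sex, riluzole, missing_mri).
    """

    data: np.ndarray
    fs: float
    subject_id: str = ""
    group: str = ""
    confounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (parcels, samples) matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least two parcels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in parcel time series")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "ParcelTimeSeries":
        return ParcelTimeSeries(
            data=data,
            fs=self.fs,
            subject_id=self.subject_id,
            group=self.group,
            confounds=dict(self.confounds),
        )


@dataclass
class PowerSpectrum:
    """Per-parcel one-sided power spectral density on a uniform grid."""

    freqs: np.ndarray  # (F,)
    psd: np.ndarray  # (P, F), power density per Hz

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if self.freqs.ndim != 1 or self.freqs.size < 2:
            raise ValueError("frequency grid needs at least two points")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.psd.shape[1] != self.freqs.size:
            raise ValueError("psd and frequency grid sizes disagree")
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")


@dataclass
class ConnectivityMatrix:
    """Band-wise parcel-by-parcel amplitude envelope correlation matrix."""

    band: BandDefinition
    values: np.ndarray  # (P, P) symmetric, unit diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v
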