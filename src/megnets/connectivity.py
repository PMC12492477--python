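"""Static connectivity: band-wise amplitude envelope correlation (AEC).

AEC between two parcels is the Pearson correlation of their band-limited
amplitude envelopes (analytic-signal magnitudes).  It is computed on
leakage-corrected data by contract; the correction itself lives in
:mod:`megnets.preprocess`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .containers import DEFAULT_BANDS, BandDefinition, ConnectivityMatrix, ParcelTimeSeries

__all__ = ["amplitude_envelope", "aec_matrix", "parcel_connectedness", "connectivity_tables"]


def amplitude_envelope(
    ts: ParcelTimeSeries, band: BandDefinition, trim_seconds: float = 1.0, order: int = 5
) -> np.ndarray:
    """Band-limited amplitude envelope per parcel, shape ``(P, T')``.

    Band-pass then analytic-signal magnitude; ``trim_seconds`` are dropped
    from each end to remove filter and Hilbert edge transients.
    """
    if band.high >= ts.fs / 2:
        raise ValueError(f"band {band.name!r} exceeds the Nyquist frequency")
    sos = butter(order, [band.low, band.high], btype="bandpass", fs=ts.fs, output="sos")
    filtered = sosfiltfilt(sos, ts.data, axis=1)
    env = np.abs(hilbert(filtered, axis=1))
    trim = int(round(trim_seconds * ts.fs))
    if 2 * trim >= env.shape[1]:
        raise ValueError("recording too short for the requested edge trim")
    return env[:, trim : env.shape[1] - trim]


def aec_matrix(ts: ParcelTimeSeries, band: BandDefinition) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of parcel amplitude envelopes."""
    env = amplitude_envelope(ts, band)
    sd = env.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance envelope for parcel(s): {bad.tolist()}")
    c = np.corrcoef(env)
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(band=band, values=c)


def parcel_connectedness(conn: ConnectivityMatrix) -> np.ndarray:
    """Mean AEC between each parcel and all other parcels (signed)."""
    v = conn.values
    P = v.shape[0]
    return (v.sum(axis=1) - np.diag(v)) / (P - 1)


def connectivity_tables(
    cohort: list[ParcelTimeSeries], bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> tuple[dict, pd.DataFrame]:
    """Per-subject per-band AEC matrices and a tidy connectedness table."""
    matrices: dict = {}
    rows = []
    for ts in cohort:
        for band in bands:
            conn = aec_matrix(ts, band)
            matrices[(ts.subject_id, band.name)] = conn
            for p, val in enumerate(parcel_connectedness(conn)):
                rows.append(
                    {
                        "subject": ts.subject_id,
                        "band": band.name,
                        "parcel": p,
                        "connectedness": val,
                    }
                )
    return matrices, pd.DataFrame(rows)
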