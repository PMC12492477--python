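"""Static spectral metrics: Welch PSDs, band power, spectral shape.

The spectral shape of each parcel's PSD is decomposed, in log10-power
space, into an aperiodic power-law component ``offset - exponent*log10(f)``
and a periodic component (full log-power minus the aperiodic fit) modelled
as a sum of Gaussian peaks.  The exponent is the steepness of the aperiodic
slope (positive for spectra that fall with frequency).  The centre of
energy (CoE) is the frequency that splits the rectified periodic component's
summed power into equal halves; a lower CoE means oscillatory slowing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import curve_fit

from .containers import DEFAULT_BANDS, BandDefinition, ParcelTimeSeries, PowerSpectrum

__all__ = [
    "welch_psd",
    "band_power",
    "fit_spectral_shape",
    "center_of_energy",
    "SpectralShape",
    "spectral_tables",
]


@dataclass
class SpectralShape:
    """Aperiodic + periodic decomposition of one parcel's PSD."""

    freqs: np.ndarray  # fit grid (Hz)
    offset: float  # log10 power at 1 Hz
    exponent: float  # aperiodic slope steepness (unitless)
    peaks: list = field(default_factory=list)  # (center Hz, height log10, width Hz)
    periodic_psd: np.ndarray | None = None  # log10 power minus aperiodic fit
    coe: float = float("nan")
    fit_error: float = float("nan")  # RMSE of full model in log10 power

    @property
    def converged(self) -> bool:
        return np.isfinite(self.fit_error)


def welch_psd(ts: ParcelTimeSeries, window_seconds: float = 2.0) -> PowerSpectrum:
    """One-sided Welch PSD per parcel (Hann window, 50% overlap).

    Density normalization: the trapezoidal integral over frequency
    approximates the signal variance.
    """
    nperseg = int(round(window_seconds * ts.fs))
    if ts.n_samples < nperseg:
        raise ValueError(
            f"recording ({ts.n_samples} samples) shorter than one "
            f"{window_seconds} s window"
        )
    freqs, psd = signal.welch(
        ts.data,
        fs=ts.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
        axis=1,
    )
    return PowerSpectrum(freqs=freqs, psd=psd)


def band_power(
    ps: PowerSpectrum, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> pd.DataFrame:
    """Mean PSD per band over grid points with ``low <= f < high``.

    Returns a tidy frame with one row per (parcel, band).
    """
    rows = []
    for b in bands:
        mask = (ps.freqs >= b.low) & (ps.freqs < b.high)
        if not mask.any():
            raise ValueError(f"band {b.name!r} contains no grid frequencies")
        power = ps.psd[:, mask].mean(axis=1)
        for p, val in enumerate(power):
            rows.append({"parcel": p, "band": b.name, "power": val})
    return pd.DataFrame(rows)


def _aperiodic_model(logf: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    return offset - exponent * logf


def _gaussian(f: np.ndarray, center: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((f - center) / sd) ** 2)


def _fit_aperiodic(logf: np.ndarray, logpsd: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logpsd, 1)
    p0 = (intercept, -slope)
    try:
        popt, _ = curve_fit(_aperiodic_model, logf, logpsd, p0=p0, maxfev=5000)
    except RuntimeError:
        popt = p0
    return float(popt[0]), float(popt[1])


def _robust_aperiodic(logf: np.ndarray, logpsd: np.ndarray) -> tuple[float, float]:
    """Aperiodic fit robust to oscillatory peaks.

    A first fit is flattened out of the spectrum and refit on the points in
    the lower part of the flattened range (lowest 40%), so that oscillatory
    peaks -- which only deviate upward in log power -- do not drag the
    power-law estimate up.  The exponent is refined again after peak
    removal in :func:`fit_spectral_shape`.
    """
    off, exp_ = _fit_aperiodic(logf, logpsd)
    for _ in range(2):
        flat = logpsd - _aperiodic_model(logf, off, exp_)
        mask = flat <= np.percentile(flat, 40.0)
        if mask.sum() < 2:
            break
        off, exp_ = _fit_aperiodic(logf[mask], logpsd[mask])
    return off, exp_


def fit_spectral_shape(
    ps: PowerSpectrum,
    parcel: int = 0,
    fit_low: float = 1.0,
    fit_high: float = 70.0,
    peak_width_limits: tuple[float, float] = (0.5, 12.0),
    min_peak_height: float = 0.05,
    peak_threshold: float = 2.0,
    max_peaks: int = 20,
) -> SpectralShape:
    """Parameterize one parcel's PSD between ``fit_low`` and ``fit_high`` Hz.

    Fixed-mode aperiodic fit plus iterative Gaussian peak extraction from
    the log-power residuals.  Peak extraction stops when no residual point
    exceeds ``max(min_peak_height, peak_threshold * SD(residual))``; peak
    widths (2 x Gaussian SD) are bounded by ``peak_width_limits``.
    """
    mask = (ps.freqs >= fit_low) & (ps.freqs <= fit_high)
    f = ps.freqs[mask]
    if f.size < 4:
        raise ValueError("fit range contains too few grid points")
    pxx = ps.psd[parcel, mask]
    if np.any(pxx <= 0):
        raise ValueError("PSD must be strictly positive over the fit range")
    logf = np.log10(f)
    logpsd = np.log10(pxx)

    offset, exponent = _robust_aperiodic(logf, logpsd)
    resid = logpsd - _aperiodic_model(logf, offset, exponent)

    sd_lo, sd_hi = peak_width_limits[0] / 2, peak_width_limits[1] / 2
    guesses: list[tuple[float, float, float]] = []
    work = resid.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        height = work[i]
        if height < min_peak_height or height < peak_threshold * work.std():
            break
        center = f[i]
        half = height / 2
        # half-height crossings, linearly interpolated between grid points
        j = i
        while j + 1 < f.size and work[j + 1] > half:
            j += 1
        right = f[j]
        if j + 1 < f.size and work[j] != work[j + 1]:
            right = f[j] + (f[j + 1] - f[j]) * (work[j] - half) / (work[j] - work[j + 1])
        k = i
        while k - 1 >= 0 and work[k - 1] > half:
            k -= 1
        left = f[k]
        if k - 1 >= 0 and work[k] != work[k - 1]:
            left = f[k] - (f[k] - f[k - 1]) * (work[k] - half) / (work[k] - work[k - 1])
        fwhm = max(right - left, f[1] - f[0])
        sd = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
        guesses.append((float(center), float(height), sd))
        work = work - _gaussian(f, center, height, sd)

    # drop guesses overlapping a taller neighbour (within 0.75 joint SD)
    guesses.sort(key=lambda g: -g[1])
    kept: list[tuple[float, float, float]] = []
    for c, h, s in guesses:
        if all(abs(c - c2) > 0.75 * (s + s2) for c2, _, s2 in kept):
            kept.append((c, h, s))
    guesses = kept

    peaks: list[tuple[float, float, float]] = []
    if guesses:
        def multi_gauss(fx, *params):
            out = np.zeros_like(fx)
            for m in range(0, len(params), 3):
                out = out + _gaussian(fx, params[m], params[m + 1], params[m + 2])
            return out

        def multi_gauss_jac(fx, *params):
            cols = []
            for m in range(0, len(params), 3):
                c, h, s = params[m : m + 3]
                g = _gaussian(fx, c, h, s)
                cols += [g * (fx - c) / s**2, g / h if h else g, g * (fx - c) ** 2 / s**3]
            return np.column_stack(cols)

        p0, lo, hi = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo += [f[0], 0.0, sd_lo]
            hi += [f[-1], 2 * max(h, min_peak_height) + 1.0, sd_hi]
        try:
            popt, _ = curve_fit(
                multi_gauss, f, resid, p0=p0, bounds=(lo, hi), maxfev=5000,
                jac=multi_gauss_jac,
            )
            fitted = [tuple(popt[m : m + 3]) for m in range(0, len(popt), 3)]
        except RuntimeError:
            fitted = guesses
        peaks = [(float(c), float(h), float(2 * s)) for c, h, s in fitted]
        peak_model = np.zeros_like(f)
        for c, h, w in peaks:
            peak_model += _gaussian(f, c, h, w / 2)
        # final aperiodic refit on the peak-removed spectrum
        offset, exponent = _fit_aperiodic(logf, logpsd - peak_model)
    else:
        peak_model = np.zeros_like(f)

    aperiodic = _aperiodic_model(logf, offset, exponent)
    periodic = logpsd - aperiodic
    model = aperiodic + peak_model
    fit_error = float(np.sqrt(np.mean((logpsd - model) ** 2)))

    shape = SpectralShape(
        freqs=f,
        offset=offset,
        exponent=exponent,
        peaks=peaks,
        periodic_psd=periodic,
        fit_error=fit_error,
    )
    shape.coe = center_of_energy(shape)
    return shape


def center_of_energy(shape: SpectralShape) -> float:
    """Frequency balancing the rectified periodic power below and above it.

    Negative periodic values are floored at zero before summation; the
    half-power crossing is located by linear interpolation of the
    cumulative trapezoidal integral.  Returns NaN when the periodic
    component is identically zero.
    """
    if shape.periodic_psd is None:
        raise ValueError("periodic component unavailable")
    p = np.clip(shape.periodic_psd, 0.0, None)
    f = shape.freqs
    total = np.trapezoid(p, f)
    if total <= 0:
        return float("nan")
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(f))]
    )
    return float(np.interp(total / 2, cum, f))


def spectral_tables(
    cohort: list[ParcelTimeSeries],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_seconds: float = 2.0,
    fit_low: float = 1.0,
    fit_high: float = 70.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level tidy tables of band power and spectral-shape metrics.

    Returns ``(power, shape)`` frames: one row per (subject, parcel, band)
    and one per (subject, parcel) with offset, exponent and CoE.
    """
    power_rows, shape_rows = [], []
    for ts in cohort:
        ps = welch_psd(ts, window_seconds)
        bp = band_power(ps, bands)
        bp.insert(0, "subject", ts.subject_id)
        power_rows.append(bp)
        for p in range(ts.n_parcels):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sh = fit_spectral_shape(ps, p, fit_low, fit_high)
            shape_rows.append(
                {
                    "subject": ts.subject_id,
                    "parcel": p,
                    "offset": sh.offset,
                    "exponent": sh.exponent,
                    "coe": sh.coe,
                    "fit_error": sh.fit_error,
                }
            )
    return pd.concat(power_rows, ignore_index=True), pd.DataFrame(shape_rows)
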