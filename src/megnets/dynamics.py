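"""Dynamic network-mode stage.

Data preparation (time-delay embedding + PCA), a desk-scale
mixing-coefficient inference surrogate (windowed covariance clustering with
simplex-constrained regression), mode spectra/coherence by regression of
short-time cross-spectra onto mode time courses, and the five dynamic
summary metrics: per-mode strength (mean), variability (SD), pattern
concentration (excess kurtosis), coactivation (pairwise correlation), and
dynamic parcel connectedness (mean coherence to all other parcels, averaged
over frequency).

All five metrics are model-agnostic functions of the mode time courses and
spectra, so they apply equally to ground-truth simulator modes and to
inferred ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import linear_sum_assignment, nnls
from scipy.stats import kurtosis as _kurtosis

from .containers import ParcelTimeSeries

__all__ = [
    "tde_pca_prepare",
    "infer_mode_mixing",
    "mode_spectra",
    "dynamic_parcel_connectedness",
    "mode_summary",
    "match_modes",
    "PreparedData",
    "ModeTimeCourses",
    "ModeSpectra",
    "ModeSummary",
]


@dataclass
class ModeTimeCourses:
    """Simplex-valued mixing coefficients, shape ``(K, T')``."""

    alpha: np.ndarray
    fs_effective: float

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if np.any(a < -1e-12):
            raise ValueError("mixing coefficients must be nonnegative")
        if np.max(np.abs(a.sum(axis=0) - 1)) > 1e-9:
            raise ValueError("mixing coefficients must sum to 1 per sample")
        self.alpha = a

    @property
    def n_modes(self) -> int:
        return self.alpha.shape[0]


@dataclass
class PreparedData:
    """TDE + PCA representation of one subject."""

    components: np.ndarray  # (n_components, T')
    projection: np.ndarray  # (embedded_dim, n_components)
    explained_variance_ratio: np.ndarray
    fs: float
    lags: np.ndarray


@dataclass
class ModeSpectra:
    psd: np.ndarray  # (K, P, F), >= 0
    coherence: np.ndarray  # (K, P, P, F) in [0, 1]
    freqs: np.ndarray


@dataclass
class ModeSummary:
    strength: np.ndarray  # (K,), mean alpha
    variability: np.ndarray  # (K,), SD alpha
    concentration: np.ndarray  # (K,), excess kurtosis
    coactivation: np.ndarray  # (K, K) correlation
    coactivation_per_mode: np.ndarray  # (K,), mean off-diagonal row


def tde_pca_prepare(
    ts: ParcelTimeSeries, n_lags: int = 15, n_components: int = 100
) -> PreparedData:
    """Time-delay embed (lags -7..+7 by default) then reduce by PCA.

    Each parcel contributes ``n_lags`` lagged copies (embedded dimension
    ``P * n_lags``); rows are standardized before projection onto the top
    principal components.
    """
    if n_lags % 2 != 1:
        raise ValueError("n_lags must be odd (symmetric lags around zero)")
    P, T = ts.data.shape
    if T <= n_lags:
        raise ValueError("recording shorter than the lag window")
    if n_components > P * n_lags:
        raise ValueError(
            f"n_components={n_components} exceeds embedded dimension {P * n_lags}"
        )
    half = n_lags // 2
    Tp = T - n_lags + 1
    emb = np.empty((P * n_lags, Tp))
    for li, lag in enumerate(range(-half, half + 1)):
        emb[li::n_lags] = ts.data[:, half + lag : half + lag + Tp]
    emb -= emb.mean(axis=1, keepdims=True)
    sd = emb.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    emb /= sd
    # PCA via SVD of the (samples x variables) matrix
    U, S, Vt = np.linalg.svd(emb.T / np.sqrt(Tp), full_matrices=False)
    W = Vt[:n_components].T  # (embedded_dim, n_components)
    comps = W.T @ emb
    evr = S**2 / np.sum(S**2)
    return PreparedData(
        components=comps,
        projection=W,
        explained_variance_ratio=evr[:n_components],
        fs=ts.fs,
        lags=np.arange(-half, half + 1),
    )


def _simplex_lstsq(Tm: np.ndarray, c: np.ndarray) -> np.ndarray:
    """min ||T a - c|| subject to a >= 0, sum(a) = 1.

    Solved by nonnegative least squares on a sum-penalty augmented system;
    the penalty weight is large relative to the data scale so the simplex
    constraint holds to high accuracy, and the result is renormalized.
    """
    K = Tm.shape[1]
    scale = max(np.linalg.norm(Tm), 1.0)
    w = 1e4 * scale
    A = np.vstack([Tm, w * np.ones((1, K))])
    b = np.concatenate([c, [w]])
    a, _ = nnls(A, b)
    s = a.sum()
    return a / s if s > 0 else np.full(K, 1.0 / K)


def infer_mode_mixing(
    prepared: PreparedData,
    K: int = 6,
    window_seconds: float = 1.0,
    step_seconds: float = 0.5,
    seed: int = 0,
    n_init: int = 10,
) -> ModeTimeCourses:
    """Desk-scale surrogate inference of mode mixing coefficients.

    1. sliding-window covariances of the prepared components;
    2. K covariance templates by k-means on vectorized upper triangles
       (seeded restarts);
    3. per window, simplex-constrained least squares expressing the window
       covariance as a convex combination of the templates;
    4. nearest-window interpolation back to the sample grid.
    """
    from sklearn.cluster import KMeans

    X = prepared.components
    D, T = X.shape
    win = int(round(window_seconds * prepared.fs))
    step = int(round(step_seconds * prepared.fs))
    if win < 20:
        raise ValueError("window must cover at least 20 samples")
    starts = np.arange(0, T - win + 1, step)
    W = len(starts)
    if K > W:
        raise ValueError(f"K={K} exceeds the number of windows ({W})")
    if K == 1:
        return ModeTimeCourses(alpha=np.ones((1, T)), fs_effective=prepared.fs)

    iu = np.triu_indices(D)
    feats = np.empty((W, iu[0].size))
    covs = []
    for i, s in enumerate(starts):
        seg = X[:, s : s + win]
        seg = seg - seg.mean(axis=1, keepdims=True)
        C = seg @ seg.T / win
        covs.append(C)
        feats[i] = C[iu]
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed).fit(feats)
    templates = km.cluster_centers_  # (K, D*(D+1)/2)

    Tm = templates.T  # (features, K)
    alpha_w = np.empty((K, W))
    for i in range(W):
        alpha_w[:, i] = _simplex_lstsq(Tm, feats[i])

    centers = starts + win // 2
    idx = np.abs(np.arange(T)[None, :] - centers[:, None]).argmin(axis=0)
    alpha = alpha_w[:, idx]
    return ModeTimeCourses(alpha=alpha, fs_effective=prepared.fs)


def mode_spectra(
    ts: ParcelTimeSeries,
    modes: ModeTimeCourses,
    window_seconds: float = 2.0,
) -> ModeSpectra:
    """Mode-specific spectra and coherence by cross-spectral regression.

    Short-time cross-spectra (Hann windows, 50% overlap) are regressed
    across windows onto the window-averaged mixing coefficients by least
    squares, per frequency and parcel pair.  Mode PSDs are the diagonals of
    the regressed cross-spectra (rectified at zero); mode coherence is the
    normalized magnitude, clipped to [0, 1].
    """
    X = ts.data
    P, T = X.shape
    K = modes.n_modes
    alpha = modes.alpha
    if alpha.shape[1] != T:
        raise ValueError("mode time courses are not aligned to the time series")
    win = int(round(window_seconds * ts.fs))
    step = win // 2
    starts = np.arange(0, T - win + 1, step)
    Wn = len(starts)
    if Wn < K + 1:
        raise ValueError("fewer spectral windows than modes + 1")
    taper = signal.get_window("hann", win)
    scale = 1.0 / (ts.fs * (taper**2).sum())
    F = win // 2 + 1
    freqs = np.fft.rfftfreq(win, 1 / ts.fs)

    A = np.empty((Wn, K))
    Zs = np.empty((Wn, P, F), dtype=complex)
    for i, s in enumerate(starts):
        seg = X[:, s : s + win]
        seg = seg - seg.mean(axis=1, keepdims=True)
        Zs[i] = np.fft.rfft(seg * taper, axis=1)
        A[i] = alpha[:, s : s + win].mean(axis=1)
    M = A.T @ A
    # R[k] = sum_w A[w, k] * Z_w Z_w^H, batched over frequency
    Zc = Zs.conj().transpose(2, 0, 1)  # (F, W, P)
    R = np.empty((K, P, P, F), dtype=complex)
    for k in range(K):
        Zk = (Zs * A[:, k][:, None, None]).transpose(2, 1, 0)  # (F, P, W)
        R[k] = np.matmul(Zk, Zc).transpose(1, 2, 0)
    R *= scale
    R[..., 1:-1] *= 2  # one-sided density
    B = np.linalg.solve(M, R.reshape(K, -1)).reshape(K, P, P, F)

    psd = np.clip(np.real(np.einsum("kppf->kpf", B)), 0.0, None)
    denom = np.sqrt(np.einsum("kpf,kqf->kpqf", psd, psd))
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(B) / denom
    coh[~np.isfinite(coh)] = 0.0
    coh = np.clip(coh, 0.0, 1.0)
    for p in range(P):
        coh[:, p, p, :] = 1.0
    return ModeSpectra(psd=psd, coherence=coh, freqs=freqs)


def dynamic_parcel_connectedness(ms: ModeSpectra) -> np.ndarray:
    """Per mode and parcel: mean coherence to other parcels, then over f."""
    K, P = ms.coherence.shape[:2]
    tot = ms.coherence.sum(axis=2) - 1.0  # subtract unit diagonal
    return tot.mean(axis=-1) / (P - 1)


def mode_summary(modes: ModeTimeCourses) -> ModeSummary:
    """The per-mode summary statistics of the mode time courses."""
    a = modes.alpha
    K, T = a.shape
    if T < 4:
        raise ValueError("need at least 4 samples for kurtosis")
    strength = a.mean(axis=1)
    variability = a.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        concentration = _kurtosis(a, axis=1, fisher=True, bias=True)
    constant = variability <= 1e-12 * (np.abs(strength) + 1.0)
    if constant.any():
        warnings.warn(
            f"constant mode time course(s) {np.flatnonzero(constant).tolist()}: "
            "coactivation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        coact = np.corrcoef(a)
    coact = np.asarray(coact, dtype=float)
    coact[constant, :] = np.nan
    coact[:, constant] = np.nan
    np.fill_diagonal(coact, 1.0)
    off = coact.copy()
    np.fill_diagonal(off, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_mode = np.nanmean(off, axis=1)
    return ModeSummary(
        strength=strength,
        variability=variability,
        concentration=concentration,
        coactivation=coact,
        coactivation_per_mode=per_mode,
    )


def match_modes(
    alpha_a: np.ndarray, alpha_b: np.ndarray
) -> tuple[np.ndarray, float]:
    """Hungarian matching of modes by maximum correlation.

    Returns ``(perm, mean_corr)`` where ``alpha_a[perm]`` best matches
    ``alpha_b`` and ``mean_corr`` is the mean matched correlation.
    """
    Ka, Kb = alpha_a.shape[0], alpha_b.shape[0]
    corr = np.corrcoef(alpha_a, alpha_b)[:Ka, Ka:]
    corr = np.nan_to_num(corr)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(Kb, dtype=int)
    perm[cols] = rows
    return perm, float(corr[rows, cols].mean())


def dynamics_tables(
    cohort: list[ParcelTimeSeries],
    alphas: dict,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort-level tidy tables of the five dynamic metrics.

    ``alphas`` maps subject id to a ``(K, T)`` mixing-coefficient array
    aligned to that subject's samples (ground-truth or inferred).
    Returns ``(summary, coactivation_pairs, connectedness)`` frames.
    """
    sum_rows, pair_rows, conn_rows = [], [], []
    for ts in cohort:
        a = np.asarray(alphas[ts.subject_id], dtype=float)
        modes = ModeTimeCourses(alpha=a, fs_effective=ts.fs)
        summ = mode_summary(modes)
        ms = mode_spectra(ts, modes)
        dconn = dynamic_parcel_connectedness(ms)
        K = modes.n_modes
        for k in range(K):
            sum_rows.append(
                {
                    "subject": ts.subject_id,
                    "mode": k,
                    "strength": summ.strength[k],
                    "variability": summ.variability[k],
                    "concentration": summ.concentration[k],
                    "coactivation_mean": summ.coactivation_per_mode[k],
                }
            )
            for j in range(k + 1, K):
                pair_rows.append(
                    {
                        "subject": ts.subject_id,
                        "mode_a": k,
                        "mode_b": j,
                        "coactivation": summ.coactivation[k, j],
                    }
                )
            for p in range(ts.n_parcels):
                conn_rows.append(
                    {
                        "subject": ts.subject_id,
                        "mode": k,
                        "parcel": p,
                        "connectedness": dconn[k, p],
                    }
                )
    return (
        pd.DataFrame(sum_rows),
        pd.DataFrame(pair_rows),
        pd.DataFrame(conn_rows),
    )
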