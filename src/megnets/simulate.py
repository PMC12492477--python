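"""Synthetic resting-state cohort generator with full ground truth.

The signal model is chosen so that every downstream metric has a known
ground truth: each subject's parcel time courses are a sum of K transient
latent "network modes" plus an aperiodic 1/f background,

    x_p(t) = periodic_scale * sum_k alpha_k(t) * m_{kp} * s_k(t) + b_p(t)

where ``alpha`` are simplex-valued mixing coefficients (softmax of smooth
correlated Gaussian logits), ``s_k`` is a unit-variance band-limited Gaussian
source with a mode-specific Gaussian spectral profile, ``m_{kp}`` is a
nonnegative spatial loading, and ``b_p`` is independent noise with power
spectral density proportional to ``f**(-chi)``.

Group effects are injected as: multiplicative amplitude scaling of named
frequency bands on named parcel sets (applied exactly in the frequency
domain), a shift of every periodic peak centre (which shifts the centre of
energy), an offset of the aperiodic exponent, and an offset added to the
off-diagonal logit correlations (which raises mode coactivation while
preserving the simplex constraint).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .containers import DEFAULT_BANDS, GROUPS, BandDefinition, ParcelTimeSeries

__all__ = [
    "CohortConfig",
    "GroupEffects",
    "GroundTruth",
    "default_config",
    "simulate_mode_timecourses",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass
class GroupEffects:
    """Per-group injected effects.

    band_power maps ``(band_name, parcel_set_name)`` to an *amplitude*
    scaling factor (power scales as its square).  ``coe_shift_hz`` shifts all
    periodic peak centres; ``exponent_shift`` offsets the aperiodic exponent;
    ``coactivation_offset`` is added to the off-diagonal logit correlations.
    """

    band_power: dict = field(default_factory=dict)
    coe_shift_hz: float = 0.0
    exponent_shift: float = 0.0
    coactivation_offset: float = 0.0


@dataclass
class AgeModel:
    mean: float
    sd: float
    #: slope of log beta-band amplitude per year, applied on the
    #: sensorimotor parcel set around the reference age.
    beta_slope: float = 0.0


@dataclass
class GroundTruth:
    """Ground truth recorded alongside each simulated subject/cohort."""

    alpha_true: dict = field(default_factory=dict)  # subject_id -> (K, T)
    injected_effects: dict = field(default_factory=dict)  # subject_id -> dict
    metadata: pd.DataFrame | None = None


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate the target study: four groups (84 HC, 61 symALS,
    16 aC9, 12 aSOD), 52 parcels at 250 Hz, 480 s per subject, six latent
    network modes each with its own spatial map and spectral profile, and a
    1/f background.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"HC": 84, "symALS": 61, "aC9": 16, "aSOD": 12}
    )
    n_parcels: int = 52
    n_modes: int = 6
    fs: float = 250.0
    duration: float = 480.0
    #: per-mode (centre Hz, bandwidth Hz, relative amplitude)
    mode_spectra_spec: list = field(
        default_factory=lambda: [
            (8.0, 2.0, 1.0),   # right temporal
            (4.0, 5.0, 1.0),   # background (broad, diffuse map)
            (6.0, 2.0, 1.0),   # frontal
            (10.0, 2.0, 1.0),  # occipital
            (14.0, 3.0, 1.0),  # left temporal
            (21.0, 5.0, 1.0),  # motor
        ]
    )
    mode_maps: np.ndarray | None = None  # (K, P) nonnegative; default built
    logit_smoothness: float = 1.0  # seconds
    logit_std: float = 1.0
    logit_correlation: np.ndarray | None = None  # (K, K); default identity
    aperiodic_exponent: float = 1.0
    periodic_scale: float = 6.0
    background_scale: float = 1.0
    #: between-subject realism: lognormal sd of per-mode amplitude jitter,
    #: normal sd of per-subject exponent jitter, lognormal sd of background.
    subject_amp_jitter: float = 0.1
    subject_exponent_jitter: float = 0.05
    subject_background_jitter: float = 0.1
    effect_table: dict = field(
        default_factory=lambda: {
            "HC": GroupEffects(),
            "symALS": GroupEffects(
                band_power={("beta", "sensorimotor"): 0.8},
                coe_shift_hz=-0.5,
                exponent_shift=-0.1,
            ),
            "aC9": GroupEffects(
                band_power={("beta", "occipital"): 0.85, ("beta", "temporal"): 0.85},
                coe_shift_hz=-1.0,
                exponent_shift=0.15,
                coactivation_offset=0.3,
            ),
            "aSOD": GroupEffects(
                coe_shift_hz=1.0,
                exponent_shift=0.1,
            ),
        }
    )
    age_model: dict = field(
        default_factory=lambda: {
            "HC": AgeModel(57.0, 16.0, beta_slope=0.004),
            "symALS": AgeModel(63.0, 11.0, beta_slope=0.0),
            "aC9": AgeModel(48.0, 14.0, beta_slope=0.004),
            "aSOD": AgeModel(47.0, 12.0, beta_slope=0.0),
        }
    )
    reference_age: float = 55.0
    sex_male_rate: dict = field(
        default_factory=lambda: {"HC": 0.52, "symALS": 0.69, "aC9": 0.31, "aSOD": 0.08}
    )
    riluzole_rate: dict = field(
        default_factory=lambda: {"HC": 0.0, "symALS": 0.524, "aC9": 0.0, "aSOD": 0.0}
    )
    missing_mri_rate: dict = field(
        default_factory=lambda: {
            "HC": 2 / 84,
            "symALS": 4 / 61,
            "aC9": 3 / 16,
            "aSOD": 1 / 12,
        }
    )
    parcel_sets: dict | None = None  # name -> index array; default built
    bands: tuple = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be nonnegative")
        highest_edge = max(b.high for b in self.bands)
        if not self.fs > 2 * highest_edge:
            raise ValueError("fs must exceed twice the highest band edge")
        if self.mode_maps is None:
            self.mode_maps = default_mode_maps(self.n_modes, self.n_parcels)
        self.mode_maps = np.asarray(self.mode_maps, dtype=float)
        if self.mode_maps.shape != (self.n_modes, self.n_parcels):
            raise ValueError("mode_maps must be (n_modes, n_parcels)")
        if np.any(self.mode_maps < 0):
            raise ValueError("mode_maps must be nonnegative")
        if self.logit_correlation is None:
            self.logit_correlation = np.eye(self.n_modes)
        self.logit_correlation = np.asarray(self.logit_correlation, dtype=float)
        _check_correlation(self.logit_correlation, self.n_modes)
        if self.parcel_sets is None:
            self.parcel_sets = default_parcel_sets(self.n_parcels)
        if len(self.mode_spectra_spec) != self.n_modes:
            raise ValueError("mode_spectra_spec must have one entry per mode")
        for grp, eff in self.effect_table.items():
            band_names = {b.name for b in self.bands}
            for band_name, set_name in eff.band_power:
                if band_name not in band_names:
                    raise ValueError(f"unknown band {band_name!r} in effect table")
                if set_name not in self.parcel_sets:
                    raise ValueError(
                        f"effect for group {grp!r} references unknown parcel set "
                        f"{set_name!r}"
                    )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def default_config(**overrides) -> CohortConfig:
    """The default study conditions, with keyword overrides."""
    return CohortConfig(**overrides)


def default_parcel_sets(n_parcels: int) -> dict:
    """Contiguous index blocks standing in for anatomical lobes."""
    bounds = {
        "frontal": (0.0, 0.23),
        "sensorimotor": (0.23, 0.42),
        "temporal": (0.42, 0.69),
        "parietal": (0.69, 0.85),
        "occipital": (0.85, 1.0),
    }
    sets = {}
    for name, (lo, hi) in bounds.items():
        sets[name] = np.arange(int(round(lo * n_parcels)), int(round(hi * n_parcels)))
    sets["all"] = np.arange(n_parcels)
    return sets


def default_mode_maps(n_modes: int, n_parcels: int) -> np.ndarray:
    """Spatial loadings: one diffuse background mode, the rest block-local."""
    sets = default_parcel_sets(n_parcels)
    temporal = sets["temporal"]
    half = len(temporal) // 2
    blocks = [
        temporal[:half],               # right temporal
        sets["all"],                   # background: diffuse
        sets["frontal"],
        sets["occipital"],
        temporal[half:],               # left temporal
        sets["sensorimotor"],
    ]
    maps = np.full((n_modes, n_parcels), 0.05)
    for k in range(n_modes):
        block = blocks[k % len(blocks)]
        maps[k, block] = 0.4 if k % len(blocks) == 1 else 1.0
    return maps


def _check_correlation(corr: np.ndarray, k: int) -> None:
    if corr.shape != (k, k):
        raise ValueError("logit correlation must be K x K")
    if np.max(np.abs(corr - corr.T)) > 1e-10:
        raise ValueError("logit correlation must be symmetric")
    if np.max(np.abs(np.diag(corr) - 1)) > 1e-10:
        raise ValueError("logit correlation must have unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValueError("logit correlation must be positive semidefinite")


def _nearest_correlation(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    w, v = np.linalg.eigh((corr + corr.T) / 2)
    w = np.clip(w, 1e-8, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def simulate_mode_timecourses(
    K: int,
    T: int,
    fs: float,
    smoothness: float = 1.0,
    logit_correlation: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    logit_std: float = 1.0,
) -> np.ndarray:
    """Simplex-valued mode mixing coefficients, shape ``(K, T)``.

    Each time column is the softmax of temporally smoothed, cross-correlated
    Gaussian logits; ``smoothness`` is the Gaussian kernel width in seconds.
    """
    if K < 1 or T < 1:
        raise ValueError("K and T must be at least 1")
    if logit_correlation is None:
        logit_correlation = np.eye(K)
    logit_correlation = np.asarray(logit_correlation, dtype=float)
    _check_correlation(logit_correlation, K)
    rng = np.random.default_rng(seed)
    if K == 1:
        return np.ones((1, T))
    z = rng.standard_normal((K, T))
    sigma = smoothness * fs
    if sigma > 0:
        z = gaussian_filter1d(z, sigma=sigma, axis=1, mode="wrap")
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = z / sd
    L = np.linalg.cholesky(logit_correlation + 1e-12 * np.eye(K))
    logits = logit_std * (L @ z)
    logits -= logits.max(axis=0, keepdims=True)
    expl = np.exp(logits)
    return expl / expl.sum(axis=0, keepdims=True)


def _bandlimited_source(
    T: int, fs: float, center: float, bandwidth: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise with a Gaussian spectral profile."""
    white = rng.standard_normal(T)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(T, 1 / fs)
    gain = np.exp(-0.5 * ((f - center) / max(bandwidth, 1e-6)) ** 2)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=T)
    sd = x.std()
    return x / sd if sd > 0 else x


def _aperiodic_background(
    T: int, fs: float, exponent: float, rng: np.random.Generator, f_min: float = 0.5
) -> np.ndarray:
    """Unit-variance noise with PSD proportional to f**(-exponent)."""
    white = rng.standard_normal(T)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(T, 1 / fs)
    fc = np.maximum(f, f_min)
    gain = fc ** (-exponent / 2)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=T)
    sd = x.std()
    return x / sd if sd > 0 else x


def _scale_band_amplitude(
    data: np.ndarray, fs: float, band: BandDefinition, factor: float
) -> np.ndarray:
    """Exact frequency-domain amplitude scaling on the half-open band."""
    spec = np.fft.rfft(data, axis=-1)
    f = np.fft.rfftfreq(data.shape[-1], 1 / fs)
    mask = (f >= band.low) & (f < band.high)
    spec[..., mask] *= factor
    return np.fft.irfft(spec, n=data.shape[-1], axis=-1)


def simulate_subject(
    config: CohortConfig,
    group: str,
    age: float,
    seed: int | np.random.Generator,
    subject_id: str = "",
    sex: int = 0,
    riluzole: int = 0,
    missing_mri: int = 0,
) -> tuple[ParcelTimeSeries, GroundTruth]:
    """Simulate one subject's parcel time series and record ground truth."""
    if group not in config.effect_table:
        raise ValueError(f"unknown group {group!r}")
    eff: GroupEffects = config.effect_table[group]
    rng = np.random.default_rng(seed)
    T = config.n_samples
    K, P = config.n_modes, config.n_parcels

    corr = config.logit_correlation.copy()
    if eff.coactivation_offset:
        off = ~np.eye(K, dtype=bool)
        corr[off] = np.clip(corr[off] + eff.coactivation_offset, -0.99, 0.99)
        corr = _nearest_correlation(corr)
    alpha = simulate_mode_timecourses(
        K, T, config.fs, config.logit_smoothness, corr, rng, config.logit_std
    )

    amp_jitter = np.exp(config.subject_amp_jitter * rng.standard_normal(K))
    data = np.zeros((P, T))
    for k, (center, bw, rel_amp) in enumerate(config.mode_spectra_spec):
        src = _bandlimited_source(T, config.fs, center + eff.coe_shift_hz, bw, rng)
        amp = config.periodic_scale * rel_amp * amp_jitter[k]
        data += np.outer(config.mode_maps[k], amp * alpha[k] * src)

    chi = (
        config.aperiodic_exponent
        + eff.exponent_shift
        + config.subject_exponent_jitter * rng.standard_normal()
    )
    bg_scale = config.background_scale * np.exp(
        config.subject_background_jitter * rng.standard_normal()
    )
    if bg_scale > 0:
        for p in range(P):
            data[p] += bg_scale * _aperiodic_background(T, config.fs, chi, rng)

    bands = {b.name: b for b in config.bands}
    age_mod = config.age_model.get(group)
    scale_by_set: dict = {}
    for (band_name, set_name), factor in eff.band_power.items():
        key = (band_name, set_name)
        scale_by_set[key] = scale_by_set.get(key, 1.0) * factor
    if age_mod is not None and age_mod.beta_slope:
        g = float(np.exp(age_mod.beta_slope * (age - config.reference_age)))
        key = ("beta", "sensorimotor")
        scale_by_set[key] = scale_by_set.get(key, 1.0) * g
    for (band_name, set_name), factor in scale_by_set.items():
        idx = config.parcel_sets[set_name]
        data[idx] = _scale_band_amplitude(data[idx], config.fs, bands[band_name], factor)

    ts = ParcelTimeSeries(
        data=data,
        fs=config.fs,
        subject_id=subject_id,
        group=group,
        confounds={
            "age": float(age),
            "sex": int(sex),
            "riluzole": int(riluzole),
            "missing_mri": int(missing_mri),
        },
    )
    gt = GroundTruth(
        alpha_true={subject_id: alpha},
        injected_effects={
            subject_id: {
                "band_power": dict(scale_by_set),
                "coe_shift_hz": eff.coe_shift_hz,
                "exponent": chi,
                "coactivation_offset": eff.coactivation_offset,
            }
        },
    )
    return ts, gt


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[ParcelTimeSeries], pd.DataFrame, GroundTruth]:
    """Simulate every configured subject; deterministic given ``config.seed``.

    One seed sequence spawns independent child seeds per subject, so the
    cohort is reproducible and subjects are mutually independent.
    """
    master = np.random.SeedSequence(config.seed)
    groups_order = [g for g in GROUPS if g in config.n_per_group] + [
        g for g in config.n_per_group if g not in GROUPS
    ]
    n_total = sum(config.n_per_group.values())
    children = master.spawn(n_total + 1)
    meta_rng = np.random.default_rng(children[0])

    cohort: list[ParcelTimeSeries] = []
    rows = []
    truth = GroundTruth()
    i = 0
    for group in groups_order:
        am = config.age_model[group]
        for _ in range(config.n_per_group[group]):
            sid = f"sub-{i:04d}"
            age = float(meta_rng.normal(am.mean, am.sd))
            sex = int(meta_rng.random() < config.sex_male_rate.get(group, 0.5))
            ril = int(meta_rng.random() < config.riluzole_rate.get(group, 0.0))
            mmri = int(meta_rng.random() < config.missing_mri_rate.get(group, 0.0))
            ts, gt = simulate_subject(
                config, group, age, children[i + 1], sid, sex, ril, mmri
            )
            cohort.append(ts)
            truth.alpha_true.update(gt.alpha_true)
            truth.injected_effects.update(gt.injected_effects)
            rows.append(
                {
                    "id": sid,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "riluzole": ril,
                    "missing_mri": mmri,
                }
            )
            i += 1
    metadata = pd.DataFrame(rows)
    truth.metadata = metadata.copy()
    return cohort, metadata, truth


def sample_ages(config: CohortConfig, group: str, n: int, seed: int = 0) -> np.ndarray:
    """Draw ages from a group's age model (for calibration checks)."""
    am = config.age_model[group]
    return np.random.default_rng(seed).normal(am.mean, am.sd, size=n)


def config_to_dict(config: CohortConfig) -> dict:
    """Plain-dict snapshot of a config (YAML/JSON-serializable)."""
    d = copy.deepcopy(config.__dict__)
    d["mode_maps"] = np.asarray(d["mode_maps"]).tolist()
    d["logit_correlation"] = np.asarray(d["logit_correlation"]).tolist()
    d["parcel_sets"] = {k: np.asarray(v).tolist() for k, v in d["parcel_sets"].items()}
    d["bands"] = [list(b) for b in d["bands"]]
    d["effect_table"] = {
        g: {
            "band_power": {f"{b}|{s}": v for (b, s), v in e.band_power.items()},
            "coe_shift_hz": e.coe_shift_hz,
            "exponent_shift": e.exponent_shift,
            "coactivation_offset": e.coactivation_offset,
        }
        for g, e in d["effect_table"].items()
    }
    d["age_model"] = {
        g: {"mean": a.mean, "sd": a.sd, "beta_slope": a.beta_slope}
        for g, a in d["age_model"].items()
    }
    return d


def config_from_dict(d: dict) -> CohortConfig:
    """Inverse of :func:`config_to_dict`."""
    d = copy.deepcopy(d)
    d["mode_maps"] = np.asarray(d["mode_maps"], dtype=float)
    d["logit_correlation"] = np.asarray(d["logit_correlation"], dtype=float)
    d["parcel_sets"] = {k: np.asarray(v, dtype=int) for k, v in d["parcel_sets"].items()}
    d["bands"] = tuple(BandDefinition(str(b[0]), float(b[1]), float(b[2])) for b in d["bands"])
    d["mode_spectra_spec"] = [tuple(m) for m in d["mode_spectra_spec"]]
    d["effect_table"] = {
        g: GroupEffects(
            band_power={
                (k.split("|")[0], k.split("|")[1]): v
                for k, v in e.get("band_power", {}).items()
            },
            coe_shift_hz=e.get("coe_shift_hz", 0.0),
            exponent_shift=e.get("exponent_shift", 0.0),
            coactivation_offset=e.get("coactivation_offset", 0.0),
        )
        for g, e in d["effect_table"].items()
    }
    d["age_model"] = {
        g: AgeModel(a["mean"], a["sd"], a.get("beta_slope", 0.0))
        for g, a in d["age_model"].items()
    }
    return CohortConfig(**d)
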