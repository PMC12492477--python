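"""Group inference: GLM contrasts with confound regression and max-t
family-wise-error-controlled permutation testing, plus the beta-power
aging-trajectory analysis.

The design has one 0/1 indicator column per group and one z-scored column
per confound.  Contrasts of parameter estimates (copes) are tested with
one-sided max-statistic permutation: per permutation the outcome rows are
shuffled among the subjects belonging to the groups entering the contrast,
the maximum t over all features is recorded, and

    p_corrected = (1 + #{max-t null >= t_observed}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix",
    "PermutationResult",
    "build_design",
    "fit_glm",
    "maxt_permutation",
    "beta_age_trajectory",
]

DEFAULT_CONTRASTS = (
    ("symALS-HC", "symALS", "HC"),
    ("aC9-HC", "aC9", "HC"),
    ("aSOD-HC", "aSOD", "HC"),
    ("aC9-aSOD", "aC9", "aSOD"),
)


@dataclass
class DesignMatrix:
    X: np.ndarray  # (N, R)
    regressor_names: list
    contrasts: dict  # name -> (R,) vector
    group_labels: np.ndarray  # (N,) group per subject


@dataclass
class PermutationResult:
    cope: np.ndarray  # (M,)
    tstat: np.ndarray  # (M,)
    p_corrected: np.ndarray  # (M,)
    null_max_t: np.ndarray  # (n_perm,)
    n_perm: int
    seed: int | None = None
    contrast_name: str = ""
    dof: int = 0


def build_design(
    metadata: pd.DataFrame,
    groups: tuple[str, ...] = ("HC", "symALS", "aC9", "aSOD"),
    confounds: tuple[str, ...] = ("age", "sex", "riluzole", "missing_mri"),
    contrasts: tuple = DEFAULT_CONTRASTS,
) -> DesignMatrix:
    """Group indicators plus z-scored confound columns, with contrasts.

    Constant confounds are dropped with a warning; a rank-deficient design
    raises.
    """
    present = [g for g in groups if (metadata["group"] == g).any()]
    missing = set(metadata["group"]) - set(groups)
    if missing:
        raise ValueError(f"subjects with unknown group(s): {sorted(missing)}")
    cols, names = [], []
    for g in present:
        cols.append((metadata["group"] == g).to_numpy(dtype=float))
        names.append(g)
    for c in confounds:
        v = metadata[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite confound values in {c!r}")
        sd = v.std()
        if sd == 0:
            warnings.warn(f"constant confound {c!r} dropped", stacklevel=2)
            continue
        cols.append((v - v.mean()) / sd)
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    cdict = {}
    for name, pos, neg in contrasts:
        if pos not in present or neg not in present:
            continue
        c = np.zeros(X.shape[1])
        c[names.index(pos)] = 1.0
        c[names.index(neg)] = -1.0
        cdict[name] = c
    return DesignMatrix(
        X=X,
        regressor_names=names,
        contrasts=cdict,
        group_labels=metadata["group"].to_numpy(),
    )


def fit_glm(
    y: np.ndarray, design: DesignMatrix, contrast: np.ndarray
) -> tuple[float, float, int]:
    """OLS fit of one outcome; returns ``(cope, t, dof)``."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(
            f"non-finite outcome for subject rows {np.flatnonzero(~np.isfinite(y)).tolist()}"
        )
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome length does not match the design")
    cope, t, dof = _glm_t(y[:, None], X, np.asarray(contrast, dtype=float))
    return float(cope[0]), float(t[0]), dof


def _glm_t(
    Y: np.ndarray,
    X: np.ndarray,
    c: np.ndarray,
    pinv: np.ndarray | None = None,
    dof: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS t-statistics for many outcomes at once."""
    if pinv is None:
        pinv = np.linalg.pinv(X)
    if dof is None:
        dof = X.shape[0] - np.linalg.matrix_rank(X)
    xtx_inv = pinv @ pinv.T  # (X'X)^-1 for full-rank X
    cxx = float(c @ xtx_inv @ c)
    beta = pinv @ Y  # (R, M)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    cope = c @ beta
    # an (essentially) exact fit has no error variance: t is defined as 0
    degenerate = sigma2 <= 1e-12 * (Y**2).mean(axis=0) + 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cope / np.sqrt(sigma2 * cxx)
    t = np.where(np.isfinite(t) & ~degenerate, t, 0.0)
    return cope, t, dof


def _active_rows(design: DesignMatrix, contrast: np.ndarray) -> np.ndarray:
    """Subjects in groups carrying nonzero contrast weight (the
    exchangeability unit for permutations)."""
    active_groups = [
        name
        for name, w in zip(design.regressor_names, contrast)
        if w != 0 and name in set(design.group_labels)
    ]
    mask = np.isin(design.group_labels, active_groups)
    return np.flatnonzero(mask)


def maxt_permutation(
    Y: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    exact: bool = False,
    contrast_name: str = "",
) -> PermutationResult:
    """One-sided max-t permutation test over all features jointly.

    ``Y`` is (subjects, features).  With ``exact=True`` and a two-group
    contrast, all distinct relabelings are enumerated instead of sampled
    (the observed labeling counts as one of them).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] == 0:
        raise ValueError("no features to test")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite values in the feature matrix")
    if n_perm < 100 and not exact:
        warnings.warn("fewer than 100 permutations: p-values are coarse", stacklevel=2)
    contrast = np.asarray(contrast, dtype=float)
    X = design.X
    pinv = np.linalg.pinv(X)
    cope, t_obs, dof = _glm_t(Y, X, contrast, pinv=pinv)
    rows = _active_rows(design, contrast)
    rng = np.random.default_rng(seed)

    null_max = []
    if exact:
        group_w = {
            name: w for name, w in zip(design.regressor_names, contrast) if w != 0
        }
        active_groups = [g for g in group_w if g in set(design.group_labels)]
        if len(active_groups) != 2:
            raise ValueError("exact enumeration supports two-group contrasts only")
        g0 = active_groups[0]
        n0 = int((design.group_labels[rows] == g0).sum())
        for comb in combinations(range(rows.size), n0):
            perm = np.concatenate(
                [np.array(comb, dtype=int),
                 np.array([i for i in range(rows.size) if i not in comb], dtype=int)]
            )
            Yp = Y.copy()
            Yp[rows] = Y[rows][perm]
            _, t_p, _ = _glm_t(Yp, X, contrast, pinv=pinv, dof=dof)
            null_max.append(t_p.max())
        n_used = len(null_max)
    else:
        for _ in range(n_perm):
            perm = rng.permutation(rows.size)
            Yp = Y.copy()
            Yp[rows] = Y[rows][perm]
            _, t_p, _ = _glm_t(Yp, X, contrast, pinv=pinv, dof=dof)
            null_max.append(t_p.max())
        n_used = n_perm
    null_max = np.asarray(null_max)
    p = (1 + (null_max[None, :] >= t_obs[:, None]).sum(axis=1)) / (1 + n_used)
    return PermutationResult(
        cope=cope,
        tstat=t_obs,
        p_corrected=p,
        null_max_t=null_max,
        n_perm=n_used,
        seed=seed,
        contrast_name=contrast_name,
        dof=dof,
    )


@dataclass
class AgeTrajectoryResult:
    selected_parcels: np.ndarray
    hc_parcel_t: np.ndarray
    hc_parcel_p: np.ndarray
    group_regressions: dict = field(default_factory=dict)  # group -> (slope, r, p_bonf)
    interaction_t: dict = field(default_factory=dict)  # group -> t vs HC slope
    mean_beta: pd.DataFrame | None = None


def beta_age_trajectory(
    betapower: pd.DataFrame,
    metadata: pd.DataFrame,
    p_select: float = 0.001,
) -> AgeTrajectoryResult:
    """Beta-power-versus-age trajectory analysis.

    Within healthy controls, parcels with a highly significant *increase*
    of beta power with age (p < ``p_select``) are selected; the mean beta
    power over the selected parcels is regressed on age per group
    (Bonferroni-corrected over groups), and the group-by-age interaction on
    that mean is tested against the control slope.

    ``betapower`` is a (subjects x parcels) frame indexed by subject id.
    """
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    meta = meta.loc[betapower.index]
    hc = meta["group"] == "HC"
    if hc.sum() < 3:
        raise ValueError("need at least 3 healthy controls")
    age_hc = meta.loc[hc, "age"].to_numpy(dtype=float)
    Yhc = betapower.loc[hc.to_numpy()].to_numpy(dtype=float)
    Xage = np.column_stack([np.ones(age_hc.size), age_hc])
    beta_hat = np.linalg.lstsq(Xage, Yhc, rcond=None)[0]
    resid = Yhc - Xage @ beta_hat
    dof = age_hc.size - 2
    s2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(Xage.T @ Xage)
    se = np.sqrt(s2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_slope = np.where(se > 0, beta_hat[1] / se, 0.0)
    p_two = 2 * stats.t.sf(np.abs(t_slope), dof)
    selected = np.flatnonzero((p_two < p_select) & (beta_hat[1] > 0))

    result = AgeTrajectoryResult(
        selected_parcels=selected, hc_parcel_t=t_slope, hc_parcel_p=p_two
    )
    if selected.size == 0:
        warnings.warn("no parcels selected; trajectory analysis skipped", stacklevel=2)
        return result

    mean_beta = betapower.iloc[:, selected].mean(axis=1)
    result.mean_beta = pd.DataFrame(
        {"mean_beta": mean_beta, "age": meta["age"], "group": meta["group"]}
    )
    groups = [g for g in ("HC", "symALS", "aC9", "aSOD") if (meta["group"] == g).any()]
    for g in groups:
        sel = (meta["group"] == g).to_numpy()
        if sel.sum() < 3:
            continue
        reg = stats.linregress(meta.loc[sel, "age"], mean_beta[sel])
        result.group_regressions[g] = (
            float(reg.slope),
            float(reg.rvalue),
            float(min(1.0, reg.pvalue * len(groups))),
        )

    # group-by-age interaction vs the control slope on the selected mean
    y = mean_beta.to_numpy(dtype=float)
    ages = meta["age"].to_numpy(dtype=float)
    zage = (ages - ages.mean()) / ages.std()
    cols, names = [], []
    for g in groups:
        ind = (meta["group"] == g).to_numpy(dtype=float)
        cols += [ind, ind * zage]
        names += [g, f"{g}:age"]
    Xint = np.column_stack(cols)
    for g in groups:
        if g == "HC":
            continue
        c = np.zeros(Xint.shape[1])
        c[names.index(f"{g}:age")] = 1.0
        c[names.index("HC:age")] = -1.0
        design = DesignMatrix(
            X=Xint, regressor_names=names, contrasts={}, group_labels=meta["group"].to_numpy()
        )
        _, t, _ = fit_glm(y, design, c)
        result.interaction_t[g] = t
    return result
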