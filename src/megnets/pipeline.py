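"""End-to-end runner: simulate -> preprocess -> spectral -> connectivity ->
dynamics -> glm -> classify, with a run manifest for reproducibility.

All randomness flows from named per-stage seeds derived from the manifest's
master seed; rerunning with the same config and seed reproduces identical
outputs for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import assemble_features, match_controls, nested_cv_classify
from .connectivity import connectivity_tables
from .dynamics import dynamics_tables, infer_mode_mixing, tde_pca_prepare
from .glm import build_design, maxt_permutation
from .io import write_cohort
from .preprocess import preprocess_cohort
from .simulate import CohortConfig, config_to_dict, simulate_cohort
from .spectral import spectral_tables

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "preprocess", "spectral", "connectivity", "dynamics", "glm", "classify")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict
    version: str = __version__
    checksums: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, units: str) -> None:
    with open(path, "w") as f:
        f.write(f"# units: {units}\n")
        df.to_csv(f, index=False)


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    seed: int | None = None,
    skip: tuple = (),
    alpha_source: str = "true",
    n_perm: int = 1000,
    write_timeseries: bool = False,
    classifier_kwargs: dict | None = None,
) -> RunManifest:
    """Run every stage on a simulated cohort and write all artifacts.

    ``alpha_source`` selects ground-truth ("true") or surrogate-inferred
    ("inferred") mode time courses for the dynamics stage.  Stages named in
    ``skip`` are omitted (downstream stages adapt, e.g. the classifier uses
    static features only when dynamics is skipped).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, ss.spawn(len(STAGES)))
    }
    manifest = RunManifest(
        config=config_to_dict(config), seed=seed, stage_seeds=stage_seeds,
        skipped=[s for s in skip],
    )

    def _done(stage: str, *paths: Path) -> None:
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
        for p in paths:
            manifest.checksums[p.name] = _sha256(p)

    # --- simulate
    try:
        config.seed = stage_seeds["simulate"]
        cohort, metadata, truth = simulate_cohort(config)
        meta_path = out / "metadata.csv"
        _write_csv(metadata, meta_path, "age: years; sex/riluzole/missing_mri: 0|1")
        paths = [meta_path]
        if write_timeseries:
            h5 = out / "cohort.h5"
            write_cohort(h5, cohort, metadata, truth.alpha_true)
            paths.append(h5)
        _done("simulate", *paths)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    # --- preprocess
    if "preprocess" not in skip:
        try:
            cohort = preprocess_cohort(cohort)
            _done("preprocess")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("preprocess", e) from e

    power = shape = None
    if "spectral" not in skip:
        try:
            power, shape = spectral_tables(cohort, bands=config.bands)
            p1, p2 = out / "band_power.csv", out / "spectral_shape.csv"
            _write_csv(power, p1, "power: z-unit^2/Hz (mean density over band)")
            _write_csv(shape, p2, "offset: log10 power; exponent: unitless; coe: Hz")
            _done("spectral", p1, p2)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("spectral", e) from e

    conn_table = None
    if "connectivity" not in skip:
        try:
            _, conn_table = connectivity_tables(cohort, bands=config.bands)
            p = out / "static_connectedness.csv"
            _write_csv(conn_table, p, "connectedness: mean AEC (correlation units)")
            _done("connectivity", p)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("connectivity", e) from e

    dyn_summary = dyn_pairs = dyn_conn = None
    if "dynamics" not in skip:
        try:
            if alpha_source == "true":
                alphas = truth.alpha_true
            else:
                alphas = {}
                for ts in cohort:
                    prep = tde_pca_prepare(
                        ts, n_components=min(100, ts.n_parcels * 15)
                    )
                    modes = infer_mode_mixing(
                        prep, K=config.n_modes, seed=stage_seeds["dynamics"]
                    )
                    pad = ts.n_samples - modes.alpha.shape[1]
                    a = np.pad(modes.alpha, ((0, 0), (pad // 2, pad - pad // 2)), mode="edge")
                    alphas[ts.subject_id] = a
            dyn_summary, dyn_pairs, dyn_conn = dynamics_tables(cohort, alphas)
            p1 = out / "dynamic_summary.csv"
            p2 = out / "dynamic_coactivation.csv"
            p3 = out / "dynamic_connectedness.csv"
            _write_csv(dyn_summary, p1, "strength/variability: mixing units; concentration: excess kurtosis")
            _write_csv(dyn_pairs, p2, "coactivation: Pearson correlation")
            _write_csv(dyn_conn, p3, "connectedness: mean coherence in [0,1]")
            _done("dynamics", p1, p2, p3)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("dynamics", e) from e

    if "glm" not in skip and power is not None:
        try:
            design = build_design(metadata)
            wide = power.pivot_table(
                index="subject", columns=["band", "parcel"], values="power"
            )
            order = metadata["id"].tolist()
            Y = np.log10(wide.loc[order].to_numpy())
            rows = []
            for name, c in design.contrasts.items():
                res = maxt_permutation(
                    Y, design, c, n_perm=n_perm, seed=stage_seeds["glm"],
                    contrast_name=name,
                )
                for m, (band, parcel) in enumerate(wide.columns):
                    rows.append(
                        {
                            "contrast": name,
                            "band": band,
                            "parcel": parcel,
                            "cope": res.cope[m],
                            "t": res.tstat[m],
                            "p_corrected": res.p_corrected[m],
                        }
                    )
            glm_df = pd.DataFrame(rows)
            p = out / "glm_band_power.csv"
            _write_csv(glm_df, p, "cope: log10 power difference; p: FWE-corrected")
            with open(out / "glm_manifest.json", "w") as f:
                json.dump({"seed": stage_seeds["glm"], "n_perm": n_perm}, f)
            _done("glm", p, out / "glm_manifest.json")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("glm", e) from e

    if "classify" not in skip:
        try:
            meta_idx = metadata.set_index("id")
            labels_all = meta_idx["group"].isin(["aC9", "aSOD"]).astype(int)
            n_risk = int(labels_all.sum())
            if n_risk >= 4:
                hc_ids = meta_idx.index[meta_idx["group"] == "HC"]
                risk_ids = meta_idx.index[labels_all == 1]
                n_ctrl = min(len(hc_ids), max(n_risk, int(round(n_risk * 40 / 28))))
                chosen, _ = match_controls(
                    meta_idx.loc[hc_ids, "age"].to_numpy(),
                    meta_idx.loc[risk_ids, "age"].to_numpy(),
                    n_controls=n_ctrl,
                    seed=stage_seeds["classify"],
                )
                keep = list(hc_ids[chosen]) + list(risk_ids)
                labels = labels_all.loc[keep]
                ft = assemble_features(
                    power=power[power.subject.isin(keep)] if power is not None else None,
                    shape=shape[shape.subject.isin(keep)] if shape is not None else None,
                    dyn_summary=dyn_summary[dyn_summary.subject.isin(keep)]
                    if dyn_summary is not None
                    else None,
                    dyn_pairs=dyn_pairs[dyn_pairs.subject.isin(keep)]
                    if dyn_pairs is not None
                    else None,
                    dyn_connectedness=dyn_conn[dyn_conn.subject.isin(keep)]
                    if dyn_conn is not None
                    else None,
                    labels=labels,
                )
                report = nested_cv_classify(
                    ft, seed=stage_seeds["classify"], **(classifier_kwargs or {})
                )
                p = out / "classifier_report.json"
                with open(p, "w") as f:
                    json.dump(
                        {
                            "roc_auc": report.roc_auc,
                            "roc_ci": list(report.roc_ci),
                            "pr_auc": report.pr_auc,
                            "pr_ci": list(report.pr_ci),
                            "confusion": report.confusion.tolist(),
                            "sensitivity": report.sensitivity,
                            "specificity": report.specificity,
                            "n_features": len(ft.feature_names),
                            "selected_features": report.selected_features,
                            "seed": report.seed,
                        },
                        f,
                        indent=2,
                    )
                curves = pd.DataFrame(report.roc_points, columns=["fpr", "tpr"])
                pc = out / "roc_curve.csv"
                _write_csv(curves, pc, "fractions in [0,1]")
                _done("classify", p, pc)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("classify", e) from e

    manifest.save(out / "manifest.json")
    return manifest
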