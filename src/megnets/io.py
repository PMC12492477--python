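"""Cohort I/O: HDF5 container, delimited-text dialect, config files.

HDF5 layout (one file per cohort)::

    /subjects/<id>/timeseries   (P, T) float64, attrs: fs, group
    /subjects/<id>/alpha_true   (K, T) float64, optional

with a metadata CSV alongside (columns: id, group, age, sex, riluzole,
missing_mri).  A delimited-text dialect (one TSV per subject) is supported
for tiny fixtures and loads to identical in-memory cohorts.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import ParcelTimeSeries
from .simulate import CohortConfig, config_from_dict, config_to_dict

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_cohort_text",
    "read_cohort_text",
    "load_config",
    "save_config",
    "read_metadata",
]

META_COLUMNS = ["id", "group", "age", "sex", "riluzole", "missing_mri"]


def _meta_path(h5_path: Path) -> Path:
    return h5_path.with_suffix(".metadata.csv")


def write_cohort(
    path: str | Path,
    cohort: list[ParcelTimeSeries],
    metadata: pd.DataFrame,
    alpha_true: dict | None = None,
) -> None:
    """Write a cohort HDF5 plus its metadata CSV."""
    path = Path(path)
    _validate_metadata(cohort, metadata)
    with h5py.File(path, "w") as f:
        grp = f.create_group("subjects")
        for ts in cohort:
            g = grp.create_group(ts.subject_id)
            d = g.create_dataset("timeseries", data=ts.data)
            d.attrs["fs"] = ts.fs
            d.attrs["group"] = ts.group
            if alpha_true and ts.subject_id in alpha_true:
                g.create_dataset("alpha_true", data=np.asarray(alpha_true[ts.subject_id]))
    metadata[META_COLUMNS].to_csv(_meta_path(path), index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing column(s): {sorted(missing)}")
    return meta


def read_cohort(
    path: str | Path,
) -> tuple[list[ParcelTimeSeries], pd.DataFrame, dict]:
    """Read a cohort HDF5; returns (cohort, metadata, alpha_true)."""
    path = Path(path)
    meta = read_metadata(_meta_path(path))
    by_id = meta.set_index("id")
    cohort, alpha_true = [], {}
    with h5py.File(path, "r") as f:
        ids = list(f["subjects"])
        for sid in sorted(ids):
            if sid not in by_id.index:
                raise ValueError(f"subject {sid!r} missing from the metadata table")
            g = f["subjects"][sid]
            data = np.asarray(g["timeseries"])
            fs = float(g["timeseries"].attrs["fs"])
            row = by_id.loc[sid]
            ts = ParcelTimeSeries(
                data=data,
                fs=fs,
                subject_id=sid,
                group=str(row["group"]),
                confounds={
                    "age": float(row["age"]),
                    "sex": int(row["sex"]),
                    "riluzole": int(row["riluzole"]),
                    "missing_mri": int(row["missing_mri"]),
                },
            )
            cohort.append(ts)
            if "alpha_true" in g:
                alpha_true[sid] = np.asarray(g["alpha_true"])
    _validate_cohort(cohort, meta)
    return cohort, meta, alpha_true


def write_cohort_text(
    directory: str | Path, cohort: list[ParcelTimeSeries], metadata: pd.DataFrame
) -> None:
    """Delimited-text dialect: one TSV per subject plus metadata.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _validate_metadata(cohort, metadata)
    for ts in cohort:
        header = f"fs={ts.fs!r} group={ts.group}"
        np.savetxt(
            directory / f"{ts.subject_id}.tsv", ts.data, delimiter="\t", header=header
        )
    metadata[META_COLUMNS].to_csv(directory / "metadata.csv", index=False)


def read_cohort_text(
    directory: str | Path,
) -> tuple[list[ParcelTimeSeries], pd.DataFrame]:
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.csv")
    cohort = []
    for _, row in meta.sort_values("id").iterrows():
        f = directory / f"{row['id']}.tsv"
        if not f.exists():
            raise ValueError(f"time-series file missing for subject {row['id']!r}")
        with open(f) as fh:
            first = fh.readline()
        fs = float(first.split("fs=")[1].split()[0])
        data = np.loadtxt(f, delimiter="\t")
        cohort.append(
            ParcelTimeSeries(
                data=data,
                fs=fs,
                subject_id=str(row["id"]),
                group=str(row["group"]),
                confounds={
                    "age": float(row["age"]),
                    "sex": int(row["sex"]),
                    "riluzole": int(row["riluzole"]),
                    "missing_mri": int(row["missing_mri"]),
                },
            )
        )
    _validate_cohort(cohort, meta)
    return cohort, meta


def _validate_metadata(cohort: list[ParcelTimeSeries], metadata: pd.DataFrame) -> None:
    ids = {ts.subject_id for ts in cohort}
    missing = ids - set(metadata["id"])
    if missing:
        raise ValueError(f"metadata rows missing for subject(s): {sorted(missing)}")


def _validate_cohort(cohort: list[ParcelTimeSeries], meta: pd.DataFrame) -> None:
    if not cohort:
        raise ValueError("empty cohort")
    P = cohort[0].n_parcels
    fs = cohort[0].fs
    for ts in cohort:
        if ts.n_parcels != P:
            raise ValueError(f"subject {ts.subject_id!r} has {ts.n_parcels} parcels, expected {P}")
        if ts.fs != fs:
            raise ValueError(f"subject {ts.subject_id!r} has fs={ts.fs}, expected {fs}")
    extra = set(meta["id"]) - {ts.subject_id for ts in cohort}
    if extra:
        raise ValueError(f"metadata rows without time series: {sorted(extra)}")


def save_config(path: str | Path, config: CohortConfig) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(config), f)


def load_config(path: str | Path) -> CohortConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} is empty or not a mapping")
    return config_from_dict(d)
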