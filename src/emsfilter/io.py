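"""On-disk formats: the HDF5 epochs container, results serialization and
CSV trial-table import.

Container layout (schema version 1)::

    /epochs/data            float64, channel x sample x trial
    /epochs/times           float64, seconds
    /epochs/labels          int, per trial
    /epochs/channel_names   UTF-8 strings
    /epochs/channel_groups  int, per channel
    /covariates/<name>      float64 per trial (NaN = missing), optional
    attrs: schema_version, sample_rate_hz, unit_group_<gid>

Round-tripping a dataset reproduces the arrays bit-exactly (64-bit
floats throughout).
"""

from __future__ import annotations

import json
from importlib.metadata import version as _pkg_version
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import EMSError, EpochedDataset, validate_dataset
from .core import SpatialFilterSet, SurrogateMatrix

SCHEMA_VERSION = 1

__all__ = [
    "read_epochs",
    "write_epochs",
    "write_results",
    "read_results",
    "read_trial_table",
    "validate_report",
]


def write_epochs(path, ds: EpochedDataset, overwrite: bool = False) -> None:
    """Write an :class:`EpochedDataset` to the HDF5 epochs container."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise EMSError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=ds.data.astype(np.float64))
        g.create_dataset("times", data=ds.times.astype(np.float64))
        g.create_dataset("labels", data=ds.labels.astype(np.int64))
        g.create_dataset(
            "channel_names",
            data=np.array(ds.channel_names, dtype=h5py.string_dtype("utf-8")),
        )
        g.create_dataset("channel_groups", data=ds.channel_groups.astype(np.int64))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sample_rate_hz"] = ds.sfreq if ds.n_samples > 1 else 0.0
        for gid, unit in ds.units.items():
            f.attrs[f"unit_group_{gid}"] = unit
        if ds.covariates:
            c = f.create_group("covariates")
            for name, vec in ds.covariates.items():
                c.create_dataset(name, data=vec.astype(np.float64))


def read_epochs(path) -> EpochedDataset:
    """Read and validate an epochs container; raises listing every
    validation violation if the stored dataset is malformed."""
    path = Path(path)
    if not path.exists():
        raise EMSError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        sv = f.attrs.get("schema_version")
        if sv is None:
            raise EMSError("missing attribute 'schema_version'")
        if int(sv) > SCHEMA_VERSION:
            raise EMSError(f"unsupported schema_version {sv}")
        if "epochs" not in f:
            raise EMSError("missing group 'epochs'")
        g = f["epochs"]
        for name in ("data", "times", "labels", "channel_names", "channel_groups"):
            if name not in g:
                raise EMSError(f"missing dataset 'epochs/{name}'")
        units = {}
        for key, val in f.attrs.items():
            if key.startswith("unit_group_"):
                units[int(key.removeprefix("unit_group_"))] = str(val)
        covariates = {}
        if "covariates" in f:
            covariates = {k: np.asarray(v) for k, v in f["covariates"].items()}
        ds = EpochedDataset(
            data=np.asarray(g["data"]),
            times=np.asarray(g["times"]),
            labels=np.asarray(g["labels"]),
            channel_names=[s.decode() if isinstance(s, bytes) else str(s)
                           for s in g["channel_names"][()]],
            channel_groups=np.asarray(g["channel_groups"]),
            covariates=covariates,
            units=units,
        )
    problems = validate_dataset(ds)
    if problems:
        raise EMSError("invalid epochs container: " + "; ".join(problems))
    return ds


def _provenance(extra: dict | None) -> dict:
    try:
        pkg = _pkg_version("emsfilter")
    except Exception:
        pkg = "unknown"
    prov = {"package_version": pkg}
    if extra:
        prov.update(extra)
    return prov


def write_results(
    path,
    surrogates: SurrogateMatrix | None = None,
    filters: SpatialFilterSet | None = None,
    reports: dict | None = None,
    provenance: dict | None = None,
    overwrite: bool = False,
) -> None:
    """Append surrogates/filters under ``/results`` of an HDF5 file and
    emit scalar reports as JSON next to it (``<path>.json``)."""
    path = Path(path)
    mode = "a" if path.exists() else "w"
    prov = _provenance(provenance)
    with h5py.File(path, mode) as f:
        if "results" in f:
            if not overwrite:
                raise EMSError(
                    f"{path} already holds results; pass overwrite=True"
                )
            del f["results"]
        r = f.create_group("results")
        for key, val in prov.items():
            if val is None:
                continue
            r.attrs[key] = json.dumps(val) if isinstance(val, (dict, list)) else val
        if surrogates is not None:
            g = r.create_group("surrogates")
            g.create_dataset("values", data=surrogates.values)
            g.create_dataset("labels", data=surrogates.labels)
            g.create_dataset("degenerate", data=surrogates.degenerate)
            if surrogates.times is not None:
                g.create_dataset("times", data=surrogates.times)
        if filters is not None:
            g = r.create_group("filters")
            g.create_dataset("filters", data=filters.filters)
            g.create_dataset("degenerate", data=filters.degenerate)
            g.attrs["scheme"] = filters.scheme
            g.attrs["normalized"] = filters.normalized
            fold_sizes = np.array([len(fd) for fd in filters.folds])
            g.create_dataset("fold_sizes", data=fold_sizes)
            g.create_dataset(
                "fold_trials", data=np.concatenate(filters.folds) if filters.folds
                else np.array([], dtype=int),
            )
    if reports is not None:
        report = {"provenance": prov, "reports": reports}
        json_path = path.with_suffix(path.suffix + ".json")
        json_path.write_text(json.dumps(report, indent=2))


def read_results(path) -> dict:
    """Read back the ``/results`` group written by :func:`write_results`."""
    out: dict = {}
    with h5py.File(Path(path), "r") as f:
        if "results" not in f:
            raise EMSError("file holds no results group")
        r = f["results"]
        out["provenance"] = {k: r.attrs[k] for k in r.attrs}
        if "surrogates" in r:
            g = r["surrogates"]
            out["surrogates"] = SurrogateMatrix(
                values=np.asarray(g["values"]),
                labels=np.asarray(g["labels"]),
                degenerate=np.asarray(g["degenerate"]).astype(bool),
                times=np.asarray(g["times"]) if "times" in g else None,
            )
        if "filters" in r:
            g = r["filters"]
            sizes = np.asarray(g["fold_sizes"])
            flat = np.asarray(g["fold_trials"])
            folds = np.split(flat, np.cumsum(sizes)[:-1]) if sizes.size else []
            out["filters"] = SpatialFilterSet(
                filters=np.asarray(g["filters"]),
                folds=[np.asarray(fd) for fd in folds],
                scheme=str(g.attrs["scheme"]),
                normalized=bool(g.attrs["normalized"]),
                degenerate=np.asarray(g["degenerate"]).astype(bool),
            )
    return out


def read_trial_table(path) -> pd.DataFrame:
    """Read a per-trial CSV table (one row per trial, header required).

    A ``label`` column provides condition ids; any other numeric column
    is a covariate (empty cells become NaN).
    """
    df = pd.read_csv(path)
    if df.shape[1] == 0:
        raise EMSError("trial table has no columns; a header row is required")
    return df


#: minimal schema for JSON report files (checked by validate_report)
REPORT_SCHEMA = {
    "required": ["provenance", "reports"],
    "provenance_required": ["package_version"],
}


def validate_report(report: dict) -> list[str]:
    """Check a JSON report object against the shipped schema; returns a
    list of violations (empty = valid)."""
    problems = []
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            problems.append(f"missing key '{key}'")
    for key in REPORT_SCHEMA["provenance_required"]:
        if key not in report.get("provenance", {}):
            problems.append(f"missing provenance key '{key}'")
    if "reports" in report and not isinstance(report["reports"], dict):
        problems.append("'reports' must be an object")
    return problems
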