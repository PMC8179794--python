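"""Readers and writers for the package's plain-text interchange formats.

All tabular data travel as CSV; parameter sets and stimulation protocols as
flat-key YAML; tensors as a directory of labeled CSV slices with a JSON axis
manifest.  Readers validate eagerly and report the offending row or field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .inference import FitDataset
from .network import (
    RECEPTORS,
    RateTable,
    TraffickingParams,
    default_rate_table,
    enforce_detailed_balance,
)
from .simulate import CellProfile, StimulusProtocol, Trajectory

__all__ = [
    "read_receptor_table",
    "write_receptor_table",
    "read_response_table",
    "write_response_table",
    "load_params",
    "save_params",
    "load_protocol",
    "write_trajectory",
    "write_tensor",
    "read_tensor",
    "write_cp_factors",
]

_TRAFFIC_FIELDS = ("k_endo", "k_endo_active", "f_sort", "k_rec", "k_deg", "phi", "v_endo_fL")

_RESPONSE_COLUMNS = ["cell_type", "ligand", "concentration_nM", "time_min",
                     "readout", "value", "replicate"]


def read_receptor_table(path) -> list:
    """Read cell-type receptor abundances (columns cell_type,receptor,count[,sem])."""
    df = pd.read_csv(path)
    required = {"cell_type", "receptor", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    profiles = {}
    for k, row in df.iterrows():
        rownum = k + 2  # 1-based, after the header line
        rec = str(row["receptor"])
        if rec not in RECEPTORS:
            raise ValueError(f"{path}: row {rownum}: unknown receptor {rec!r}")
        count = float(row["count"])
        if not np.isfinite(count) or count < 0:
            raise ValueError(f"{path}: row {rownum}: negative or non-finite count {count}")
        profiles.setdefault(str(row["cell_type"]), {})[rec] = count
    return [CellProfile(name, receptor_surface=surf) for name, surf in profiles.items()]


def write_receptor_table(profiles, path) -> None:
    rows = []
    for p in profiles:
        table = p.receptor_surface or p.receptor_synthesis
        for rec, count in table.items():
            rows.append({"cell_type": p.name, "receptor": rec, "count": count})
    pd.DataFrame(rows, columns=["cell_type", "receptor", "count"]).to_csv(path, index=False)


def read_response_table(path, profiles=None, scale_group: str = "pSTAT") -> list:
    """Read dose-response measurements into one FitDataset per cell type.

    ``profiles`` maps cell-type name -> CellProfile; without it, profiles are
    placeholder-empty and must be attached before fitting.  Duplicate
    (cell_type, ligand, concentration, time, replicate) rows are rejected.
    """
    df = pd.read_csv(path)
    missing = set(_RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    key_cols = ["cell_type", "ligand", "concentration_nM", "time_min", "readout", "replicate"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicate observation row at line {first}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        bad = int(np.flatnonzero(~np.isfinite(df["value"].to_numpy(dtype=float)))[0]) + 2
        raise ValueError(f"{path}: non-finite value at line {bad}")
    datasets = []
    for cell, sub in df.groupby("cell_type", sort=True):
        profile = (profiles or {}).get(str(cell), CellProfile(str(cell)))
        datasets.append(FitDataset(
            name=str(cell), profile=profile,
            data=sub.drop(columns=["cell_type"]).reset_index(drop=True),
            scale_group=scale_group,
        ))
    return datasets


def write_response_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_RESPONSE_COLUMNS)


def save_params(path, rates: RateTable, traffic: TraffickingParams) -> None:
    """Flat-key YAML with every rate constant and trafficking parameter."""
    doc = {k: float(v) for k, v in sorted(rates.values.items())}
    doc.update({k: float(getattr(traffic, k)) for k in _TRAFFIC_FIELDS})
    doc["fitted"] = sorted(rates.fitted)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path) -> tuple:
    """Read (RateTable, TraffickingParams); unknown keys are rejected.

    Missing rate keys fall back to the package defaults, so a config may
    override only a subset; detailed balance is re-enforced on load.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    fitted = set(doc.pop("fitted", []))
    base = default_rate_table()
    rate_updates, traffic_kwargs = {}, {}
    for key, val in doc.items():
        if key in _TRAFFIC_FIELDS:
            traffic_kwargs[key] = float(val)
        elif key in base.values:
            rate_updates[key] = float(val)
        else:
            raise ValueError(f"{path}: unknown parameter key {key!r}")
    rates = enforce_detailed_balance(base.with_updates(**rate_updates))
    if fitted:
        rates = RateTable(values=rates.values, fitted=frozenset(fitted))
    return rates, TraffickingParams(**traffic_kwargs)


def load_protocol(path) -> StimulusProtocol:
    """YAML protocol: list of events plus an output time grid (minutes)."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        events = [(str(e["ligand"]), float(e["concentration_nM"]), float(e.get("onset_min", 0.0)))
                  for e in doc["events"]]
        t_grid = np.asarray(doc["t_grid"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed protocol ({exc})") from exc
    return StimulusProtocol(events=events, t_grid=t_grid)


def write_trajectory(traj: Trajectory, path) -> None:
    """Tidy CSV: time_min, compartment, species, abundance."""
    n = traj.network.n_comp_species
    rows = []
    for k, t in enumerate(traj.times):
        y = traj.states[k]
        for j, s in enumerate(traj.network.species):
            rows.append({"time_min": t, "compartment": "surf", "species": s, "abundance": y[j]})
            rows.append({"time_min": t, "compartment": "endo", "species": s, "abundance": y[n + j]})
        for j, lig in enumerate(traj.network.ligands):
            rows.append({"time_min": t, "compartment": "endo", "species": lig,
                         "abundance": y[2 * n + j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_tensor(da: xr.DataArray, directory) -> None:
    """Directory of per-slice CSVs (first axis) plus a JSON axis manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dims = list(da.dims)
    manifest = {
        "dims": dims,
        "coords": {d: [_json_safe(v) for v in da.coords[d].values] for d in dims if d in da.coords},
        "shape": list(da.shape),
        "name": da.name or "tensor",
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for k in range(da.shape[0]):
        pd.DataFrame(np.asarray(da[k].values)).to_csv(directory / f"slice_{k:03d}.csv",
                                                      index=False, header=False)


def read_tensor(directory) -> xr.DataArray:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    slices = [
        pd.read_csv(directory / f"slice_{k:03d}.csv", header=None).to_numpy(dtype=float)
        for k in range(manifest["shape"][0])
    ]
    arr = np.stack(slices)
    expected = tuple(manifest["shape"])
    if arr.shape != expected:
        raise ValueError(f"{directory}: slice shapes {arr.shape} do not match manifest {expected}")
    return xr.DataArray(arr, dims=manifest["dims"],
                        coords={d: v for d, v in manifest.get("coords", {}).items()},
                        name=manifest.get("name"))


def write_cp_factors(cp, directory) -> None:
    """One CSV per mode with component columns, plus a JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for dim, frame in zip(cp.dims, cp.factor_frames()):
        frame.to_csv(directory / f"factor_{dim}.csv", index=False)
    (directory / "decomposition.json").write_text(json.dumps({
        "rank": cp.rank, "r2x": cp.r2x, "seed": cp.seed,
        "n_restarts": cp.n_restarts, "n_iter": cp.n_iter,
    }, indent=1))


def _json_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return str(v) if not isinstance(v, (int, float, str, bool)) else v
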