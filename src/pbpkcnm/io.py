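"""Readers and writers for the tabular study dialect.

A study directory holds three UTF-8, comma-separated, '.'-decimal CSVs:

* ``patients.csv`` — one row per patient: demographics, dose, and the
  per-kg organ volumes (``v_<organ>``) and blood flows (``q_<organ>``).
* ``objectives.csv`` — one row per patient: the 13 objective entries in
  canonical order (five urinary ratios, four fecal ratios, four Cmax).
* ``bounds.csv`` — 105 rows ``id,name,unit,min,max`` giving the estimation
  range of every drug parameter.

The packaged fixtures under ``pbpkcnm/data`` reproduce the source cohort
(seven colorectal-cancer patients) verbatim and are the default study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cnm import Cluster, CNMConfig
from .model import OBSERVABLE_NAMES
from .parameters import N_PARAMS, PARAM_NAMES, BoundBox
from .physiology import build_physiology
from .pipeline import StudyInputs

__all__ = [
    "load_study",
    "load_packaged_study",
    "write_study",
    "write_cluster",
    "read_cluster",
    "RunManifest",
]


class SchemaError(ValueError):
    """A study file violates the expected layout."""


def _read_patients(tab: pd.DataFrame, path: str):
    patients = []
    for row_no, rec in enumerate(tab.to_dict(orient="records")):
        try:
            patients.append(build_physiology(rec))
        except ValueError as exc:
            raise SchemaError(f"{path}, row {row_no + 1}: {exc}") from exc
    return patients


def _read_objectives(tab: pd.DataFrame, path: str) -> pd.DataFrame:
    expected = ["patient_id", *OBSERVABLE_NAMES]
    if list(tab.columns) != expected:
        raise SchemaError(
            f"{path}: columns must be exactly {expected}, got {list(tab.columns)}"
        )
    for col in OBSERVABLE_NAMES:
        bad = tab.index[~(tab[col] > 0)]
        if len(bad):
            raise SchemaError(f"{path}, row {bad[0] + 1}, column {col}: "
                              "objective entries must be positive")
    return tab


def _read_bounds(tab: pd.DataFrame, path: str) -> BoundBox:
    for col in ("id", "name", "min", "max"):
        if col not in tab.columns:
            raise SchemaError(f"{path}: missing column {col}")
    if list(tab["id"]) != list(range(1, N_PARAMS + 1)):
        raise SchemaError(f"{path}: parameter IDs must run 1..{N_PARAMS}")
    try:
        return BoundBox(tab["min"].to_numpy(float), tab["max"].to_numpy(float))
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def _assemble(patients, objectives: pd.DataFrame, bounds: BoundBox,
              path: str) -> StudyInputs:
    by_id = {str(r["patient_id"]): [r[c] for c in OBSERVABLE_NAMES]
             for r in objectives.to_dict(orient="records")}
    rows = []
    for p in patients:
        if str(p.patient_id) not in by_id:
            raise SchemaError(f"{path}: no objective row for patient {p.patient_id}")
        rows.append(by_id[str(p.patient_id)])
    return StudyInputs(patients=patients, objectives=np.asarray(rows, float),
                       bounds=bounds)


def load_study(directory: str | Path) -> StudyInputs:
    """Load and validate a study directory into :class:`StudyInputs`."""
    directory = Path(directory)
    frames = {}
    for name in ("patients", "objectives", "bounds"):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing study file: {path}")
        frames[name] = pd.read_csv(path)
    patients = _read_patients(frames["patients"], str(directory / "patients.csv"))
    objectives = _read_objectives(frames["objectives"],
                                  str(directory / "objectives.csv"))
    bounds = _read_bounds(frames["bounds"], str(directory / "bounds.csv"))
    return _assemble(patients, objectives, bounds, str(directory))


def load_packaged_study() -> StudyInputs:
    """The packaged seven-patient cohort (physiology, objectives, bounds)."""
    root = resources.files("pbpkcnm.data")
    frames = {}
    for name in ("patients", "objectives", "bounds"):
        with root.joinpath(f"{name}.csv").open() as fh:
            frames[name] = pd.read_csv(fh)
    patients = _read_patients(frames["patients"], "patients.csv")
    objectives = _read_objectives(frames["objectives"], "objectives.csv")
    bounds = _read_bounds(frames["bounds"], "bounds.csv")
    return _assemble(patients, objectives, bounds, "packaged data")


def write_study(inputs: StudyInputs, directory: str | Path) -> None:
    """Write a study directory in the dialect read by :func:`load_study`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    recs = []
    for p in inputs.patients:
        rec = {
            "patient_id": p.patient_id, "sex": p.sex, "age": p.age,
            "height_cm": p.height, "weight_kg": p.weight,
            "bmi": round(p.bmi, 1),
            "dose_ug_per_kg": p.dose, "infusion_min": p.infusion_duration,
        }
        rec.update({f"v_{k}": v for k, v in p.volume.items()})
        rec.update({f"q_{k}": v for k, v in p.flow.items()})
        recs.append(rec)
    pd.DataFrame.from_records(recs).to_csv(directory / "patients.csv", index=False)
    obj = pd.DataFrame(inputs.objectives, columns=list(OBSERVABLE_NAMES))
    obj.insert(0, "patient_id", [p.patient_id for p in inputs.patients])
    obj.to_csv(directory / "objectives.csv", index=False)
    pd.DataFrame({
        "id": np.arange(1, N_PARAMS + 1), "name": PARAM_NAMES,
        "unit": "", "min": inputs.bounds.lower, "max": inputs.bounds.upper,
    }).to_csv(directory / "bounds.csv", index=False)


def write_cluster(cluster: Cluster, path: str | Path) -> None:
    """Dump a cluster to CSV: 105 parameter columns (canonical names) plus
    ``ssr`` and ``status``; full float precision round-trips."""
    tab = pd.DataFrame(cluster.points, columns=list(PARAM_NAMES))
    tab["ssr"] = cluster.ssr
    tab["status"] = np.where(cluster.ok, "ok", "failed")
    tab.to_csv(path, index=False, float_format="%.17g")


def read_cluster(path: str | Path) -> Cluster:
    """Read a cluster CSV written by :func:`write_cluster`."""
    tab = pd.read_csv(path, float_precision="round_trip")
    expected = [*PARAM_NAMES, "ssr", "status"]
    if list(tab.columns) != expected:
        raise SchemaError(f"{path}: corrupted cluster header")
    ok = (tab["status"] == "ok").to_numpy()
    ssr = tab["ssr"].to_numpy(float)
    ssr[~ok] = np.inf
    return Cluster(
        points=tab[list(PARAM_NAMES)].to_numpy(float),
        observables=np.zeros((len(tab), 13)),
        ssr=ssr,
        ok=ok,
    )


@dataclasses.dataclass
class RunManifest:
    """Reproducibility sidecar written at the end of a CLI run."""

    seed: int
    config: dict
    package_version: str
    outputs: dict[str, str]
    wall_time_s: float

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["config_hash"] = self.config_hash
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(payload, indent=2, sort_keys=True))
        tmp.replace(path)  # atomic on POSIX


def manifest_for(config: CNMConfig, seed: int, outputs: Mapping[str, Path],
                 t_start: float) -> RunManifest:
    from . import __version__

    return RunManifest(
        seed=seed,
        config=dataclasses.asdict(config),
        package_version=__version__,
        outputs={k: str(v) for k, v in outputs.items()},
        wall_time_s=round(time.time() - t_start, 3),
    )
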