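"""Readers and writers for measurement tables, coefficient and factor files.

A cycle study is stored as a directory bundle: ``measurements.csv`` (columns
``region, time_h, cps, volume_cc, sensitivity``), an optional ``blood.csv``
(``time_h, conc`` in MBq/cc) and ``study.json`` with the cycle metadata.
All delimited text is comma-separated, '.' decimal, UTF-8, header row
mandatory.  Coefficient and dose-factor files are JSON; floats are written
with full ``repr`` precision so read/write round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    BloodSample,
    CycleDoseRecord,
    CycleStudy,
    DoseFactorTable,
    MLRCoefficients,
    VOIMeasurement,
)
from .errors import DataValidationError, TableParseError

MEASUREMENT_COLUMNS = ["region", "time_h", "cps", "volume_cc", "sensitivity"]
BLOOD_COLUMNS = ["time_h", "conc"]

_MEAS_FILE = "measurements.csv"
_BLOOD_FILE = "blood.csv"
_META_FILE = "study.json"


def _check_columns(df: pd.DataFrame, expected: list[str], path: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise TableParseError(f"missing column(s) {missing}", path=path)


def read_cycle_study(path: str | Path) -> CycleStudy:
    """Read a cycle-study bundle directory back into a validated CycleStudy.

    Raises :class:`TableParseError` naming the offending file/row on any
    schema or invariant violation.
    """
    path = Path(path)
    meta_path = path / _META_FILE
    if not meta_path.exists():
        raise TableParseError("study bundle is missing study.json", path=str(path))
    meta = json.loads(meta_path.read_text())

    meas_path = path / _MEAS_FILE
    try:
        # round_trip float parsing: file <-> memory must be the identity
        df = pd.read_csv(meas_path, float_precision="round_trip")
    except FileNotFoundError:
        raise TableParseError("study bundle is missing measurements.csv",
                              path=str(path)) from None
    _check_columns(df, MEASUREMENT_COLUMNS, str(meas_path))

    seen: set[tuple[str, float]] = set()
    measurements = []
    for idx, row in df.iterrows():
        key = (str(row["region"]), float(row["time_h"]))
        if key in seen:
            raise TableParseError(
                f"duplicate (region, time) pair {key}", path=str(meas_path), row=idx)
        seen.add(key)
        try:
            measurements.append(VOIMeasurement(
                region_id=str(row["region"]),
                time_h=float(row["time_h"]),
                count_rate_cps=float(row["cps"]),
                volume_cc=float(row["volume_cc"]),
                sensitivity_MBq_per_cps=float(row["sensitivity"]),
            ))
        except (DataValidationError, ValueError) as exc:
            raise TableParseError(str(exc), path=str(meas_path), row=idx) from exc

    blood_samples = []
    blood_path = path / _BLOOD_FILE
    if blood_path.exists():
        bdf = pd.read_csv(blood_path, float_precision="round_trip")
        _check_columns(bdf, BLOOD_COLUMNS, str(blood_path))
        for idx, row in bdf.iterrows():
            try:
                blood_samples.append(BloodSample(
                    time_h=float(row["time_h"]),
                    concentration_MBq_per_cc=float(row["conc"]),
                ))
            except (DataValidationError, ValueError) as exc:
                raise TableParseError(str(exc), path=str(blood_path), row=idx) from exc

    try:
        return CycleStudy(
            patient_id=str(meta["patient_id"]),
            cycle_index=int(meta["cycle_index"]),
            injected_activity_MBq=float(meta["injected_activity_MBq"]),
            phantom=str(meta["phantom"]),
            measurements=tuple(measurements),
            blood_samples=tuple(blood_samples),
        )
    except DataValidationError as exc:
        raise TableParseError(str(exc), path=str(path)) from exc


def write_cycle_study(study: CycleStudy, path: str | Path) -> Path:
    """Write a CycleStudy as a directory bundle; returns the bundle path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = [
        {"region": m.region_id, "time_h": repr(m.time_h), "cps": repr(m.count_rate_cps),
         "volume_cc": repr(m.volume_cc), "sensitivity": repr(m.sensitivity_MBq_per_cps)}
        for m in study.measurements
    ]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(
        path / _MEAS_FILE, index=False)
    brows = [{"time_h": repr(b.time_h), "conc": repr(b.concentration_MBq_per_cc)}
             for b in study.blood_samples]
    pd.DataFrame(brows, columns=BLOOD_COLUMNS).to_csv(path / _BLOOD_FILE, index=False)
    meta = {
        "patient_id": study.patient_id,
        "cycle_index": study.cycle_index,
        "injected_activity_MBq": study.injected_activity_MBq,
        "phantom": study.phantom,
    }
    (path / _META_FILE).write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# Coefficient files

def _coefficients_from_dict(target: str, label: str, entry: dict,
                            conc_units: str) -> MLRCoefficients:
    kind = entry.get("kind", "marrow" if "beta0" in entry else "solid")
    prefix = "alpha" if kind == "solid" else "beta"
    vals = {}
    for i in range(3):
        key = f"{prefix}{i}"
        if key not in entry:
            raise TableParseError(
                f"coefficient set for target {target!r} @ {label!r} is missing {key!r}")
        vals[i] = float(entry[key])
    theta_bb = entry.get("theta_bm_bm")
    theta_rm = entry.get("theta_bm_rm")
    if kind == "marrow" and (theta_bb is None or theta_rm is None):
        raise TableParseError(
            f"marrow coefficient set for target {target!r} @ {label!r} "
            "is missing theta_bm_bm/theta_bm_rm")
    try:
        return MLRCoefficients(
            target=target, t_f_label=label, kind=kind,
            intercept=vals[0], slope_conc=vals[1], slope_time=vals[2],
            theta_bm_bm=None if theta_bb is None else float(theta_bb),
            theta_bm_rm=None if theta_rm is None else float(theta_rm),
            r2_train=entry.get("r2_train"), n_train=entry.get("n_train"),
            conc_units=conc_units,
        )
    except DataValidationError as exc:
        raise TableParseError(
            f"invalid coefficient set for target {target!r} @ {label!r}: {exc}"
        ) from exc


def read_coefficients(path: str | Path) -> dict[str, dict[str, MLRCoefficients]]:
    """Read a coefficient file: ``{target: {t_f_label: MLRCoefficients}}``."""
    path = Path(path)
    payload = json.loads(path.read_text())
    conc_units = payload.get("unit_contract", "mCi/cc")
    out: dict[str, dict[str, MLRCoefficients]] = {}
    for target, by_label in payload["targets"].items():
        out[target] = {
            label: _coefficients_from_dict(target, label, entry, conc_units)
            for label, entry in by_label.items()
        }
    return out


def write_coefficients(coeffs: dict[str, dict[str, MLRCoefficients]],
                       path: str | Path,
                       description: str = "trained regression coefficients") -> Path:
    path = Path(path)
    targets: dict[str, dict] = {}
    for target, by_label in coeffs.items():
        targets[target] = {}
        for label, c in by_label.items():
            prefix = "alpha" if c.kind == "solid" else "beta"
            entry: dict = {
                "kind": c.kind,
                f"{prefix}0": c.intercept,
                f"{prefix}1": c.slope_conc,
                f"{prefix}2": c.slope_time,
            }
            if c.theta_bm_bm is not None:
                entry["theta_bm_bm"] = c.theta_bm_bm
                entry["theta_bm_rm"] = c.theta_bm_rm
            if c.r2_train is not None:
                entry["r2_train"] = c.r2_train
            if c.n_train is not None:
                entry["n_train"] = c.n_train
            targets[target][label] = entry
    payload = {"description": description, "unit_contract": "mCi/cc",
               "targets": targets}
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# Dose-factor and sphere tables

def _dose_factor_table_from_dict(phantom: str, entry: dict) -> DoseFactorTable:
    entries = {(d["source"], d["target"]): float(d["DF"])
               for d in entry.get("dose_factors", [])}
    return DoseFactorTable(
        phantom=phantom,
        entries=entries,
        theta_bm_bm=float(entry["theta_bm_bm"]),
        theta_bm_rm=float(entry["theta_bm_rm"]),
        organ_self_theta={k: float(v)
                          for k, v in entry.get("organ_self_theta", {}).items()},
        organ_masses_kg={k: float(v)
                         for k, v in entry.get("organ_masses_kg", {}).items()},
    )


def read_dose_factors(path: str | Path, phantom: str = "adult_male") -> DoseFactorTable:
    payload = json.loads(Path(path).read_text())
    try:
        entry = payload["phantoms"][phantom]
    except KeyError:
        raise TableParseError(f"no phantom {phantom!r} in dose-factor file",
                              path=str(path)) from None
    return _dose_factor_table_from_dict(phantom, entry)


def _packaged(name: str) -> str:
    return resources.files("prrtdose.data").joinpath(name).read_text()


def load_packaged_dose_factors(phantom: str = "adult_male") -> DoseFactorTable:
    """The packaged synthetic dose-factor table (see its description field)."""
    payload = json.loads(_packaged("dose_factors_synthetic.json"))
    return _dose_factor_table_from_dict(phantom, payload["phantoms"][phantom])


def load_packaged_coefficients() -> dict[str, dict[str, MLRCoefficients]]:
    """The packaged published coefficient sets, by target and t_f label."""
    payload = json.loads(_packaged("mlr_coefficients_published.json"))
    out: dict[str, dict[str, MLRCoefficients]] = {}
    conc_units = payload.get("unit_contract", "mCi/cc")
    for target, by_label in payload["targets"].items():
        out[target] = {
            label: _coefficients_from_dict(target, label, entry, conc_units)
            for label, entry in by_label.items()
        }
    return out


def load_packaged_sphere_theta():
    """Packaged synthetic sphere self-coupling table -> SphereThetaTable."""
    from .standard import SphereThetaTable

    payload = json.loads(_packaged("sphere_theta_synthetic.json"))
    return SphereThetaTable(np.asarray(payload["mass_kg"], dtype=float),
                            np.asarray(payload["theta"], dtype=float))


def read_sphere_theta(path: str | Path):
    from .standard import SphereThetaTable

    payload = json.loads(Path(path).read_text())
    return SphereThetaTable(np.asarray(payload["mass_kg"], dtype=float),
                            np.asarray(payload["theta"], dtype=float))


# ---------------------------------------------------------------------------
# Dose records

def write_dose_records(records: list[CycleDoseRecord], path: str | Path) -> Path:
    path = Path(path)
    payload = [dataclasses.asdict(r) for r in records]
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_dose_records(path: str | Path) -> list[CycleDoseRecord]:
    payload = json.loads(Path(path).read_text())
    return [CycleDoseRecord(patient_id=str(r["patient_id"]),
                            cycle_index=int(r["cycle_index"]),
                            doses_mGy={k: float(v) for k, v in r["doses_mGy"].items()},
                            protocol=str(r["protocol"]))
            for r in payload]
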