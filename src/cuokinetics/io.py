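"""CSV curve tables, configuration files and result records.

The on-disk dialect matches the lab-facing units of the dissolution
figures: hours and mM for the curves, nm and ug/mL for the particles.
Everything is converted to strict SI at the boundary (1 mM == 1 mol
m^-3; 1 ug/mL == 1e-3 kg m^-3).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .particles import CUO_DENSITY, CUO_MOLAR_MASS, MediumSpec, ParticleSystem
from .pure import ReleaseCurve

__all__ = [
    "CURVE_COLUMNS",
    "SchemaError",
    "read_curves",
    "write_curves",
    "particle_from_condition",
    "medium_from_condition",
    "load_config",
    "write_result_json",
]

CURVE_COLUMNS = [
    "time_h",
    "cu_mM",
    "condition",
    "amino_acid",
    "f_fe0_pct",
    "d0_nm",
    "mass_conc_ug_ml",
    "c_aa0_mM",
]

RESULT_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A curve table violates the CurveTable schema."""


def write_curves(curves: list[ReleaseCurve], path) -> None:
    """Write curves as one CurveTable CSV (hours / mM at the boundary)."""
    rows = []
    for curve in curves:
        cond = curve.condition
        for t, c in zip(curve.times, curve.c_cu):
            rows.append(
                {
                    "time_h": t / 3600.0,
                    "cu_mM": c,
                    "condition": curve.label,
                    "amino_acid": cond.get("amino_acid", "custom"),
                    "f_fe0_pct": 100.0 * float(cond.get("f_fe0", 0.0)),
                    "d0_nm": 1e9 * float(cond.get("d0", np.nan)),
                    "mass_conc_ug_ml": 1e3 * float(cond.get("mass_conc", np.nan)),
                    "c_aa0_mM": float(cond.get("c_aa0", np.nan)),
                }
            )
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, index=False)


def read_curves(path) -> list[ReleaseCurve]:
    """Read a CurveTable CSV into SI release curves, one per condition.

    Rows are grouped by the ``condition`` column and sorted by time
    within each group.  The parsed particle/medium metadata lands in
    each curve's ``condition`` dict (SI units).
    """
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"curve table is missing column(s): {', '.join(missing)}")
    for col in ("time_h", "cu_mM"):
        bad = np.flatnonzero(df[col].to_numpy() < 0)
        if bad.size:
            raise SchemaError(
                f"negative {col} at data row {int(bad[0]) + 1}"
            )
    curves = []
    for label, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("time_h")
        first = grp.iloc[0]
        curves.append(
            ReleaseCurve(
                times=grp["time_h"].to_numpy(dtype=float) * 3600.0,
                c_cu=grp["cu_mM"].to_numpy(dtype=float),
                condition={
                    "label": str(label),
                    "amino_acid": str(first["amino_acid"]),
                    "f_fe0": float(first["f_fe0_pct"]) / 100.0,
                    "d0": float(first["d0_nm"]) * 1e-9,
                    "mass_conc": float(first["mass_conc_ug_ml"]) * 1e-3,
                    "c_aa0": float(first["c_aa0_mM"]),
                },
            )
        )
    return curves


def particle_from_condition(cond: dict, **overrides) -> ParticleSystem:
    """Build a ParticleSystem from a curve's condition metadata."""
    kw = {
        "d0": cond.get("d0", 10e-9),
        "f_fe0": cond.get("f_fe0", 0.0),
        "mass_conc": cond.get("mass_conc", 0.0125),
        "density": cond.get("density", CUO_DENSITY),
        "molar_mass": cond.get("molar_mass", CUO_MOLAR_MASS),
    }
    kw.update(overrides)
    return ParticleSystem(**kw)


def medium_from_condition(cond: dict, **overrides) -> MediumSpec:
    kw = {
        "amino_acid": cond.get("amino_acid", "custom"),
        "c_aa0": cond.get("c_aa0", 5.0),
        "nu": cond.get("nu", 2.0),
    }
    kw.update(overrides)
    return MediumSpec(**kw)


def load_config(path) -> dict:
    """Load a JSON or YAML run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    return json.loads(text)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _to_jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj


def write_result_json(payload: dict, path, input_file=None) -> None:
    """Write a versioned, machine-readable result record.

    When ``input_file`` is given, its SHA-256 checksum is embedded for
    provenance.
    """
    record = {"schema_version": RESULT_SCHEMA_VERSION}
    if input_file is not None:
        digest = hashlib.sha256(Path(input_file).read_bytes()).hexdigest()
        record["input_file"] = str(input_file)
        record["input_sha256"] = digest
    record.update(_to_jsonable(payload))
    Path(path).write_text(json.dumps(record, indent=2) + "\n", encoding="utf-8")
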