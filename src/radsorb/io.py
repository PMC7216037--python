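"""CSV / config / report file formats.

Curve CSV dialect: columns ``time_min, fraction_sorbed_pct[, s_q_pct]``,
mandatory header, '.' decimal separator, times in minutes everywhere.
Model-prediction CSV adds the phase concentrations:
``time_min, c_mol_per_L, q_mol_per_kg, fraction_sorbed_pct``.
Configs are YAML or JSON (by extension); reports are versioned JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curve import FRACTION_PCT, KineticCurve
from .models import Trajectory

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "write_prediction_csv",
    "load_config",
    "config_hash",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


def read_curve_csv(path) -> KineticCurve:
    """Read an observed sorbed-fraction curve."""
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    if "time_min" not in cols or "fraction_sorbed_pct" not in cols:
        raise ValueError(
            f"{path}: expected columns time_min, fraction_sorbed_pct "
            f"(got {list(df.columns)})"
        )
    s_q = df[cols["s_q_pct"]].to_numpy(float) if "s_q_pct" in cols else None
    return KineticCurve(
        df[cols["time_min"]].to_numpy(float),
        df[cols["fraction_sorbed_pct"]].to_numpy(float),
        s_q=s_q,
        kind=FRACTION_PCT,
    )


def write_curve_csv(path, curve: KineticCurve) -> None:
    if curve.kind != FRACTION_PCT:
        raise ValueError("curve CSV dialect stores sorbed fractions")
    data = {"time_min": curve.times, "fraction_sorbed_pct": curve.y}
    if curve.s_q is not None:
        data["s_q_pct"] = curve.s_q
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_prediction_csv(path, traj: Trajectory) -> None:
    pd.DataFrame(
        {
            "time_min": traj.times,
            "c_mol_per_L": traj.c,
            "q_mol_per_kg": traj.q,
            "fraction_sorbed_pct": traj.fraction_pct,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def load_config(path) -> dict:
    """Load a YAML or JSON config mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable sha256 of a config mapping (for log provenance)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):  # NaN → null
        return None
    return obj


def write_report(path, report: dict) -> None:
    report = dict(report)
    report.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
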