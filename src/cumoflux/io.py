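"""Readers/writers for datasets, flux sets and reports, plus run manifests.

Canonical dialect: UTF-8 CSV with header, '.' decimal, comma separator
(TSV accepted on read).  Times are hours; fluxes mmol/L-cell/h.  Numbers
are serialized at 12 significant digits so write -> read round-trips are
lossless at working precision.  Steady-state observations carry
``time_h = ss``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import Dataset
from .network import FluxSet

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_flux_csv",
    "write_flux_csv",
    "RunManifest",
    "write_json",
]

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_dataset(path) -> Dataset:
    """Read an observation table (columns observable,time_h,value,sigma).

    ``time_h`` entries equal to 'ss' (case-insensitive) mark steady-state
    observations.  Missing columns raise a SchemaError naming them;
    non-numeric values raise with the offending line number.  Duplicate
    (observable, time) rows are retained with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    need = ["observable", "time_h", "value", "sigma"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")

    def parse_col(col, allow_ss=False):
        out = []
        for i, v in enumerate(df[col]):
            s = str(v).strip()
            if allow_ss and s.lower() in ("ss", "steady", "nan", ""):
                out.append(np.nan)
                continue
            try:
                out.append(float(s))
            except ValueError:
                raise SchemaError(
                    f"{path.name}, line {i + 2}: non-numeric {col}={s!r}"
                ) from None
        return np.array(out)

    frame = pd.DataFrame(
        {
            "observable": df["observable"].astype(str),
            "time_h": parse_col("time_h", allow_ss=True),
            "value": parse_col("value"),
            "sigma": parse_col("sigma"),
        }
    )
    dup = frame.duplicated(subset=["observable", "time_h"], keep=False)
    if dup.any():
        warnings.warn(
            f"{path.name}: {int(dup.sum())} duplicate (observable, time) rows "
            "retained",
            stacklevel=2,
        )
    meta = {}
    metapath = path.with_suffix(".meta.json")
    if metapath.exists():
        meta = json.loads(metapath.read_text())
    return Dataset(frame, meta)


def write_dataset(dataset: Dataset, path, *, write_meta: bool = True) -> Path:
    path = Path(path)
    out = dataset.frame.copy()
    out["time_h"] = [
        "ss" if np.isnan(t) else _FLOAT_FMT % t for t in out["time_h"]
    ]
    out["value"] = [_FLOAT_FMT % v for v in out["value"]]
    out["sigma"] = [_FLOAT_FMT % v for v in out["sigma"]]
    out.to_csv(path, sep=_sep_for(path), index=False)
    if write_meta and dataset.meta:
        path.with_suffix(".meta.json").write_text(
            json.dumps(_jsonable(dataset.meta), indent=2) + "\n"
        )
    return path


def read_flux_csv(path) -> FluxSet:
    """Two-column (name, net) CSV with an optional exchange column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if "name" not in df.columns or "net" not in df.columns:
        raise SchemaError(f"{path.name}: need columns name,net[,exchange]")
    fs = FluxSet()
    for _, row in df.iterrows():
        exch = float(row["exchange"]) if "exchange" in df.columns and pd.notna(row.get("exchange")) else 0.0
        fs[str(row["name"])] = (float(row["net"]), exch)
    return fs


def write_flux_csv(fluxes: FluxSet, path) -> Path:
    path = Path(path)
    rows = [
        {"name": k, "net": _FLOAT_FMT % v[0], "exchange": _FLOAT_FMT % v[1]}
        for k, v in fluxes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, allow_nan=True) + "\n")
    return path


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    seed: int | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)
    options: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path):
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        self.inputs[str(p)] = digest

    def add_output(self, path):
        self.outputs.append(str(path))

    def write(self, path) -> Path:
        return write_json(self.__dict__, path)
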