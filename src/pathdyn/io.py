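"""Readers and writers for the multiomics CSV format, manifests and configs.

File format
-----------
A strain's time series is a wide CSV with a ``strain`` column, a ``time``
column (hours, strictly increasing) and one column per species, prefixed
``met:`` for metabolites and ``prot:`` for proteins::

    strain,time,met:limonene,met:mevalonate,prot:LS
    L1,0.0,0.0,0.0,0.05
    L1,12.0,0.31,1.2,0.61

On write the species columns are ordered deterministically (metabolites
first, then proteins, each block alphabetical) and floats are serialised at
full double precision, so write -> read round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError
from .timeseries import OmicsTimeSeries

__all__ = [
    "read_omics_csv",
    "write_omics_csv",
    "DatasetManifest",
    "load_config",
]

FORMAT_VERSION = "1"


def read_omics_csv(path: str | Path, rename: dict[str, str] | None = None) -> OmicsTimeSeries:
    """Read one strain's multiomics time series from a wide CSV.

    Parameters
    ----------
    path : path
        CSV file in the ``strain,time,met:*,prot:*`` layout.
    rename : dict, optional
        Adapter map applied to raw column names before schema parsing, for
        ingesting exports whose headers do not carry the ``met:``/``prot:``
        prefixes.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if rename:
        df = df.rename(columns=rename)
    if "time" not in df.columns:
        raise SchemaError(f"{path}: missing required 'time' column")
    strain_id = "unknown"
    if "strain" in df.columns:
        ids = df["strain"].unique()
        if len(ids) != 1:
            raise SchemaError(f"{path}: expected exactly one strain per file, got {list(ids)}")
        strain_id = str(ids[0])
    met_cols, prot_cols = [], []
    for col in df.columns:
        if col in ("strain", "time"):
            continue
        if col.startswith("met:"):
            met_cols.append(col)
        elif col.startswith("prot:"):
            prot_cols.append(col)
        else:
            raise SchemaError(
                f"{path}: unknown column {col!r}; species columns must be "
                "prefixed 'met:' or 'prot:'"
            )
    times = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SchemaError(f"{path}: 'time' column must be strictly increasing")
    try:
        return OmicsTimeSeries(
            strain_id=strain_id,
            times=times,
            metabolites=df[met_cols].to_numpy(dtype=float).reshape(len(times), -1),
            proteins=df[prot_cols].to_numpy(dtype=float).reshape(len(times), -1),
            metabolite_names=tuple(c[4:] for c in met_cols),
            protein_names=tuple(c[5:] for c in prot_cols),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_omics_csv(series: OmicsTimeSeries, path: str | Path) -> Path:
    """Write a series as CSV with deterministic column order and full precision."""
    path = Path(path)
    met_order = sorted(series.metabolite_names)
    prot_order = sorted(series.protein_names)
    df = series.to_frame()
    cols = (
        ["strain", "time"]
        + [f"met:{n}" for n in met_order]
        + [f"prot:{n}" for n in prot_order]
    )
    df[cols].to_csv(path, index=False, float_format="%.17g")
    return path


@dataclass
class StrainRecord:
    strain_id: str
    path: str
    role: str = "train"  # train | test
    pathway: str = "limonene"


@dataclass
class DatasetManifest:
    """Index of a set of strain CSV files sharing species registries."""

    strains: list[StrainRecord] = field(default_factory=list)
    metabolite_names: tuple[str, ...] = ()
    protein_names: tuple[str, ...] = ()
    units: str = "arbitrary"
    format_version: str = FORMAT_VERSION

    def add(self, series: OmicsTimeSeries, path: str | Path, role: str = "train",
            pathway: str = "limonene") -> None:
        if any(r.strain_id == series.strain_id for r in self.strains):
            raise SchemaError(f"duplicate strain id {series.strain_id!r} in manifest")
        if not self.metabolite_names:
            self.metabolite_names = series.metabolite_names
            self.protein_names = series.protein_names
        elif (self.metabolite_names != series.metabolite_names
              or self.protein_names != series.protein_names):
            raise SchemaError(
                f"strain {series.strain_id!r} species names differ from manifest registry"
            )
        self.strains.append(StrainRecord(series.strain_id, str(path), role, pathway))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format_version": self.format_version,
            "units": self.units,
            "metabolite_names": list(self.metabolite_names),
            "protein_names": list(self.protein_names),
            "strains": [vars(r) for r in self.strains],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        manifest = cls(
            strains=[StrainRecord(**r) for r in payload["strains"]],
            metabolite_names=tuple(payload["metabolite_names"]),
            protein_names=tuple(payload["protein_names"]),
            units=payload.get("units", "arbitrary"),
            format_version=payload.get("format_version", FORMAT_VERSION),
        )
        base = Path(path).parent
        for record in manifest.strains:
            if not (base / record.path).exists() and not Path(record.path).exists():
                raise SchemaError(f"manifest references missing file {record.path!r}")
        return manifest

    def load_series(self, record: StrainRecord, base: str | Path = ".") -> OmicsTimeSeries:
        p = Path(record.path)
        if not p.exists():
            p = Path(base) / record.path
        return read_omics_csv(p)


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config file into a dict (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
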