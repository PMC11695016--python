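"""Time-series file formats and run configuration.

Gait trials travel as OpenSim-style storage files (``.sto``/``.mot``: free
header terminated by ``endheader``, tab-delimited numeric body) or plain CSV,
auto-detected by extension.  Angles are degrees in files and radians inside
the library; the conversion happens at this boundary only.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml


class StorageParseError(ValueError):
    """Malformed storage file; message carries the offending line number."""


@dataclass
class TimeSeriesTable:
    """Rectangular time series: a time column plus named data channels."""
    data: pd.DataFrame                      # first column must be "time" (s)
    units: dict = field(default_factory=dict)
    name: str = "table"
    in_degrees: bool = True

    def __post_init__(self):
        if "time" not in self.data.columns:
            raise ValueError("TimeSeriesTable requires a 'time' column")
        t = self.data["time"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time column must be strictly increasing")
        for c in self.data.columns:
            self.units.setdefault(c, "s" if c == "time" else "")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


def write_storage(table: TimeSeriesTable, path) -> None:
    """Write a table in the OpenSim storage dialect (or CSV by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table.data.to_csv(path, index=False)
        return
    n_rows, n_cols = table.data.shape
    lines = [table.name, "version=1",
             f"nRows={n_rows}", f"nColumns={n_cols}",
             f"inDegrees={'yes' if table.in_degrees else 'no'}",
             "endheader",
             "\t".join(table.data.columns)]
    body = "\n".join("\t".join(f"{v:.12g}" for v in row)
                     for row in table.data.to_numpy())
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_storage(path) -> TimeSeriesTable:
    """Read an OpenSim storage file or CSV into a :class:`TimeSeriesTable`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        return TimeSeriesTable(data=df, name=path.stem)
    lines = path.read_text().splitlines()
    meta = {}
    header_end = None
    name = path.stem
    for i, line in enumerate(lines):
        s = line.strip()
        if s.lower() == "endheader":
            header_end = i
            break
        if "=" in s:
            k, v = s.split("=", 1)
            meta[k.strip().lower()] = v.strip()
        elif i == 0 and s:
            name = s
    if header_end is None:
        raise StorageParseError(f"{path}: no 'endheader' line found")
    try:
        cols = lines[header_end + 1].split("\t")
    except IndexError:
        raise StorageParseError(f"{path}: missing column header after line "
                                f"{header_end + 1}")
    rows = []
    for ln, line in enumerate(lines[header_end + 2:], start=header_end + 3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != len(cols):
            raise StorageParseError(
                f"{path}:{ln}: expected {len(cols)} values, found {len(parts)}")
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise StorageParseError(f"{path}:{ln}: {exc}") from None
    df = pd.DataFrame(rows, columns=[c.strip() for c in cols])
    if "nrows" in meta and int(meta["nrows"]) != len(df):
        raise StorageParseError(
            f"{path}: header says nRows={meta['nrows']}, body has {len(df)}")
    if "ncolumns" in meta and int(meta["ncolumns"]) != len(df.columns):
        raise StorageParseError(
            f"{path}: header says nColumns={meta['ncolumns']}, body has "
            f"{len(df.columns)}")
    t = df["time"].to_numpy() if "time" in df else None
    if t is not None and t.size > 1 and not np.all(np.diff(t) > 0):
        raise StorageParseError(f"{path}: non-monotone time column")
    return TimeSeriesTable(
        data=df, name=name,
        in_degrees=meta.get("indegrees", "yes").lower() == "yes")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"model", "condition", "ocp", "analysis", "synthetic", "seed",
             "output_dir"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""
    model: dict = field(default_factory=dict)
    condition: dict = field(default_factory=dict)
    ocp: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "gaitopt_run"

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: copy.deepcopy(v) for k, v in raw.items()})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {"model": self.model, "condition": self.condition,
                "ocp": self.ocp, "analysis": self.analysis,
                "synthetic": self.synthetic, "seed": self.seed,
                "output_dir": self.output_dir}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
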