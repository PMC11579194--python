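"""Covariate table container: subjects x covariates with type metadata.

A :class:`CovariateTable` wraps a :class:`pandas.DataFrame` and carries, for
each covariate column, whether it is continuous or categorical, whether it is
modelled on the log scale (biochemical measurements), and an optional
per-subject sampling-weight column.  Missing values are plain NaN / None in
the underlying frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class ColumnSpec:
    """Type metadata for one covariate column."""

    name: str
    kind: str  # "continuous" | "categorical"
    log_scale: bool = False
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.log_scale and self.kind == CATEGORICAL:
            raise ValueError(f"log_scale is meaningless for categorical column {self.name!r}")

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "log_scale": self.log_scale, "unit": self.unit}

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnSpec":
        return cls(name=d["name"], kind=d["kind"], log_scale=bool(d.get("log_scale", False)), unit=d.get("unit"))


@dataclass
class CovariateTable:
    """Rectangular covariate table with schema and optional sampling weights."""

    df: pd.DataFrame
    columns: list[ColumnSpec]
    weight_column: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for spec in self.columns:
            if spec.name not in self.df.columns:
                raise KeyError(f"schema column {spec.name!r} not present in data")
        if self.weight_column is not None:
            if self.weight_column not in self.df.columns:
                raise KeyError(f"weight column {self.weight_column!r} not present in data")
            w = np.asarray(self.df[self.weight_column], dtype=float)
            if np.nanmin(w) < 0:
                raise ValueError("sampling weights must be nonnegative")

    # -- basic views ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def covariates(self) -> list[str]:
        return [c.name for c in self.columns]

    def spec(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(f"no such covariate {name!r}")

    @property
    def continuous(self) -> list[str]:
        return [c.name for c in self.columns if c.kind == CONTINUOUS]

    @property
    def categorical(self) -> list[str]:
        return [c.name for c in self.columns if c.kind == CATEGORICAL]

    @property
    def weights(self) -> np.ndarray | None:
        if self.weight_column is None:
            return None
        return np.asarray(self.df[self.weight_column], dtype=float)

    def values(self, name: str) -> np.ndarray:
        """Column values on the natural scale (NaN for missing)."""
        col = self.df[name]
        if self.spec(name).kind == CONTINUOUS:
            return np.asarray(col, dtype=float)
        return np.asarray(col, dtype=object)

    def missing_mask(self, name: str) -> np.ndarray:
        return np.asarray(self.df[name].isna())

    def subset_rows(self, mask: np.ndarray) -> "CovariateTable":
        return CovariateTable(
            df=self.df.loc[np.asarray(mask)].reset_index(drop=True),
            columns=list(self.columns),
            weight_column=self.weight_column,
            meta=dict(self.meta),
        )

    def drop_covariate(self, name: str) -> "CovariateTable":
        cols = [c for c in self.columns if c.name != name]
        return CovariateTable(df=self.df, columns=cols, weight_column=self.weight_column, meta=dict(self.meta))

    # -- I/O ------------------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the table as CSV plus a sidecar ``<name>.meta.json`` schema."""
        path = Path(path)
        cols = self.covariates + ([self.weight_column] if self.weight_column else [])
        self.df[cols].to_csv(path, index=False)
        if sidecar:
            meta = {
                "columns": [c.to_dict() for c in self.columns],
                "weight_column": self.weight_column,
                "meta": _jsonable(self.meta),
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        columns: list[ColumnSpec] | None = None,
        weight_column: str | None = None,
    ) -> "CovariateTable":
        """Read a CSV; if no schema is given, look for a sidecar, else infer.

        Inference: numeric dtype -> continuous (natural scale), anything else
        -> categorical.  Log-scale flags cannot be inferred and default off.
        """
        path = Path(path)
        df = pd.read_csv(path)
        if columns is None:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                columns = [ColumnSpec.from_dict(d) for d in meta["columns"]]
                if weight_column is None:
                    weight_column = meta.get("weight_column")
            else:
                columns = infer_schema(df, exclude=[weight_column] if weight_column else [])
        return cls(df=df, columns=columns, weight_column=weight_column)


def infer_schema(df: pd.DataFrame, exclude: list[str] | None = None) -> list[ColumnSpec]:
    exclude = set(exclude or [])
    specs = []
    for name in df.columns:
        if name in exclude:
            continue
        kind = CONTINUOUS if pd.api.types.is_numeric_dtype(df[name]) else CATEGORICAL
        specs.append(ColumnSpec(name=name, kind=kind))
    return specs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
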