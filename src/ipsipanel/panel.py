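"""Data model for recurring-exposure panels.

A panel is wide-format: one row per individual, with time-invariant covariates
``C`` and per-wave blocks ``L_t`` (numeric covariates), ``X_t`` (binary
exposure) and ``Y_t`` (numeric outcome) for waves ``t = 1..T`` (1-based).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A declared column is missing or the schema itself is malformed."""


class ValidationError(ValueError):
    """Panel content violates an invariant (e.g. non-binary exposure)."""


class TemporalOrdering(str, Enum):
    """Within-wave causal order of exposure and outcome."""

    EXPOSURE_FIRST = "exposure_first"  # X_t precedes Y_t:  H_t = (C, L1,X1,Y1, ..., L_t)
    OUTCOME_FIRST = "outcome_first"    # Y_t precedes X_t:  H_t = (C, L1,Y1,X1, ..., L_t,Y_t)


@dataclass(frozen=True)
class PanelSchema:
    """Column-role declaration for a wide panel.

    ``L``/``X``/``Y`` map wave index (1-based) to column name(s).  The
    convenience constructor :meth:`from_dict` also accepts prefix strings that
    expand via the ``name_t`` suffix convention; explicit per-wave mappings win
    over the convention when both are given.
    """

    id: str
    T: int
    C: tuple[str, ...]
    L: Mapping[int, tuple[str, ...]]
    X: Mapping[int, str]
    Y: Mapping[int, str]

    def __post_init__(self) -> None:
        if self.T < 1:
            raise SchemaError("T must be >= 1")
        for t in range(1, self.T + 1):
            for role, table in (("L", self.L), ("X", self.X), ("Y", self.Y)):
                if t not in table:
                    raise SchemaError(f"schema missing wave {t} for role {role}")
        names = self.all_columns()
        dupes = {c for c in names if names.count(c) > 1}
        if dupes:
            raise SchemaError(f"duplicate column role assignment: {sorted(dupes)}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PanelSchema":
        try:
            T = int(d["T"])
        except KeyError as exc:
            raise SchemaError("schema must declare T") from exc

        def expand_block(val: Any) -> dict[int, tuple[str, ...]]:
            if isinstance(val, str):  # suffix convention: name_1..name_T
                return {t: (f"{val}_{t}",) for t in range(1, T + 1)}
            out: dict[int, tuple[str, ...]] = {}
            for k, v in dict(val).items():
                cols = (v,) if isinstance(v, str) else tuple(v)
                out[int(k)] = cols
            return out

        def expand_single(val: Any) -> dict[int, str]:
            if isinstance(val, str):
                return {t: f"{val}_{t}" for t in range(1, T + 1)}
            return {int(k): str(v) for k, v in dict(val).items()}

        C = d.get("C", ())
        return cls(
            id=str(d.get("id", "id")),
            T=T,
            C=(C,) if isinstance(C, str) else tuple(C),
            L=expand_block(d.get("L", {})),
            X=expand_single(d.get("X", {})),
            Y=expand_single(d.get("Y", {})),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PanelSchema":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def all_columns(self) -> list[str]:
        cols = [self.id, *self.C]
        for t in range(1, self.T + 1):
            cols.extend(self.L[t])
            cols.append(self.X[t])
            cols.append(self.Y[t])
        return cols

    def analysis_columns(self) -> list[str]:
        return [c for c in self.all_columns() if c != self.id]


@dataclass
class PanelDataset:
    """Validated wide-format recurring-exposure panel."""

    data: pd.DataFrame
    schema: PanelSchema
    centering: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def T(self) -> int:
        return self.schema.T

    @property
    def ids(self) -> np.ndarray:
        return self.data[self.schema.id].to_numpy()

    def x(self, t: int) -> np.ndarray:
        return self.data[self.schema.X[t]].to_numpy(dtype=float)

    def y(self, t: int) -> np.ndarray:
        return self.data[self.schema.Y[t]].to_numpy(dtype=float)

    def l_columns(self, t: int) -> tuple[str, ...]:
        return self.schema.L[t]

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def columns_dict(self) -> dict[str, np.ndarray]:
        return {c: self.data[c].to_numpy(dtype=float)
                for c in self.schema.analysis_columns()}

    def validate(self) -> None:
        missing = [c for c in self.schema.all_columns() if c not in self.data.columns]
        if missing:
            raise SchemaError(f"panel is missing declared column(s): {missing}")
        for t in range(1, self.T + 1):
            col = self.schema.X[t]
            vals = self.data[col].to_numpy(dtype=float)
            bad = vals[~np.isin(vals, (0.0, 1.0))]
            if bad.size:
                raise ValidationError(
                    f"exposure column {col!r} must be binary 0/1; "
                    f"found value(s) {sorted(set(bad.tolist()))[:5]}"
                )

    def subset(self, indices: np.ndarray) -> "PanelDataset":
        """Row subset / resample (used by the bootstrap)."""
        return PanelDataset(self.data.iloc[indices].reset_index(drop=True),
                            self.schema, dict(self.centering))


@dataclass(frozen=True)
class HistoryDesign:
    """Ordered pre-exposure column list H_t for one wave under one ordering."""

    t: int
    ordering: TemporalOrdering
    columns: tuple[str, ...]


def history_columns(schema: PanelSchema, t: int,
                    ordering: TemporalOrdering = TemporalOrdering.EXPOSURE_FIRST,
                    ) -> tuple[str, ...]:
    """Ordered pre-exposure columns H_t: C block, then wave blocks in time order."""
    if not 1 <= t <= schema.T:
        raise IndexError(f"wave index t={t} out of range 1..{schema.T}")
    ordering = TemporalOrdering(ordering)
    cols: list[str] = list(schema.C)
    for u in range(1, t):
        cols.extend(schema.L[u])
        if ordering is TemporalOrdering.EXPOSURE_FIRST:
            cols.extend([schema.X[u], schema.Y[u]])
        else:
            cols.extend([schema.Y[u], schema.X[u]])
    cols.extend(schema.L[t])
    if ordering is TemporalOrdering.OUTCOME_FIRST:
        cols.append(schema.Y[t])
    return tuple(cols)


def build_history(panel: PanelDataset, t: int,
                  ordering: TemporalOrdering = TemporalOrdering.EXPOSURE_FIRST) -> HistoryDesign:
    """History design H_t for one wave of a panel under the given ordering."""
    ordering = TemporalOrdering(ordering)
    return HistoryDesign(t=t, ordering=ordering,
                         columns=history_columns(panel.schema, t, ordering))


def load_panel(path: str | Path, schema: PanelSchema | Mapping[str, Any] | str | Path,
               sep: str | None = None) -> PanelDataset:
    """Read a delimited text panel, complete-case filter it, and validate.

    Rows with any missing value among the declared analysis columns are
    dropped (complete-case default); the dropped count is logged.
    """
    if isinstance(schema, (str, Path)):
        schema = PanelSchema.from_file(schema)
    elif not isinstance(schema, PanelSchema):
        schema = PanelSchema.from_dict(schema)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in schema.all_columns() if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path} is missing declared column(s): {missing}")
    declared = schema.all_columns()
    n0 = len(df)
    df = df.dropna(subset=declared).reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.warning("complete-case filter dropped %d of %d row(s)", dropped, n0)
    for c in declared:
        df[c] = pd.to_numeric(df[c])
    return PanelDataset(df[declared].copy(), schema)


def write_panel(panel: PanelDataset, path: str | Path, sep: str = ",") -> None:
    panel.data.to_csv(path, sep=sep, index=False)


def center_covariates(panel: PanelDataset, columns: Sequence[str]) -> PanelDataset:
    """Subtract each named column's sample mean; constants kept for reporting.

    Idempotent: re-centering a centered column shifts it by ~0 and the stored
    constant accumulates the total shift from the original data.
    """
    df = panel.data.copy()
    centering = dict(panel.centering)
    for c in columns:
        if c not in df.columns:
            raise SchemaError(f"unknown column {c!r}")
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise TypeError(f"column {c!r} is not numeric")
        m = float(df[c].mean())
        df[c] = df[c] - m
        centering[c] = centering.get(c, 0.0) + m
    out = replace(panel, data=df, centering=centering)
    return out
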