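"""The cohort table: n rows of categorical state indices over a schema."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import VariableSpec

__all__ = ["DiscreteDataset"]


class DiscreteDataset:
    """n x |V| matrix of state indices, column order fixed by the schema.

    Cells are stored as integer indices into each variable's state list;
    :meth:`to_frame` materialises the string labels.  ``codes`` is an
    int32 array of shape ``(n, len(schema))``.
    """

    def __init__(self, schema: list[VariableSpec], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int32)
        if codes.ndim != 2 or codes.shape[1] != len(schema):
            raise ValueError(
                f"codes shape {codes.shape} does not match schema of {len(schema)} variables"
            )
        if codes.shape[0] < 1:
            raise ValueError("dataset needs at least one row")
        for j, spec in enumerate(schema):
            col = codes[:, j]
            if col.min() < 0 or col.max() >= spec.cardinality:
                bad = int(np.argmax((col < 0) | (col >= spec.cardinality)))
                raise ValueError(
                    f"column {spec.name!r}: row {bad} holds index {col[bad]}, "
                    f"valid range is 0..{spec.cardinality - 1}"
                )
        self.schema = list(schema)
        self.codes = codes
        self._index = {s.name: j for j, s in enumerate(self.schema)}

    # -- construction -------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema: list[VariableSpec]) -> "DiscreteDataset":
        """Build from a DataFrame of state labels (strings)."""
        missing_cols = [s.name for s in schema if s.name not in frame.columns]
        if missing_cols:
            raise ValueError(f"missing columns: {missing_cols}")
        n = len(frame)
        codes = np.empty((n, len(schema)), dtype=np.int32)
        for j, spec in enumerate(schema):
            lut = {lab: i for i, lab in enumerate(spec.states)}
            col = frame[spec.name].astype(str).to_numpy()
            for r, lab in enumerate(col):
                try:
                    codes[r, j] = lut[lab]
                except KeyError:
                    raise ValueError(
                        f"unknown state code {lab!r} at row {r}, column {spec.name!r}; "
                        f"valid states: {spec.states}"
                    ) from None
        return cls(schema, codes)

    # -- accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.schema]

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([s.cardinality for s in self.schema], dtype=np.int64)

    def column_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def spec(self, name: str) -> VariableSpec:
        return self.schema[self.column_index(name)]

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.column_index(name)]

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, spec in enumerate(self.schema):
            labels = np.asarray(spec.states, dtype=object)
            data[spec.name] = labels[self.codes[:, j]]
        return pd.DataFrame(data)

    def copy(self) -> "DiscreteDataset":
        return DiscreteDataset(self.schema, self.codes.copy())

    def __repr__(self) -> str:
        return f"DiscreteDataset(n={self.n}, variables={len(self.schema)})"
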