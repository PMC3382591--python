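"""Core aligned-matrix containers.

The pipeline moves three genes/TFs x samples matrices around: log2
expression (with replicate columns mapped to cell lines), TF regulation
scores, and gene-level CNV. Expression gets a thin wrapper because the
column -> cell-line mapping is part of its contract; the other two are
plain DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, UnknownIdentifierError


@dataclass
class ExpressionMatrix:
    """Genes x sample-columns log2 expression with a column->line map.

    ``values`` has unique gene ids as index and sample/replicate ids as
    columns; ``sample_to_line`` maps every column to exactly one cell
    line (for patient cohorts the "line" is simply the patient id).
    """

    values: pd.DataFrame
    sample_to_line: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ContractError(f"duplicate gene ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ContractError("expression values must be finite")
        self.sample_to_line = pd.Series(self.sample_to_line)
        missing = set(self.values.columns) - set(self.sample_to_line.index)
        if missing:
            raise ContractError(f"columns without a cell-line mapping: {sorted(missing)[:5]}")
        self.sample_to_line = self.sample_to_line.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> list[str]:
        """Cell lines in first-appearance column order."""
        return list(dict.fromkeys(self.sample_to_line))

    def line_columns(self, line: str) -> list[str]:
        cols = [c for c, l in self.sample_to_line.items() if l == line]
        if not cols:
            raise UnknownIdentifierError(f"cell line {line!r} has no columns")
        return cols

    def collapse_replicates(self) -> pd.DataFrame:
        """Genes x cell-lines matrix of per-line replicate means."""
        groups = self.values.T.groupby(self.sample_to_line)
        collapsed = groups.mean().T
        return collapsed[self.lines]

    @classmethod
    def from_single_samples(cls, values: pd.DataFrame) -> "ExpressionMatrix":
        """Each column is its own 'line' (patient cohorts)."""
        return cls(values, pd.Series(values.columns, index=values.columns))
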