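"""Baseline expression loading and discretization to 0-9 levels.

Replicate expression values (e.g. microarray intensities of untreated
control cells) are averaged per gene and linearly rescaled onto a 10-level
integer grayscale: 0 = not detectable, 9 = maximal in the table. These
levels are the simulator's initial node states. Complexes, compounds and
genes missing from the table start at level 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:
    from .network_model import PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineLevels",
    "read_expression_table",
    "read_series_matrix",
    "average_replicates",
    "normalize_to_levels",
    "initialize_states",
]


@dataclass(frozen=True)
class BaselineLevels:
    """Per-node integer expression level on the 0..scale_max grayscale."""

    levels: Mapping[str, int]
    scale_max: int = 9

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.levels.items()
               if not 0 <= v <= self.scale_max}
        if bad:
            raise ValueError(
                f"levels outside [0, {self.scale_max}]: {sorted(bad)[:5]}")

    def get(self, node_id: str, default: int = 0) -> int:
        return self.levels.get(node_id, default)


def read_expression_table(path: str) -> pd.DataFrame:
    """Read a genes x replicates expression matrix.

    First column = gene symbol, remaining columns = replicate values.
    Comma-separated for ``.csv``, otherwise tab-separated.
    """
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.index = table.index.astype(str)
    if (table < 0).any().any():
        raise ValueError(f"{path}: expression values must be nonnegative")
    return table


def read_series_matrix(path: str) -> pd.DataFrame:
    """Read the data table of a GEO series-matrix text file.

    Extracts the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``; a file without those markers is read as a
    plain TSV expression table.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    starts = [i for i, l in enumerate(lines)
              if l.strip().lower() == "!series_matrix_table_begin"]
    if not starts:
        return read_expression_table(path)
    begin = starts[0] + 1
    try:
        end = next(i for i, l in enumerate(lines[begin:], begin)
                   if l.strip().lower() == "!series_matrix_table_end")
    except StopIteration:
        end = len(lines)
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[begin:end])), sep="\t",
                        index_col=0)
    table.index = table.index.astype(str).str.strip('"')
    table.columns = [str(c).strip('"') for c in table.columns]
    return table


def average_replicates(table: pd.DataFrame | Mapping[str, list[float]]
                       ) -> pd.Series:
    """Arithmetic mean over replicate columns, per gene."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame.from_dict(
            {g: pd.Series(v, dtype=float) for g, v in table.items()},
            orient="index")
    if table.empty:
        raise ValueError("expression table is empty")
    means = table.mean(axis=1, skipna=True)
    missing = means[means.isna()].index.tolist()
    if missing:
        raise ValueError(f"genes with zero replicate values: {missing[:5]}")
    return means


def normalize_to_levels(values: Mapping[str, float] | pd.Series,
                        scale_max: int = 9,
                        log2_transform: bool = False) -> BaselineLevels:
    """Linear min-max rescale of mean expression onto {0, ..., scale_max}.

    level = round(scale_max * (x - min) / (max - min)), rounding half away
    from zero, so the lowest gene maps to 0 and the highest to scale_max.
    The scale is global across all genes; levels are therefore invariant
    under positive affine transforms of the input. A degenerate table
    (max == min) maps everything to 0 with a warning.

    log2_transform applies log2(x + 1) first, the usual variance-stabilizing
    convention for raw array intensities (off by default).
    """
    series = pd.Series(dict(values), dtype=float)
    if series.empty:
        raise ValueError("no expression values to normalize")
    if log2_transform:
        series = np.log2(series + 1.0)
    lo, hi = float(series.min()), float(series.max())
    if hi == lo:
        logger.warning("degenerate expression range (max == min); "
                       "all levels set to 0")
        return BaselineLevels({g: 0 for g in series.index}, scale_max)
    scaled = scale_max * (series - lo) / (hi - lo)
    # round half away from zero (values are nonnegative here)
    levels = np.floor(scaled + 0.5).astype(int)
    return BaselineLevels(levels.to_dict(), scale_max)


def initialize_states(net: "PathwayNetwork",
                      baseline: BaselineLevels) -> dict[str, int]:
    """Initial state for every network node.

    Gene nodes take their baseline level; complex and compound nodes start
    at 0, as do genes missing from the expression table (logged).
    """
    states: dict[str, int] = {}
    for node in net.nodes:
        if node.kind != "gene":
            states[node.id] = 0
        elif node.id in baseline.levels:
            states[node.id] = baseline.levels[node.id]
        else:
            logger.info("gene %s absent from expression table; level 0",
                        node.id)
            states[node.id] = 0
    return states
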