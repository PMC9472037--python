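"""Trip-table validation, standardization and round-tripping.

The structure-learning score is scale-sensitive and all effect sizes are
reported in SD units, so every analysis variable is standardized to mean 0,
SD 1 (sample SD, n-1 convention) before modelling. The per-column moments are
kept so results can be mapped back to raw units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StandardizationParams",
    "standardize",
    "inverse_standardize",
    "drop_incomplete",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column (mean, SD) of the standardizing transform."""

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        bad = [c for c, s in self.sds.items() if not s > 0]
        if bad:
            raise ValueError(f"nonpositive SD for column(s): {bad}")

    @property
    def columns(self) -> list[str]:
        return list(self.means)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"means": self.means, "sds": self.sds}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StandardizationParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(means=payload["means"], sds=payload["sds"])


def standardize(
    table: pd.DataFrame,
    columns=None,
    *,
    include_binary: bool = True,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Center and scale the named columns to mean 0, SD 1 (sample SD).

    All effect sizes downstream are in SD-per-SD units, so 0/1 flag columns
    are standardized like continuous ones by default; ``include_binary=False``
    leaves two-valued 0/1 columns untouched.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    out = table.copy()
    for c in columns:
        col = table[c]
        if not pd.api.types.is_numeric_dtype(col):
            raise TypeError(f"column {c!r} is not numeric")
        vals = col.dropna()
        if vals.empty:
            raise ValueError(f"column {c!r} is entirely missing")
        if not include_binary and set(np.unique(vals)) <= {0.0, 1.0}:
            continue
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if not sd > 0:
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (col - mu) / sd
        means[c] = mu
        sds[c] = sd
    out.attrs["scale"] = "standardized"
    return out, StandardizationParams(means=means, sds=sds)


def inverse_standardize(table: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Map standardized columns back to raw units."""
    out = table.copy()
    for c in params.columns:
        out[c] = table[c] * params.sds[c] + params.means[c]
    out.attrs["scale"] = "raw"
    return out


def drop_incomplete(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Complete-case filter: remove rows missing any analysis variable."""
    subset = list(columns) if columns is not None else list(table.columns)
    out = table.dropna(subset=subset).reset_index(drop=True)
    dropped = len(table) - len(out)
    if dropped:
        logger.info("dropped %d incomplete trip(s) of %d", dropped, len(table))
    return out
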