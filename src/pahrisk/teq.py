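"""Benzo[a]pyrene-equivalent toxic concentrations.

The toxic equivalent of a PAH mixture is the TEF-weighted sum of compound
concentrations: TEQ_i = C_i x TEF_i, expressed in ug/g BaP-equivalents.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

from .concentrations import ConcentrationTable
from .registry import CompoundRegistry, default_registry

__all__ = ["TEQResult", "compute_teq", "teq_by_location"]


@dataclasses.dataclass(frozen=True)
class TEQResult:
    """Per-compound and total BaP-equivalent concentrations (ug/g)."""

    per_compound: dict[str, float]
    total: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.per_compound, name="teq")


def compute_teq(
    concentrations: Mapping[str, float] | pd.Series,
    registry: CompoundRegistry | None = None,
) -> TEQResult:
    """TEQ_i = C_i x TEF_i for each compound, plus the mixture total.

    *concentrations* maps compound abbreviation to concentration in ug/g
    (typically the per-compound means of a site).  Every key must be
    registered and every value non-negative.
    """
    registry = registry if registry is not None else default_registry()
    per: dict[str, float] = {}
    for abbrev, c in dict(concentrations).items():
        if c < 0:
            raise ValueError(f"negative concentration for {abbrev}: {c}")
        per[abbrev] = float(c) * registry[abbrev].tef
    return TEQResult(per_compound=per, total=float(sum(per.values())))


def teq_by_location(table: ConcentrationTable) -> pd.Series:
    """Total TEQ of each sampling location (ug/g BaP-equivalents).

    Missing cells contribute zero to the location total.
    """
    tefs = table.registry.tefs().reindex(table.compounds)
    return (table.data.fillna(0.0) * tefs).sum(axis=1).rename("teq_total")
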