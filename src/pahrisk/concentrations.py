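"""Soil-concentration tables and composition profiling.

A :class:`ConcentrationTable` holds per-location, per-compound soil
concentrations in ug/g dry soil (equivalently mg/kg).  ``summarize`` produces
the per-compound summary statistics (mean, std, min, max, % of total) that
drive the downstream toxicity-equivalence and risk calculations, and the
``ring_distribution`` / ``mw_distribution`` / ``carcinogenic_fraction``
helpers express the compound mix as source-diagnostic composition profiles.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import CompoundRegistry, default_registry

__all__ = [
    "ConcentrationTable",
    "ValidationError",
    "read_concentrations",
    "summarize",
    "ring_distribution",
    "mw_distribution",
    "carcinogenic_fraction",
]


class ValidationError(ValueError):
    """A concentration table violates the input contract."""


class ConcentrationTable:
    """Locations x compounds matrix of soil concentrations (ug/g dry soil).

    Values must be finite and non-negative; missing cells are NaN and are
    excluded from statistics.  Every compound column must resolve in the
    registry.
    """

    def __init__(self, data: pd.DataFrame, registry: CompoundRegistry | None = None):
        self.registry = registry if registry is not None else default_registry()
        unknown = [c for c in data.columns if c not in self.registry]
        if unknown:
            raise ValidationError(f"unknown compound columns: {unknown}")
        values = data.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.any(values < 0):
                bad = data.columns[np.nanmin(values, axis=0) < 0].tolist()
                raise ValidationError(f"negative concentrations in columns: {bad}")
        if np.any(np.isinf(values)):
            raise ValidationError("non-finite concentrations present")
        self.data = data.astype(float)

    @property
    def locations(self) -> list:
        return list(self.data.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_locations(self) -> int:
        return len(self.data)

    def substitute_nondetects(self, detection_limit: float, value: str = "zero") -> "ConcentrationTable":
        """Replace values below *detection_limit* by 0, DL/2 or DL.

        *value* is one of ``"zero"``, ``"half"`` or ``"dl"``; the default
        mirrors reporting non-detects as zero with no blank correction.
        """
        repl = {"zero": 0.0, "half": detection_limit / 2.0, "dl": detection_limit}
        try:
            fill = repl[value]
        except KeyError:
            raise ValueError(f"value must be one of {list(repl)}, got {value!r}") from None
        out = self.data.where(~(self.data < detection_limit), fill)
        return ConcentrationTable(out, self.registry)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="location")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ConcentrationTable {self.n_locations} locations x {len(self.compounds)} compounds>"


def read_concentrations(path: str | Path, registry: CompoundRegistry | None = None) -> ConcentrationTable:
    """Read a wide CSV (first column = location label, header = compound
    abbreviations) into a validated :class:`ConcentrationTable`."""
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty or unparseable CSV: {path}") from None
    except pd.errors.ParserError as e:
        raise ValidationError(f"malformed CSV {path}: {e}") from None
    if df.shape[1] == 0:
        raise ValidationError(f"no compound columns in {path}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(f"non-numeric concentration columns: {non_numeric}")
    return ConcentrationTable(df, registry)


def summarize(table: ConcentrationTable, ddof: int = 1) -> pd.DataFrame:
    """Per-compound summary statistics over locations.

    Returns a DataFrame indexed by compound with columns ``mean``, ``std``,
    ``min``, ``max`` (ug/g) and ``pct_of_total`` (= 100 * mean / sum of
    means).  The sum of means is stored in ``result.attrs["total_mean"]``.

    *ddof* selects the standard-deviation denominator (default n-1, sample
    std).  Single-location tables report std = 0 with a warning rather than
    failing, so toy examples stay runnable.
    """
    if table.n_locations == 0:
        raise ValidationError("cannot summarize an empty table")
    df = table.data
    if table.n_locations <= ddof:
        warnings.warn(
            f"only {table.n_locations} location(s): std reported as 0",
            UserWarning,
            stacklevel=2,
        )
        std = pd.Series(0.0, index=df.columns)
    else:
        std = df.std(ddof=ddof)
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "std": std,
            "min": df.min(),
            "max": df.max(),
        }
    )
    total = float(out["mean"].sum())
    out["pct_of_total"] = 100.0 * out["mean"] / total if total > 0 else 0.0
    out.index.name = "compound"
    out.attrs["total_mean"] = total
    return out


def _shares(summary: pd.DataFrame, keys: pd.Series) -> dict:
    """Percentage of the summed means attributable to each level of *keys*."""
    means = summary["mean"]
    total = float(means.sum())
    grouped = means.groupby(keys.loc[means.index]).sum()
    if total <= 0:
        return {k: 0.0 for k in grouped.index}
    return {k: 100.0 * v / total for k, v in grouped.items()}


def ring_distribution(summary: pd.DataFrame, registry: CompoundRegistry | None = None) -> dict[int, float]:
    """Share of total mean concentration per aromatic-ring class.

    Returns a mapping ring-count -> percentage; percentages sum to 100 over
    the classes present (when the total is positive).
    """
    registry = registry if registry is not None else default_registry()
    rings = pd.Series({a: registry[a].n_rings for a in summary.index})
    return _shares(summary, rings)


def mw_distribution(summary: pd.DataFrame, registry: CompoundRegistry | None = None) -> dict[str, float]:
    """Share of total mean concentration per molecular-weight class
    (LMW = 2-3 rings, MMW = 4 rings, HMW = 5-6 rings)."""
    registry = registry if registry is not None else default_registry()
    classes = pd.Series({a: registry[a].mw_class for a in summary.index})
    return _shares(summary, classes)


def carcinogenic_fraction(summary: pd.DataFrame, registry: CompoundRegistry | None = None) -> tuple[float, float]:
    """Sum of means over the carcinogenic compounds and its % of total.

    Returns ``(sum_ug_per_g, pct_of_total)``.
    """
    registry = registry if registry is not None else default_registry()
    flagged = [a for a in summary.index if registry[a].carcinogenic]
    carc_sum = float(summary.loc[flagged, "mean"].sum()) if flagged else 0.0
    total = float(summary["mean"].sum())
    pct = 100.0 * carc_sum / total if total > 0 else 0.0
    return carc_sum, pct
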