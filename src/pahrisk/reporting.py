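"""Pipeline assembly and report formatting.

``run_pipeline`` composes the stages (read -> summarize -> TEQ -> risk ->
classify) into a :class:`ReportBundle`; the formatting helpers apply the
printed rounding conventions (ILCR to 2 significant figures, HQ and
percentages to 2 decimals).  All numbers are carried at full precision until
formatting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import pandas as pd

from . import __version__
from .concentrations import (
    ConcentrationTable,
    carcinogenic_fraction,
    mw_distribution,
    read_concentrations,
    ring_distribution,
    summarize,
)
from .registry import CompoundRegistry, default_registry
from .risk import RiskResult, assess, load_exposure_config
from .teq import compute_teq

__all__ = [
    "ReportBundle",
    "run_pipeline",
    "round_sig",
    "format_summary",
    "format_risk",
    "display_risk",
]


def round_sig(x: float, digits: int = 2) -> float:
    """Round to *digits* significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclasses.dataclass
class ReportBundle:
    """Everything one pipeline run produced, at full precision.

    ``summary`` is the per-compound table (mean/std/min/max/% of total/TEQ),
    ``risk`` maps receptor -> :class:`RiskResult`, ``composition`` holds the
    ring-count, molecular-weight and carcinogenic profiles, and
    ``provenance`` records the configuration actually used.
    """

    summary: pd.DataFrame
    total_concentration: float
    total_teq: float
    carcinogenic_sum: float
    carcinogenic_pct: float
    risk: dict[str, RiskResult]
    composition: dict
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "summary": self.summary.round(6).to_dict(orient="index"),
            "total_concentration": self.total_concentration,
            "total_teq": self.total_teq,
            "carcinogenic_sum": self.carcinogenic_sum,
            "carcinogenic_pct": self.carcinogenic_pct,
            "risk": {k: v.as_dict() for k, v in self.risk.items()},
            "composition": {
                "by_rings": {str(k): v for k, v in self.composition["by_rings"].items()},
                "by_mw_class": self.composition["by_mw_class"],
            },
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _config_digest(parts: dict) -> str:
    blob = json.dumps(parts, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(
    concentrations: str | Path | ConcentrationTable,
    registry: CompoundRegistry | None = None,
    exposure_config: str | Path | None = None,
    concentration_basis: str = "total",
    receptors: tuple[str, ...] = ("adult", "child"),
) -> ReportBundle:
    """Run the full assessment on a concentration table or wide CSV.

    *concentration_basis* selects the concentration C driving the risk
    equations: ``"total"`` (sum of the per-compound mean concentrations, the
    default) or ``"teq"`` (total BaP-equivalent concentration).
    """
    registry = registry if registry is not None else default_registry()
    if isinstance(concentrations, ConcentrationTable):
        table = concentrations
        source = "<in-memory table>"
    else:
        table = read_concentrations(concentrations, registry)
        source = str(concentrations)

    summary = summarize(table)
    teq = compute_teq(summary["mean"], registry)
    summary = summary.assign(teq=summary.index.map(teq.per_compound))
    total_c = float(summary["mean"].sum())
    carc_sum, carc_pct = carcinogenic_fraction(summary, registry)
    composition = {
        "by_rings": ring_distribution(summary, registry),
        "by_mw_class": mw_distribution(summary, registry),
    }

    if concentration_basis == "total":
        c_drive = total_c
    elif concentration_basis == "teq":
        c_drive = teq.total
    else:
        raise ValueError(
            f"concentration_basis must be 'total' or 'teq', got {concentration_basis!r}"
        )

    profiles, factors = load_exposure_config(exposure_config)
    unknown = [r for r in receptors if r not in profiles]
    if unknown:
        raise ValueError(f"receptors not in exposure config: {unknown}")
    risk = {r: assess(c_drive, profiles[r], factors) for r in receptors}

    provenance = {
        "version": __version__,
        "source": source,
        "n_locations": table.n_locations,
        "n_compounds": len(table.compounds),
        "concentration_basis": concentration_basis,
        "driving_concentration": c_drive,
        "exposure_config": str(exposure_config) if exposure_config else "<packaged defaults>",
        "slope_factors": dataclasses.asdict(factors),
        "profiles": {r: dataclasses.asdict(profiles[r]) for r in receptors},
    }
    provenance["config_digest"] = _config_digest(
        {k: provenance[k] for k in ("concentration_basis", "slope_factors", "profiles")}
    )

    return ReportBundle(
        summary=summary,
        total_concentration=total_c,
        total_teq=teq.total,
        carcinogenic_sum=carc_sum,
        carcinogenic_pct=carc_pct,
        risk=risk,
        composition=composition,
        provenance=provenance,
    )


def format_summary(bundle: ReportBundle) -> pd.DataFrame:
    """Per-compound summary with printed rounding, plus total rows."""
    df = bundle.summary.copy()
    out = pd.DataFrame(
        {
            "Mean": df["mean"].round(2),
            "Std": df["std"].round(2),
            "Min": df["min"].round(2),
            "Max": df["max"].round(2),
            "% of Total": df["pct_of_total"].round(2),
            "TEQ": df["teq"].round(3),
        },
        index=df.index,
    )
    out.loc["Total"] = [
        round(bundle.total_concentration, 2),
        float("nan"),
        float("nan"),
        float("nan"),
        100.0,
        round(bundle.total_teq, 3),
    ]
    out.loc["Carcinogenic"] = [
        round(bundle.carcinogenic_sum, 2),
        float("nan"),
        float("nan"),
        float("nan"),
        round(bundle.carcinogenic_pct, 2),
        float("nan"),
    ]
    return out


def format_risk(bundle: ReportBundle) -> pd.DataFrame:
    """Receptor x quantity risk table with printed rounding."""
    rows = {}
    for receptor, r in bundle.risk.items():
        rows[receptor] = {
            "ILCR ingestion": round_sig(r.ilcr_ingestion, 2),
            "ILCR inhalation": round_sig(r.ilcr_inhalation, 2),
            "ILCR dermal": round_sig(r.ilcr_dermal, 2),
            "ILCR total": round_sig(r.ilcr_total, 2),
            "EDI": round(r.edi, 3),
            "HQ": round(r.hq, 2),
            "cancer risk exceeds 1e-6": r.cancer_exceeds,
            "HQ exceeds 1": r.noncancer_exceeds,
        }
    return pd.DataFrame(rows)


def display_risk(bundle: ReportBundle) -> str:
    """Risk table rendered with scientific notation for the tiny ILCRs."""
    df = format_risk(bundle)
    shown = df.map(
        lambda v: f"{v:.2g}" if isinstance(v, float) and 0 < abs(v) < 1e-2 else v
    )
    return shown.to_string()
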