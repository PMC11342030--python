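"""Multi-route incremental lifetime cancer risk and non-cancer hazard.

Implements the standard screening-level equations for human exposure to
contaminated soil through accidental ingestion, inhalation of resuspended
particulates, and dermal contact:

    ILCR_ing  = C * CSF_ing  * (BW/70)^(1/3) * IR_ing * EF * ED / (BW * AT * 10^6)
    ILCR_inh  = C * CSF_inh  * (BW/70)^(1/3) * IR_inh * EF * ED / (BW * AT * PEF)
    ILCR_derm = C * CSF_derm * (BW/70)^(1/3) * SA * AF * ABS * EF * ED / (BW * AT * 10^6)

with C the soil concentration in mg/kg.  The (BW/70)^(1/3) factor rescales
the slope factors (derived for a 70 kg reference adult) to the receptor's
body weight; the 10^6 divisor converts mg soil to kg.  Non-carcinogenic
hazard is the quotient of the estimated daily intake and a reference dose:

    EDI = C * IR_ing * ED * EF * CF / (AT * BW),    HQ = EDI / RfD.

Screening thresholds: total ILCR above 1e-6 (WHO permissible excess cancer
risk) and HQ above 1 flag a potential concern.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "ExposureProfile",
    "SlopeFactors",
    "RiskResult",
    "ProfileError",
    "bw_adjustment",
    "ilcr_ingestion",
    "ilcr_inhalation",
    "ilcr_dermal",
    "total_ilcr",
    "edi",
    "hazard_quotient",
    "classify_risk",
    "assess",
    "load_exposure_config",
    "default_profiles",
]

#: Screening threshold for total incremental lifetime cancer risk.
CANCER_RISK_THRESHOLD = 1e-6
#: Screening threshold for the non-carcinogenic hazard quotient.
HAZARD_QUOTIENT_THRESHOLD = 1.0
#: Reference adult body weight (kg) used in the slope-factor rescaling.
REFERENCE_BW = 70.0


class ProfileError(ValueError):
    """An exposure profile or slope-factor set violates its contract."""


@dataclasses.dataclass(frozen=True)
class ExposureProfile:
    """Receptor-specific exposure parameters.

    Attributes
    ----------
    receptor : str
        ``"adult"`` or ``"child"`` (free-form labels are allowed).
    ir_ing : float
        Soil ingestion rate, mg/day.
    ir_inh : float
        Inhalation rate, m^3/day.
    sa : float
        Exposed skin area, cm^2.
    af : float
        Soil-to-skin adherence factor, mg/cm^2.
    abs_frac : float
        Dermal absorption fraction, dimensionless in (0, 1].
    ef : float
        Exposure frequency, days/year (<= 366).
    ed : float
        Exposure duration, years.
    bw : float
        Body weight, kg.
    at : float
        Averaging time, days.
    """

    receptor: str
    ir_ing: float
    ir_inh: float
    sa: float
    af: float
    abs_frac: float
    ef: float
    ed: float
    bw: float
    at: float

    def __post_init__(self) -> None:
        for field in ("ir_ing", "ir_inh", "sa", "af", "abs_frac", "ef", "ed", "bw", "at"):
            v = getattr(self, field)
            if not v > 0:
                raise ProfileError(f"{self.receptor}: {field} must be positive, got {v}")
        if not self.abs_frac <= 1:
            raise ProfileError(f"{self.receptor}: abs_frac must be in (0, 1], got {self.abs_frac}")
        if self.ef > 366:
            raise ProfileError(f"{self.receptor}: ef cannot exceed 366 days/year, got {self.ef}")
        if self.at < self.ef * self.ed:
            raise ProfileError(
                f"{self.receptor}: averaging time {self.at} d is shorter than "
                f"exposure EF x ED = {self.ef * self.ed} d"
            )


@dataclasses.dataclass(frozen=True)
class SlopeFactors:
    """Dose-response and unit-conversion constants shared by both receptors.

    ``csf_ing``/``csf_inh``/``csf_derm`` are route-specific cancer slope
    factors in (mg/kg/day)^-1; ``pef`` is the particulate emission factor in
    m^3/kg converting soil concentration to inhalable particulate exposure;
    ``rfd`` is the non-cancer reference dose paired with the conversion
    factor ``cf`` used inside the daily-intake formula; ``unit_factor`` is
    the mg-to-kg soil divisor of the ingestion/dermal equations.
    """

    csf_ing: float
    csf_inh: float
    csf_derm: float
    pef: float
    rfd: float
    cf: float = 1.0
    unit_factor: float = 1e6

    def __post_init__(self) -> None:
        for field in ("csf_ing", "csf_inh", "csf_derm", "pef", "rfd", "cf", "unit_factor"):
            v = getattr(self, field)
            if not v > 0:
                raise ProfileError(f"slope factors: {field} must be positive, got {v}")


@dataclasses.dataclass(frozen=True)
class RiskResult:
    """Route-wise ILCR, daily intake and hazard quotient for one receptor."""

    receptor: str
    concentration: float
    ilcr_ingestion: float
    ilcr_inhalation: float
    ilcr_dermal: float
    ilcr_total: float
    edi: float
    hq: float
    cancer_exceeds: bool
    noncancer_exceeds: bool

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def bw_adjustment(bw: float) -> float:
    """Body-weight rescaling factor (BW / 70)^(1/3).

    Equals 1 for the 70 kg reference adult; grows slower than BW itself, so
    risk per unit intake still falls with increasing body weight.
    """
    if not bw > 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    return (bw / REFERENCE_BW) ** (1.0 / 3.0)


def _check_c(c: float) -> None:
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")


def ilcr_ingestion(c: float, p: ExposureProfile, s: SlopeFactors) -> float:
    """Incremental lifetime cancer risk from accidental soil ingestion.

    *c* is the soil concentration in mg/kg.
    """
    _check_c(c)
    return (
        c * s.csf_ing * bw_adjustment(p.bw) * p.ir_ing * p.ef * p.ed
        / (p.bw * p.at * s.unit_factor)
    )


def ilcr_inhalation(c: float, p: ExposureProfile, s: SlopeFactors) -> float:
    """ILCR from inhalation of soil-derived particulates (PEF-converted)."""
    _check_c(c)
    return (
        c * s.csf_inh * bw_adjustment(p.bw) * p.ir_inh * p.ef * p.ed
        / (p.bw * p.at * s.pef)
    )


def ilcr_dermal(c: float, p: ExposureProfile, s: SlopeFactors) -> float:
    """ILCR from dermal contact with contaminated soil."""
    _check_c(c)
    return (
        c * s.csf_derm * bw_adjustment(p.bw) * p.sa * p.af * p.abs_frac * p.ef * p.ed
        / (p.bw * p.at * s.unit_factor)
    )


def total_ilcr(ingestion: float, inhalation: float, dermal: float) -> float:
    """Total ILCR: arithmetic sum of the three route contributions."""
    return ingestion + inhalation + dermal


def edi(c: float, p: ExposureProfile, cf: float = 1.0) -> float:
    """Estimated daily intake via the ingestion route.

    EDI = C * IR_ing * ED * EF * CF / (AT * BW).  The conversion factor *cf*
    must be consistent with the units of the reference dose it is compared
    against.
    """
    _check_c(c)
    if not cf > 0:
        raise ValueError(f"conversion factor must be positive, got {cf}")
    return c * p.ir_ing * p.ed * p.ef * cf / (p.at * p.bw)


def hazard_quotient(edi_value: float, rfd: float) -> float:
    """Non-carcinogenic hazard quotient HQ = EDI / RfD."""
    if not rfd > 0:
        raise ValueError(f"reference dose must be positive, got {rfd}")
    return edi_value / rfd


def classify_risk(
    ilcr_total_value: float, hq_value: float
) -> tuple[bool, bool]:
    """Threshold classification.

    Returns ``(cancer_exceeds, noncancer_exceeds)``: ILCR strictly above
    1e-6, HQ strictly above 1.  A value exactly at the threshold does not
    flag (strict inequality).
    """
    return (
        ilcr_total_value > CANCER_RISK_THRESHOLD,
        hq_value > HAZARD_QUOTIENT_THRESHOLD,
    )


def assess(c: float, profile: ExposureProfile, factors: SlopeFactors) -> RiskResult:
    """Full single-receptor assessment: all three ILCR routes, their total,
    the daily intake, the hazard quotient and the threshold flags."""
    ing = ilcr_ingestion(c, profile, factors)
    inh = ilcr_inhalation(c, profile, factors)
    derm = ilcr_dermal(c, profile, factors)
    tot = total_ilcr(ing, inh, derm)
    intake = edi(c, profile, factors.cf)
    hq = hazard_quotient(intake, factors.rfd)
    cancer, noncancer = classify_risk(tot, hq)
    return RiskResult(
        receptor=profile.receptor,
        concentration=c,
        ilcr_ingestion=ing,
        ilcr_inhalation=inh,
        ilcr_dermal=derm,
        ilcr_total=tot,
        edi=intake,
        hq=hq,
        cancer_exceeds=cancer,
        noncancer_exceeds=noncancer,
    )


def load_exposure_config(
    path: str | Path | None = None,
) -> tuple[dict[str, ExposureProfile], SlopeFactors]:
    """Load exposure profiles and slope factors from a YAML config.

    With no *path*, the packaged defaults are used.  The file must contain
    ``receptors`` (mapping receptor -> parameter block), ``slope_factors``
    and ``noncancer`` (rfd, cf) sections.
    """
    if path is None:
        with resources.as_file(
            resources.files("pahrisk.data").joinpath("exposure_defaults.yaml")
        ) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    try:
        receptors = {
            name: ExposureProfile(
                receptor=name,
                ir_ing=block["ir_ing"],
                ir_inh=block["ir_inh"],
                sa=block["sa"],
                af=block["af"],
                abs_frac=block["abs"],
                ef=block["ef"],
                ed=block["ed"],
                bw=block["bw"],
                at=block["at"],
            )
            for name, block in raw["receptors"].items()
        }
        sf = raw["slope_factors"]
        nc = raw["noncancer"]
        factors = SlopeFactors(
            csf_ing=float(sf["csf_ing"]),
            csf_inh=float(sf["csf_inh"]),
            csf_derm=float(sf["csf_derm"]),
            pef=float(sf["pef"]),
            rfd=float(nc["rfd"]),
            cf=float(nc.get("cf", 1.0)),
            unit_factor=float(sf.get("unit_factor", 1e6)),
        )
    except KeyError as e:
        raise ProfileError(f"exposure config missing key: {e}") from None
    return receptors, factors


def default_profiles() -> tuple[ExposureProfile, ExposureProfile, SlopeFactors]:
    """Packaged adult and child profiles plus slope factors."""
    receptors, factors = load_exposure_config()
    return receptors["adult"], receptors["child"], factors


Receptor = Literal["adult", "child"]
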