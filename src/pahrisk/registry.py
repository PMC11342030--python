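"""Registry of priority PAH compounds and their toxicity metadata.

Each entry carries the compound's abbreviation, full name, number of fused
aromatic rings, molecular-weight class, toxicity equivalence factor (TEF,
potency relative to benzo[a]pyrene) and whether it belongs to the seven-member
carcinogenic set (USEPA class B2).

The default registry ships the 16 USEPA priority PAHs with the Nisbet & LaGoy
(1992) TEF scheme, plus benzo[e]pyrene behind an opt-in flag.  The registry is
data-driven (a packaged CSV) so alternative TEF schemes can be supplied
without code changes.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "PAHCompound",
    "CompoundRegistry",
    "UnknownCompoundError",
    "default_registry",
    "mw_class_for_rings",
    "ring_class",
]

#: Ring counts considered valid for a fused-ring PAH.
_VALID_RINGS = {2, 3, 4, 5, 6}


class UnknownCompoundError(KeyError):
    """Raised when a compound abbreviation is not present in the registry."""

    def __init__(self, abbreviation: str):
        super().__init__(abbreviation)
        self.abbreviation = abbreviation

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown PAH compound abbreviation: {self.abbreviation!r}"


def mw_class_for_rings(n_rings: int) -> str:
    """Molecular-weight class implied by the ring count.

    2-3 rings -> LMW, 4 rings -> MMW, 5-6 rings -> HMW.
    """
    if n_rings in (2, 3):
        return "LMW"
    if n_rings == 4:
        return "MMW"
    if n_rings in (5, 6):
        return "HMW"
    raise ValueError(f"invalid ring count: {n_rings}")


@dataclasses.dataclass(frozen=True)
class PAHCompound:
    """Metadata for one PAH compound.

    Attributes
    ----------
    abbreviation : str
        Short code, e.g. ``"BaP"``.
    full_name : str
        IUPAC-style name, e.g. ``"benzo[a]pyrene"``.
    n_rings : int
        Number of fused aromatic rings (2-6).
    tef : float
        Toxicity equivalence factor relative to benzo[a]pyrene (BaP = 1).
    carcinogenic : bool
        Membership in the 7-compound carcinogenic set.
    """

    abbreviation: str
    full_name: str
    n_rings: int
    tef: float
    carcinogenic: bool

    def __post_init__(self) -> None:
        if self.n_rings not in _VALID_RINGS:
            raise ValueError(
                f"{self.abbreviation}: n_rings must be in {sorted(_VALID_RINGS)}, "
                f"got {self.n_rings}"
            )
        if not 0 <= self.tef <= 1:
            raise ValueError(f"{self.abbreviation}: tef must lie in [0, 1], got {self.tef}")

    @property
    def mw_class(self) -> str:
        """Molecular-weight class (LMW/MMW/HMW), a pure function of n_rings."""
        return mw_class_for_rings(self.n_rings)


class CompoundRegistry(Mapping[str, PAHCompound]):
    """Ordered, immutable lookup of :class:`PAHCompound` by abbreviation."""

    def __init__(self, compounds: Iterator[PAHCompound] | list[PAHCompound]):
        self._compounds: dict[str, PAHCompound] = {}
        for c in compounds:
            if c.abbreviation in self._compounds:
                raise ValueError(f"duplicate compound abbreviation: {c.abbreviation!r}")
            self._compounds[c.abbreviation] = c

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, abbreviation: str) -> PAHCompound:
        try:
            return self._compounds[abbreviation]
        except KeyError:
            raise UnknownCompoundError(abbreviation) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._compounds)

    def __len__(self) -> int:
        return len(self._compounds)

    # Convenience ----------------------------------------------------------
    @property
    def abbreviations(self) -> list[str]:
        return list(self._compounds)

    @property
    def carcinogenic(self) -> list[str]:
        """Abbreviations of the compounds flagged carcinogenic."""
        return [a for a, c in self._compounds.items() if c.carcinogenic]

    def tefs(self) -> pd.Series:
        """TEF per compound, indexed by abbreviation."""
        return pd.Series({a: c.tef for a, c in self._compounds.items()}, name="tef")

    @classmethod
    def from_csv(cls, path: str | Path, include_disabled: bool = False) -> "CompoundRegistry":
        """Load a registry from a CSV with columns
        ``abbreviation, full_name, n_rings, tef, carcinogenic[, enabled]``.

        Rows with ``enabled`` false are skipped unless *include_disabled*.
        """
        df = pd.read_csv(path)
        required = {"abbreviation", "full_name", "n_rings", "tef", "carcinogenic"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry file {path} missing columns: {sorted(missing)}")
        if "enabled" in df.columns and not include_disabled:
            df = df[df["enabled"].astype(str).str.lower().isin(["true", "1", "yes"])]
        compounds = [
            PAHCompound(
                abbreviation=str(r.abbreviation),
                full_name=str(r.full_name),
                n_rings=int(r.n_rings),
                tef=float(r.tef),
                carcinogenic=str(r.carcinogenic).lower() in ("true", "1", "yes"),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(compounds)


def default_registry(include_bep: bool = False) -> CompoundRegistry:
    """The packaged registry: 16 priority PAHs, Nisbet-LaGoy TEFs.

    Parameters
    ----------
    include_bep : bool
        Also register benzo[e]pyrene (TEF 0, non-carcinogenic).  Disabled by
        default so that totals over the registry cover exactly the 16
        priority compounds.
    """
    with resources.as_file(
        resources.files("pahrisk.data").joinpath("pah_registry.csv")
    ) as p:
        return CompoundRegistry.from_csv(p, include_disabled=include_bep)


def ring_class(registry: CompoundRegistry, abbreviation: str) -> int:
    """Number of fused aromatic rings for a registered compound."""
    return registry[abbreviation].n_rings
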