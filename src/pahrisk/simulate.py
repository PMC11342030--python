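"""Seeded synthetic soil-PAH datasets.

Soil contaminant concentrations are non-negative and right-skewed, so each
cell is drawn from an independent lognormal whose parameters are solved so
that the *arithmetic* mean equals the compound's target:

    E[X] = exp(mu + sigma^2 / 2) = m   =>   mu = ln(m) - sigma^2 / 2.

The default profile targets the bundled reference survey means (a
HMW-dominant mixture from automobile-workshop soils), so a simulated site
run through the summary -> TEQ -> risk pipeline recovers the reference
results up to sampling error.  Compounds with a zero target mean are
identically zero; independence across compounds is assumed (no covariance
information is available for the reference survey).
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .concentrations import ConcentrationTable
from .registry import CompoundRegistry, default_registry

__all__ = ["SiteProfile", "default_profile", "generate_site", "reference_means"]


def reference_means() -> pd.Series:
    """Per-compound mean concentrations (ug/g) of the bundled reference
    survey, indexed by abbreviation."""
    with resources.as_file(
        resources.files("pahrisk.data").joinpath("reference_site_summary.csv")
    ) as p:
        df = pd.read_csv(p, index_col="compound")
    return df["mean"]


@dataclasses.dataclass(frozen=True)
class SiteProfile:
    """Target marginals for one synthetic site.

    ``compound_means`` maps abbreviation -> target arithmetic mean in ug/g;
    ``dispersion`` is the lognormal shape sigma (log-scale standard
    deviation), either one global value or one per compound; ``n_locations``
    is the number of sampling locations to draw; ``seed`` fixes the RNG.
    """

    compound_means: Mapping[str, float]
    dispersion: float | Mapping[str, float] = 0.5
    n_locations: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.compound_means:
            raise ValueError("compound_means must be non-empty")
        for a, m in self.compound_means.items():
            if m < 0 or not math.isfinite(m):
                raise ValueError(f"target mean for {a} must be finite and >= 0, got {m}")
        for a, s in self._sigmas().items():
            if s < 0 or not math.isfinite(s):
                raise ValueError(f"dispersion for {a} must be finite and >= 0, got {s}")
        if self.n_locations < 1:
            raise ValueError(f"n_locations must be >= 1, got {self.n_locations}")

    def _sigmas(self) -> dict[str, float]:
        if isinstance(self.dispersion, Mapping):
            missing = set(self.compound_means) - set(self.dispersion)
            if missing:
                raise ValueError(f"dispersion missing compounds: {sorted(missing)}")
            return {a: float(self.dispersion[a]) for a in self.compound_means}
        return {a: float(self.dispersion) for a in self.compound_means}


def default_profile(
    n_locations: int = 5,
    dispersion: float = 0.5,
    seed: int | None = None,
) -> SiteProfile:
    """Profile targeting the bundled reference survey means (HMW-dominant)."""
    return SiteProfile(
        compound_means=reference_means().to_dict(),
        dispersion=dispersion,
        n_locations=n_locations,
        seed=seed,
    )


def generate_site(
    profile: SiteProfile, registry: CompoundRegistry | None = None
) -> ConcentrationTable:
    """Draw a locations x compounds concentration table from *profile*.

    Each cell is lognormal with mu = ln(m) - sigma^2/2 so its expectation is
    the target mean m; sigma = 0 degenerates to every location sitting
    exactly at the mean, and m = 0 yields an identically-zero column.
    Reproducible under a fixed seed.
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(profile.seed)
    sigmas = profile._sigmas()
    n = profile.n_locations
    cols: dict[str, np.ndarray] = {}
    for abbrev, m in profile.compound_means.items():
        sigma = sigmas[abbrev]
        if m == 0:
            cols[abbrev] = np.zeros(n)
        elif sigma == 0:
            cols[abbrev] = np.full(n, m)
        else:
            mu = math.log(m) - sigma**2 / 2.0
            cols[abbrev] = rng.lognormal(mean=mu, sigma=sigma, size=n)
    index = pd.Index([f"L{i + 1}" for i in range(n)], name="location")
    return ConcentrationTable(pd.DataFrame(cols, index=index), registry)
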