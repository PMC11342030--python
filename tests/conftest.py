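import numpy as np
import pandas as pd
import pytest

import pahrisk as pr

# Per-compound mean soil concentrations (ug/g) of the bundled reference
# survey, frozen here independently of the packaged CSV so tests notice if
# the shipped data drifts.
REFERENCE_MEANS = {
    "Naph": 1.65, "Acy": 3.36, "Acen": 5.36, "Fln": 10.81, "Phe": 3.55,
    "Ant": 3.38, "Flt": 5.17, "Pyr": 6.67, "BbF": 17.30, "BkF": 17.53,
    "CHR": 3.24, "BaP": 5.39, "BaA": 2.45, "IcP": 5.83, "DhA": 6.68,
    "BgP": 0.0,
}

# TEQ column of the reference survey as printed (3 dp).
REFERENCE_TEQ = {
    "Naph": 0.002, "Acy": 0.003, "Acen": 0.005, "Fln": 0.011, "Phe": 0.004,
    "Ant": 0.034, "Flt": 0.005, "Pyr": 0.007, "BbF": 1.730, "BkF": 1.753,
    "CHR": 0.032, "BaP": 5.390, "BaA": 0.245, "IcP": 0.583, "DhA": 6.680,
    "BgP": 0.000,
}


@pytest.fixture(scope="session")
def registry():
    return pr.default_registry()


@pytest.fixture(scope="session")
def reference_means():
    return pd.Series(REFERENCE_MEANS)


@pytest.fixture(scope="session")
def profiles():
    adult, child, factors = pr.default_profiles()
    return {"adult": adult, "child": child, "factors": factors}


@pytest.fixture()
def degenerate_table(registry, reference_means):
    """Five identical locations sitting exactly at the reference means."""
    data = pd.DataFrame(
        np.tile(reference_means.to_numpy(), (5, 1)),
        index=pd.Index([f"L{i}" for i in range(1, 6)], name="location"),
        columns=reference_means.index,
    )
    return pr.ConcentrationTable(data, registry)


@pytest.fixture()
def small_table(registry):
    """Tiny hand-checkable table: 3 locations x 2 compounds."""
    data = pd.DataFrame(
        {"BaP": [1.0, 2.0, 3.0], "Naph": [4.0, 4.0, 4.0]},
        index=pd.Index(["a", "b", "c"], name="location"),
    )
    return pr.ConcentrationTable(data, registry)
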