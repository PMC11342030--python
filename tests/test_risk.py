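"""Route-specific cancer-risk and hazard-quotient equations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pahrisk as pr
from pahrisk.risk import ExposureProfile, ProfileError, SlopeFactors

# Route ILCRs at C = 98.37 mg/kg (sum of the reference-survey means),
# frozen from a direct arithmetic evaluation of the screening equations
# outside the package.
ORACLE_C = 98.37
ORACLE = {
    ("adult", "ingestion"): 3.8979107e-4,
    ("child", "ingestion"): 4.3489831e-4,
    ("adult", "dermal"): 6.9241311e-4,
    ("child", "dermal"): 5.4213351e-4,
    ("adult", "inhalation"): 3.0231580e-8,
    ("child", "inhalation"): 8.4325065e-9,
}

ROUTE_FN = {
    "ingestion": pr.ilcr_ingestion,
    "inhalation": pr.ilcr_inhalation,
    "dermal": pr.ilcr_dermal,
}


@pytest.mark.parametrize("bw,expected", [(70.0, 1.0), (60.0, 0.9499), (18.0, 0.6359)])
def test_bw_adjustment_cube_root(bw, expected):
    assert pr.bw_adjustment(bw) == pytest.approx(expected, abs=1e-4)


def test_bw_adjustment_rejects_nonpositive():
    with pytest.raises(ValueError):
        pr.bw_adjustment(0.0)


@pytest.mark.parametrize("receptor,route", sorted(ORACLE))
def test_route_ilcr_matches_arithmetic_oracle(profiles, receptor, route):
    value = ROUTE_FN[route](ORACLE_C, profiles[receptor], profiles["factors"])
    assert value == pytest.approx(ORACLE[(receptor, route)], rel=1e-6)


@pytest.mark.parametrize("route", sorted(ROUTE_FN))
def test_zero_concentration_gives_zero_risk(profiles, route):
    assert ROUTE_FN[route](0.0, profiles["adult"], profiles["factors"]) == 0.0


def test_negative_concentration_rejected(profiles):
    with pytest.raises(ValueError, match="non-negative"):
        pr.ilcr_ingestion(-1.0, profiles["adult"], profiles["factors"])


def test_doubling_pef_halves_inhalation_risk(profiles):
    f = profiles["factors"]
    doubled = SlopeFactors(
        csf_ing=f.csf_ing, csf_inh=f.csf_inh, csf_derm=f.csf_derm,
        pef=2 * f.pef, rfd=f.rfd, cf=f.cf, unit_factor=f.unit_factor,
    )
    base = pr.ilcr_inhalation(10.0, profiles["adult"], f)
    assert pr.ilcr_inhalation(10.0, profiles["adult"], doubled) == pytest.approx(base / 2)


def test_total_is_sum_of_routes(profiles):
    r = pr.assess(ORACLE_C, profiles["adult"], profiles["factors"])
    assert r.ilcr_total == pytest.approx(
        r.ilcr_ingestion + r.ilcr_inhalation + r.ilcr_dermal, rel=1e-15
    )
    assert r.ilcr_total == pytest.approx(1.08e-3, rel=0.01)


def _profile(**overrides):
    base = dict(
        receptor="x", ir_ing=100, ir_inh=20, sa=5700, af=0.07,
        abs_frac=0.13, ef=365, ed=24, bw=60, at=25550,
    )
    base.update(overrides)
    return ExposureProfile(**base)


@settings(deadline=None, max_examples=50)
@given(
    c=st.floats(1e-3, 1e4),
    scale=st.floats(1.1, 4.0),
)
def test_risk_monotone_in_concentration_exposure_and_bodyweight(profiles, c, scale):
    """ILCR routes are linear in C, EF and ED; heavier receptors carry
    strictly lower ingestion/dermal risk (BW^(1/3 - 1) net exponent)."""
    f = profiles["factors"]
    p = _profile()
    base = pr.ilcr_ingestion(c, p, f)
    assert pr.ilcr_ingestion(scale * c, p, f) == pytest.approx(scale * base, rel=1e-9)
    p_ed = _profile(ed=24 / scale, at=25550)
    assert pr.ilcr_ingestion(c, p_ed, f) == pytest.approx(base / scale, rel=1e-9)
    p_ef = _profile(ef=365 / scale)
    assert pr.ilcr_ingestion(c, p_ef, f) == pytest.approx(base / scale, rel=1e-9)
    p_heavy = _profile(bw=60 * scale)
    assert pr.ilcr_ingestion(c, p_heavy, f) < base
    assert pr.ilcr_dermal(c, p_heavy, f) < pr.ilcr_dermal(c, p, f)


def test_edi_matches_hand_evaluation(profiles):
    # 98.34 * 100 * 24 * 365 / (25550 * 60) and the child analogue
    assert pr.edi(98.34, profiles["adult"], cf=1.0) == pytest.approx(56.194, abs=1e-3)
    assert pr.edi(98.34, profiles["child"], cf=1.0) == pytest.approx(93.657, abs=1e-3)
    assert pr.edi(0.0, profiles["adult"]) == 0.0


def test_hazard_quotient_ratio_and_domain():
    assert pr.hazard_quotient(1.0, 1.0) == 1.0
    assert pr.hazard_quotient(56.194, 2.0e-3) == pytest.approx(28097.0, rel=1e-4)
    with pytest.raises(ValueError):
        pr.hazard_quotient(1.0, 0.0)


@settings(deadline=None, max_examples=50)
@given(k=st.floats(1e-3, 1e3), c=st.floats(0, 1e3))
def test_hq_invariant_under_joint_unit_rescaling(profiles, k, c):
    """Multiplying CF and RfD by the same factor leaves HQ unchanged."""
    p = profiles["adult"]
    rfd = 2.0e-3
    hq1 = pr.hazard_quotient(pr.edi(c, p, cf=1.0), rfd)
    hq2 = pr.hazard_quotient(pr.edi(c, p, cf=k) if c > 0 else 0.0, rfd * k)
    assert hq2 == pytest.approx(hq1, rel=1e-9, abs=1e-12)


def test_classification_thresholds_are_strict():
    assert pr.classify_risk(2e-6, 2.0) == (True, True)
    assert pr.classify_risk(1e-7, 0.5) == (False, False)
    # values exactly at a threshold do not flag
    assert pr.classify_risk(1e-6, 1.0) == (False, False)


@pytest.mark.parametrize(
    "overrides,match",
    [
        (dict(bw=-5), "positive"),
        (dict(abs_frac=1.5), "abs_frac"),
        (dict(ef=400), "366"),
        (dict(at=100), "averaging time"),
    ],
)
def test_profile_validation(overrides, match):
    with pytest.raises(ProfileError, match=match):
        _profile(**overrides)


def test_packaged_exposure_defaults(profiles):
    a, c, f = profiles["adult"], profiles["child"], profiles["factors"]
    assert (a.ir_ing, a.ir_inh, a.sa, a.af, a.ed, a.bw) == (100, 20, 5700, 0.07, 24, 60)
    assert (c.ir_ing, c.ir_inh, c.sa, c.af, c.ed, c.bw) == (200, 10, 2800, 0.2, 6, 18)
    assert a.abs_frac == c.abs_frac == 0.13
    assert a.ef == c.ef == 365 and a.at == c.at == 25550
    assert (f.csf_ing, f.csf_inh, f.csf_derm) == (7.3, 3.85, 25)
    assert f.pef == 1.36e9 and f.unit_factor == 1e6
    assert f.rfd == 2.0e-3 and f.cf == 1.0
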