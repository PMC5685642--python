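"""Integration, conservation laws, initial rates, stoichiometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tyrokin import (AssayConditions, ProgressCurve, WindowPolicy,
                     build_deoxyarbutin_scheme, build_release_oxidize_variant,
                     constant_set, enzyme_split, initial_rate, integrate,
                     rate_vs_substrate, run_until_oxygen_depleted,
                     stoichiometry_ratio, v0_full)

ENZ = ("E_m", "E_d", "E_ox", "E_oxD-Arb", "E_mD-ArbOH", "E_mD-Arb")


def test_no_substrate_no_product(base_scheme):
    cond = AssayConditions({**enzyme_split(3e-7), "O2": 0.26e-3,
                            "H2O2": 1.25e-6}, 60.0)
    curve = integrate(base_scheme, cond, grid=200)
    # zero up to integrator dust, far below the absolute tolerance
    assert np.all(np.abs(curve["P"]) <= curve.provenance["atol"])


def test_conservation_laws(short_curve):
    """Total enzyme and total phenolic moiety are conserved along the
    trajectory to within ten times the absolute solver tolerance."""
    atol = short_curve.provenance["atol"]
    e_tot = sum(short_curve[name] for name in ENZ)
    assert np.all(np.abs(e_tot - e_tot[0]) < 10 * atol + 1e-9 * e_tot[0])
    darb = (short_curve["D-Arb"] + short_curve["E_oxD-Arb"]
            + short_curve["E_mD-ArbOH"] + short_curve["E_mD-Arb"]
            + short_curve["P"])
    assert np.all(np.abs(darb - darb[0]) < 10 * atol + 1e-9 * darb[0])


def test_product_rises_and_plateaus_at_oxygen_exhaustion(base_scheme,
                                                         fig4b_conditions):
    curve, summary = run_until_oxygen_depleted(base_scheme, fig4b_conditions)
    p = curve["P"]
    assert np.all(np.diff(p) >= -1e-15)          # monotone accumulation
    assert summary["P_final_M"] == pytest.approx(0.26e-3, rel=0.02)
    late = (p[-1] - p[-200]) / (curve.time[-1] - curve.time[-200])
    early = (p[200] - p[0]) / curve.time[200]
    assert late < 0.1 * early                     # plateau


def test_stoichiometry_one_to_one(base_scheme, fig4b_conditions):
    curve, summary = run_until_oxygen_depleted(base_scheme, fig4b_conditions)
    assert stoichiometry_ratio(curve) == pytest.approx(1.0, abs=0.01)


def test_stoichiometry_requires_oxygen_consumption(short_curve):
    frozen = ProgressCurve(short_curve.time[:5],
                           np.tile(short_curve.concentrations[:, :1], 5),
                           short_curve.species, dict(short_curve.provenance),
                           short_curve.roles)
    with pytest.raises(ValueError, match="no oxygen consumed"):
        stoichiometry_ratio(frozen)


def test_release_variant_ratio_at_least_one():
    """The immediate-oxidation variant makes extra product without O2
    bookkeeping on the k19 step, so P per O2 is >= 1."""
    scheme = build_release_oxidize_variant(constant_set("s8"))
    cond = AssayConditions({**enzyme_split(7.5e-7), "D-Arb": 0.4e-3,
                            "O2": 0.26e-3, "H2O2": 1.25e-6}, 600.0)
    curve = integrate(scheme, cond, grid=500)
    assert stoichiometry_ratio(curve) >= 1.0


def test_oxygen_depletion_event_edge_cases(base_scheme, fig4b_conditions):
    cond0 = fig4b_conditions.replace_initial(O2=0.0)
    curve, summary = run_until_oxygen_depleted(base_scheme, cond0)
    assert summary["t_depleted_s"] == 0.0
    from tyrokin.simulate import IntegrationError
    cond_short = AssayConditions(fig4b_conditions.initial, 10.0)
    with pytest.raises(IntegrationError, match="did not reach"):
        run_until_oxygen_depleted(base_scheme, cond_short)


def test_initial_rate_exact_line(short_curve):
    """A synthetic exactly-linear trace returns its slope to machine
    precision under every window policy."""
    t = np.linspace(0.0, 10.0, 500)
    a = 3.2e-9
    fake = ProgressCurve(t, np.vstack([a * t]), ("P",), {"atol": 1e-12})
    for policy in (WindowPolicy(), WindowPolicy(mode="max_slope"),
                   WindowPolicy(mode="fixed", fixed_window=(1.0, 9.0))):
        est = initial_rate(fake, "P", policy)
        assert est.rate == pytest.approx(a, rel=1e-9)


def test_initial_rate_window_too_short(short_curve):
    with pytest.raises(ValueError, match="3 samples"):
        initial_rate(short_curve, "P",
                     WindowPolicy(mode="fixed", fixed_window=(0.0, 0.01)))


def test_initial_rate_matches_steady_state_prediction(base_scheme, fig4_params):
    """QSSA agreement: with enzyme three orders below substrate the
    extracted initial rate matches the closed-form rate within 5%."""
    cond = AssayConditions({**enzyme_split(1e-7), "D-Arb": 2e-4,
                            "O2": 0.26e-3, "H2O2": 1.25e-6}, 120.0)
    curve = integrate(base_scheme, cond, grid=2000)
    est = initial_rate(curve, "P")
    ref = v0_full(fig4_params, 2e-4, 0.26e-3, 1.25e-6, 1e-7)
    assert est.rate == pytest.approx(ref, rel=0.05)


def test_rate_vs_substrate_shape_and_enzyme_linearity(base_scheme):
    base = AssayConditions({**enzyme_split(3e-7), "O2": 0.26e-3,
                            "H2O2": 1.25e-6}, 60.0)
    levels = [2e-5, 1e-4, 5e-4]
    t1 = rate_vs_substrate(base_scheme, base, "D-Arb", levels, grid=1500)
    assert np.all(np.diff(t1["v0_M_per_s"]) > 0)  # monotone in substrate
    # enzyme linearity holds where the enzyme binds a negligible share of
    # the substrate (E0 << S); one shared post-transient window removes
    # depletion bias between the runs
    shared = WindowPolicy(mode="fixed", fixed_window=(0.5, 5.0))
    lin_levels = [1e-4, 5e-4, 1e-3]
    small = AssayConditions({**enzyme_split(1e-7), "O2": 0.26e-3,
                             "H2O2": 1.25e-6}, 60.0)
    doubled = AssayConditions({**enzyme_split(2e-7), "O2": 0.26e-3,
                               "H2O2": 1.25e-6}, 60.0)
    t1w = rate_vs_substrate(base_scheme, small, "D-Arb", lin_levels, grid=1500,
                            window=shared)
    t2w = rate_vs_substrate(base_scheme, doubled, "D-Arb", lin_levels, grid=1500,
                            window=shared)
    ratio = t2w["v0_M_per_s"] / t1w["v0_M_per_s"]
    assert np.allclose(ratio, 2.0, rtol=0.02)     # linear in enzyme

    with pytest.raises(ValueError, match="distinct"):
        rate_vs_substrate(base_scheme, base, "D-Arb", [1e-4, 1e-4])
    with pytest.raises(ValueError, match="empty"):
        rate_vs_substrate(base_scheme, base, "D-Arb", [])


def test_explicit_and_stiff_integrators_agree(base_scheme, fig4b_conditions):
    """LSODA and the explicit adaptive Runge-Kutta produce the same
    trajectory of the oxygen-exhaustion problem to 1e-6 relative (both run
    at tightened tolerances so solver error does not mask disagreement)."""
    cond = AssayConditions(fig4b_conditions.initial, 120.0)
    kw = dict(grid=200, rtol=1e-10, atol=1e-14)
    a = integrate(base_scheme, cond, method="LSODA", **kw)
    b = integrate(base_scheme, cond, method="RK45", **kw)
    scale = np.abs(a.concentrations).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    assert np.max(np.abs(a.concentrations - b.concentrations) / scale) < 1e-6


def test_preincubation_two_phase(base_scheme):
    """A zero-length pre-incubation is a no-op; a one-minute H2O2
    pre-incubation raises the subsequent initial rate."""
    main = {"D-Arb": 2e-4, "O2": 0.26e-3}
    plain = AssayConditions({**enzyme_split(5e-7), **main, "H2O2": 1.25e-6}, 60.0)
    pre0 = AssayConditions({**main},
                           60.0,
                           preincubation=AssayConditions(
                               {**enzyme_split(5e-7), "H2O2": 1.25e-6}, 1e-6))
    v_plain = initial_rate(integrate(base_scheme, plain, grid=1000), "P").rate
    v_pre0 = initial_rate(integrate(base_scheme, pre0, grid=1000), "P").rate
    assert v_pre0 == pytest.approx(v_plain, rel=1e-3)
    pre = AssayConditions({**main}, 60.0,
                          preincubation=AssayConditions(
                              {**enzyme_split(5e-7), "H2O2": 2e-5}, 60.0))
    v_act = initial_rate(integrate(base_scheme, pre, grid=1000), "P").rate
    assert v_act > 2.0 * v_plain


@settings(max_examples=10, deadline=None, derandomize=True)
@given(s0=st.floats(1e-6, 1e-3), e0=st.floats(1e-8, 2e-6),
       h0=st.floats(1e-8, 1e-4))
def test_enzyme_conservation_property(s0, e0, h0):
    """Enzyme-moiety conservation holds for arbitrary initial conditions."""
    scheme = build_deoxyarbutin_scheme(constant_set("fig4"))
    cond = AssayConditions({**enzyme_split(e0), "D-Arb": s0,
                            "O2": 0.26e-3, "H2O2": h0}, 30.0)
    curve = integrate(scheme, cond, grid=60)
    e_tot = sum(curve[name] for name in ENZ)
    assert np.all(np.abs(e_tot - e_tot[0]) < 1e-12 + 1e-8 * e_tot[0])


def test_conditions_validation():
    with pytest.raises(ValueError, match="negative"):
        AssayConditions({"D-Arb": -1e-4}, 10.0)
    with pytest.raises(ValueError, match="duration"):
        AssayConditions({"D-Arb": 1e-4}, 0.0)
    with pytest.raises(ValueError, match="sum to 1"):
        enzyme_split(1e-6, f_ox=0.5, f_m=0.2)
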