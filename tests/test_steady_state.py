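"""Closed-form rate law: coefficient oracle, limits, derived constants."""

import numpy as np
import pytest

from tyrokin import (constant_set, derived_constants, eox_fraction,
                     eq1_coefficients, km_from_constants, re_from_h2o2,
                     v0_full, v0_michaelis, v0_oxygen_saturated)
from tyrokin.constants import RateConstants

FIG5_LABELS = ("k8", "k-8", "k9", "k-9", "k10", "k11", "k12", "k-12", "k15", "k-15")


def _params(**vals):
    return RateConstants(dict(vals), "test")


def _unit_set(value=1.0):
    return _params(**{lab: value for lab in FIG5_LABELS})


def qssa_rate_numeric(params, S, O2, H2O2, E0):
    """Independent oracle: exact linear solve of the six enzyme-form
    balances at fixed ligand concentrations; rate = k11 * [E_mD-ArbOH]."""
    k = params
    # forms: Em, Ed, Eox, EoxS, EmSOH, EmS
    A = np.zeros((6, 6))
    def add(rate, src, dst):
        A[src, src] -= rate
        if dst is not None:
            A[dst, src] += rate
    add(k["k15"] * H2O2, 0, 2); add(k["k-15"], 2, 0)
    add(k["k8"] * O2, 1, 2);    add(k["k-8"], 2, 1)
    add(k["k9"] * S, 2, 3);     add(k["k-9"], 3, 2)
    add(k["k10"], 3, 4)
    add(k["k11"], 4, 1)
    add(k["k12"] * S, 0, 5);    add(k["k-12"], 5, 0)
    B = np.vstack([A[:-1], np.ones(6)])
    b = np.zeros(6); b[-1] = E0
    x = np.linalg.solve(B, b)
    return k["k11"] * x[4]


def test_unit_constants_coefficients():
    """With every constant set to 1 the seven products collapse to the
    frozen pattern (the k-9 + k10 and k10 + k11 sums each equal 2)."""
    c = eq1_coefficients(_unit_set())
    assert (c.alpha1, c.beta1, c.beta2, c.beta3, c.beta4, c.beta5, c.beta6) \
        == (1.0, 2.0, 2.0, 1.0, 2.0, 2.0, 2.0)


def test_zero_constant_zeroes_coefficients_without_error():
    c = eq1_coefficients(_unit_set().updated(k8=0.0))
    assert c.alpha1 == 0.0 and c.beta2 == 0.0 and c.beta1 > 0


def test_coefficients_match_linear_solve_oracle(rng):
    """The closed-form products equal the exact enzyme-form elimination for
    100 random positive constant sets (log-uniform over 6 decades)."""
    for _ in range(100):
        vals = {lab: float(10 ** rng.uniform(-2, 4)) for lab in FIG5_LABELS}
        params = _params(**vals)
        S, O2, H2O2, E0 = (float(10 ** rng.uniform(-6, -3)) for _ in range(4))
        direct = v0_full(params, S, O2, H2O2, E0)
        oracle = qssa_rate_numeric(params, S, O2, H2O2, E0)
        assert direct == pytest.approx(oracle, rel=1e-9)


def test_coefficients_match_symbolic_elimination():
    """One-shot symbolic check: solving the balance equations with sympy
    reproduces the implemented coefficient products exactly."""
    sp = pytest.importorskip("sympy")
    syms = {lab: sp.Symbol(lab.replace("-", "m"), positive=True)
            for lab in FIG5_LABELS}
    S, O2, H, E0 = sp.symbols("S O2 H E0", positive=True)
    Em, Ed, Eox, EoxS, EmSOH, EmS = sp.symbols("Em Ed Eox EoxS EmSOH EmS")
    k = syms
    eqs = [
        sp.Eq(-k["k15"] * Em * H + k["k-15"] * Eox - k["k12"] * Em * S
              + k["k-12"] * EmS, 0),
        sp.Eq(k["k11"] * EmSOH - k["k8"] * Ed * O2 + k["k-8"] * Eox, 0),
        sp.Eq(k["k9"] * Eox * S - (k["k-9"] + k["k10"]) * EoxS, 0),
        sp.Eq(k["k10"] * EoxS - k["k11"] * EmSOH, 0),
        sp.Eq(k["k12"] * Em * S - k["k-12"] * EmS, 0),
        sp.Eq(Em + Ed + Eox + EoxS + EmSOH + EmS, E0),
    ]
    sol = sp.solve(eqs, [Em, Ed, Eox, EoxS, EmSOH, EmS], dict=True)[0]
    v = sp.cancel(k["k11"] * sol[EmSOH])

    # the implemented coefficient products, rebuilt symbolically
    a1 =k["k8"] * k["k9"] * k["k10"] * k["k11"] * k["k-12"] * k["k15"]
    b1 = k["k-8"] * k["k11"] * k["k-12"] * k["k15"] * (k["k-9"] + k["k10"])
    b2 = k["k8"] * k["k11"] * k["k-12"] * k["k-15"] * (k["k-9"] + k["k10"])
    b3 = k["k9"] * k["k10"] * k["k11"] * k["k-12"] * k["k15"]
    b4 = k["k8"] * k["k11"] * k["k12"] * k["k-15"] * (k["k-9"] + k["k10"])
    b5 = k["k8"] * k["k11"] * k["k-12"] * k["k15"] * (k["k-9"] + k["k10"])
    b6 = k["k8"] * k["k9"] * k["k-12"] * k["k15"] * (k["k10"] + k["k11"])
    closed = a1 * S * O2 * H * E0 / (b1 * H + b2 * O2 + b3 * H * S
                                     + b4 * S * O2 + b5 * H * O2 + b6 * H * O2 * S)
    assert sp.simplify(v - closed) == 0


def test_rate_law_edge_cases(fig4_params):
    assert v0_full(fig4_params, 0.0, 2.6e-4, 1.25e-6, 3e-7) == 0.0
    with pytest.raises(ZeroDivisionError):
        v0_full(fig4_params, 0.0, 0.0, 0.0, 3e-7)
    with pytest.raises(ValueError):
        v0_full(fig4_params, -1e-4, 2.6e-4, 1.25e-6, 3e-7)


def test_km_from_printed_constants():
    km = km_from_constants(1.6e5, 3.8, 1.5)
    assert km == pytest.approx(3.3125e-5)
    assert km * 1e3 == pytest.approx(0.033, abs=5e-4)  # printed 0.033 mM
    assert km_from_constants(1.0, 0.0, 1.0) == 1.0
    assert km_from_constants(1.6e5, 3.8, 0.0) == pytest.approx(3.8 / 1.6e5)
    with pytest.raises(ZeroDivisionError):
        km_from_constants(0.0, 3.8, 1.5)


def test_resting_partition():
    assert re_from_h2o2(2e6, 10.0, 1.25e-6) == pytest.approx(4.0)
    assert re_from_h2o2(2e6, 10.0, 5e-6) == pytest.approx(1.0)  # H2O2 = K15
    assert re_from_h2o2(2e6, 10.0, 1.0) == pytest.approx(5e-6, rel=1e-12)
    with pytest.raises(ZeroDivisionError):
        re_from_h2o2(2e6, 10.0, 0.0)
    assert eox_fraction(4.0) == pytest.approx(0.2)
    assert eox_fraction(0.0) == 1.0
    assert eox_fraction(1.0) == 0.5


def test_limit_chain_full_to_oxygen_saturated(fig4_params):
    """As O2 grows the full law converges on the oxygen-saturated form
    (un-simplified variant) to better than 1e-3 relative."""
    S, H, E0 = 2e-4, 1.25e-6, 3e-7
    sat = v0_oxygen_saturated(fig4_params, S, H, E0, simplified=False)
    full = v0_full(fig4_params, S, 1e3 * 1e-3, H, E0)  # O2 = 1 M >> K8
    assert full == pytest.approx(sat, rel=1e-3)


def test_limit_chain_k11_dominates_k10():
    """The printed simplification drops k10 against k11; with k11/k10 = 1e4
    the two oxygen-saturated forms agree to 1e-3."""
    params = constant_set("fig4").updated(k11=1.5e4 * 1.0)
    a = v0_oxygen_saturated(params, 2e-4, 1.25e-6, 3e-7, simplified=False)
    b = v0_oxygen_saturated(params, 2e-4, 1.25e-6, 3e-7, simplified=True)
    assert a == pytest.approx(b, rel=1e-3)


def test_limit_chain_km_equals_k12_gives_michaelis_form(fig4_params):
    """When the dead-end constant K12 is made equal to KM the saturated
    form reduces to the Michaelis form with effective enzyme E0/(1+R_E)."""
    km = km_from_constants(fig4_params["k9"], fig4_params["k-9"], fig4_params["k10"])
    tuned = fig4_params.updated(**{"k-12": km * fig4_params["k12"]})
    S, H, E0 = 2e-4, 1.25e-6, 3e-7
    re = re_from_h2o2(tuned["k15"], tuned["k-15"], H)
    a = v0_oxygen_saturated(tuned, S, H, E0, simplified=True)
    b = v0_michaelis(tuned, S, E0, re)
    assert a == pytest.approx(b, rel=1e-12)


def test_michaelis_midpoint_and_effective_enzyme(fig4_params):
    km = km_from_constants(fig4_params["k9"], fig4_params["k-9"], fig4_params["k10"])
    E0 = 3e-7
    v_half = v0_michaelis(fig4_params, km, E0, 4.0)
    assert v_half == pytest.approx(0.5 * 1.5 * 0.2 * E0)
    # frozen arithmetic: S = 0.2 mM, KM = 0.033125 mM, effective enzyme 60 nM
    v = v0_michaelis(fig4_params, 2e-4, E0, 4.0)
    assert v == pytest.approx(1.5 * 2e-4 * 6e-8 / (km + 2e-4), rel=1e-12)
    assert v == pytest.approx(7.72e-8, rel=5e-3)


def test_monotonicity_and_linearity_grids(fig4_params):
    S_grid = np.logspace(-6, -2, 25)
    v_S = [v0_full(fig4_params, s, 2.6e-4, 1.25e-6, 3e-7) for s in S_grid]
    assert np.all(np.diff(v_S) > 0)
    assert v_S[-1] / v_S[-2] < 1.05  # saturating
    H_grid = np.logspace(-8, -4, 25)
    v_H = [v0_full(fig4_params, 2e-4, 2.6e-4, h, 3e-7) for h in H_grid]
    assert np.all(np.diff(v_H) > 0)
    E_grid = np.linspace(1e-8, 1e-6, 7)
    v_E = np.array([v0_full(fig4_params, 2e-4, 2.6e-4, 1.25e-6, e) for e in E_grid])
    assert np.allclose(v_E / E_grid, v_E[0] / E_grid[0], rtol=1e-12)


def test_derived_constants(fig4_params):
    dc = derived_constants(fig4_params)
    assert dc.KM_DArb == pytest.approx(3.3125e-5)
    assert dc.K15 == pytest.approx(5e-6)
    assert dc.K12 == pytest.approx(2.375e-5)
    assert dc.kcat_DArb == 1.5
    assert dc.RE(1.25e-6) == pytest.approx(4.0)
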