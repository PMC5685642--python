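"""Closed-form steady-state rate laws for the deoxyarbutin cycle.

Applying the quasi-steady-state approximation to the six enzyme-form
balance equations of the base mechanism gives the initial quinone-formation
rate

    v0 = a1 [S][O2][H2O2][E]0 /
         (b1 [H2O2] + b2 [O2] + b3 [H2O2][S] + b4 [S][O2]
          + b5 [H2O2][O2] + b6 [H2O2][O2][S])

with coefficient products of the microscopic constants (S = D-Arb).  The
oxygen-saturated limit collapses to a Michaelis form in S whose effective
enzyme pool is the oxy fraction [E_ox]0 = [E]0/(1+R_E), R_E = K15/[H2O2]0.

The closed forms here are the fast predictors and the analytic oracle for
the ODE simulator; conversely the exact numerical solve of the enzyme-form
balance (tests) is the independent oracle for these products.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import RateConstants

__all__ = [
    "RateLawCoefficients",
    "DerivedConstants",
    "eq1_coefficients",
    "v0_full",
    "v0_oxygen_saturated",
    "v0_michaelis",
    "km_from_constants",
    "re_from_h2o2",
    "eox_fraction",
    "derived_constants",
]

_FIG5_LABELS = ("k8", "k-8", "k9", "k-9", "k10", "k11", "k12", "k-12", "k15", "k-15")


@dataclass(frozen=True)
class RateLawCoefficients:
    """The seven coefficient products of the full rate law."""
    alpha1: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    beta6: float


def eq1_coefficients(params: RateConstants) -> RateLawCoefficients:
    """Coefficient products for the full steady-state rate law.

    Derived by exact elimination of the six enzyme-form balances; the
    denominator terms are commensurate (each beta_i times its concentration
    monomial has units of s^-5 when E0 is factored out of the numerator).
    """
    params.require(*_FIG5_LABELS)
    k8, km8 = params["k8"], params["k-8"]
    k9, km9 = params["k9"], params["k-9"]
    k10, k11 = params["k10"], params["k11"]
    k12, km12 = params["k12"], params["k-12"]
    k15, km15 = params["k15"], params["k-15"]
    return RateLawCoefficients(
        alpha1=k8 * k9 * k10 * k11 * km12 * k15,
        beta1=km8 * k11 * km12 * k15 * (km9 + k10),
        beta2=k8 * k11 * km12 * km15 * (km9 + k10),
        beta3=k9 * k10 * k11 * km12 * k15,
        beta4=k8 * k11 * k12 * km15 * (km9 + k10),
        beta5=k8 * k11 * km12 * k15 * (km9 + k10),
        beta6=k8 * k9 * km12 * k15 * (k10 + k11),
    )


def v0_full(params: RateConstants, S: float, O2: float, H2O2: float,
            E0: float) -> float:
    """Full steady-state initial rate (M/s) at the given concentrations.

    The printed closed form omits the total-enzyme factor; it is restored
    here so every rate law in this module shares M/s units.
    """
    if min(S, O2, H2O2, E0) < 0:
        raise ValueError("concentrations must be non-negative")
    c = eq1_coefficients(params)
    den = (c.beta1 * H2O2 + c.beta2 * O2 + c.beta3 * H2O2 * S
           + c.beta4 * S * O2 + c.beta5 * H2O2 * O2 + c.beta6 * H2O2 * O2 * S)
    if den == 0:
        raise ZeroDivisionError("rate undefined: all denominator terms vanish")
    return c.alpha1 * S * O2 * H2O2 * E0 / den


def _v0_oxygen_saturated_exact(params: RateConstants, S: float, H2O2: float,
                               E0: float) -> float:
    """O2 -> infinity limit without the k11 >> k10 simplification."""
    k9, km9 = params["k9"], params["k-9"]
    k10, k11 = params["k10"], params["k11"]
    K12 = params["k-12"] / params["k12"]
    K15 = params["k-15"] / params["k15"]
    kcat = k10 * k11 / (k10 + k11)
    km_eff = (k11 / (k10 + k11)) * (km9 + k10) / k9
    den = (km_eff * K15 + (km_eff * K15 / K12) * S + km_eff * H2O2 + H2O2 * S)
    if den == 0:
        raise ZeroDivisionError("rate undefined at S = H2O2 = 0")
    return kcat * S * H2O2 * E0 / den


def v0_oxygen_saturated(params: RateConstants, S: float, H2O2: float,
                        E0: float, *, simplified: bool = True) -> float:
    """Oxygen-saturated rate (M/s); with ``simplified`` the k11 >> k10
    reduction is applied exactly where the derivation applies it."""
    if not simplified:
        return _v0_oxygen_saturated_exact(params, S, H2O2, E0)
    k10 = params["k10"]
    KM = km_from_constants(params["k9"], params["k-9"], k10)
    K12 = params["k-12"] / params["k12"]
    K15 = params["k-15"] / params["k15"]
    den = KM * (K15 / H2O2 + (K15 / K12) * (S / H2O2) + 1.0) + S if H2O2 > 0 else 0.0
    if H2O2 == 0 and S == 0:
        raise ZeroDivisionError("rate undefined at S = H2O2 = 0")
    if H2O2 == 0:
        return 0.0  # all enzyme locked as E_m: no oxy form, no turnover
    return k10 * S * E0 / den


def v0_michaelis(params: RateConstants, S: float, E0: float, RE: float) -> float:
    """Michaelis form with the KM ~ K12 reduction: the effective enzyme is
    the oxy fraction E0/(1+RE)."""
    if RE < 0:
        raise ValueError("RE must be non-negative")
    k10 = params["k10"]
    KM = km_from_constants(params["k9"], params["k-9"], k10)
    return k10 * S * (E0 / (1.0 + RE)) / (KM + S)


def km_from_constants(k9: float, k_9: float, k10: float) -> float:
    """Michaelis constant of the oxy-form substrate binding: (k-9 + k10)/k9."""
    if k9 == 0:
        raise ZeroDivisionError("k9 must be positive")
    return (k_9 + k10) / k9


def re_from_h2o2(k15: float, k_15: float, H2O2: float) -> float:
    """Resting met/oxy partition R_E = K15/[H2O2]0 with K15 = k-15/k15."""
    if H2O2 == 0:
        raise ZeroDivisionError("R_E diverges at [H2O2]0 = 0 (all enzyme E_m)")
    if k15 == 0:
        raise ZeroDivisionError("k15 must be positive")
    return (k_15 / k15) / H2O2


def eox_fraction(RE: float) -> float:
    """Initial oxy-form fraction of the total enzyme: 1/(1 + R_E)."""
    if RE < 0:
        raise ValueError("RE must be non-negative")
    return 1.0 / (1.0 + RE)


@dataclass(frozen=True)
class DerivedConstants:
    """Aggregate equilibrium/Michaelis constants implied by a constant set."""
    KM_DArb: float   # M
    K15: float       # M
    K12: float       # M
    kcat_DArb: float  # s^-1 (= k10)

    def RE(self, H2O2: float) -> float:
        return self.K15 / H2O2


def derived_constants(params: RateConstants) -> DerivedConstants:
    params.require("k9", "k-9", "k10", "k12", "k-12", "k15", "k-15")
    return DerivedConstants(
        KM_DArb=km_from_constants(params["k9"], params["k-9"], params["k10"]),
        K15=params["k-15"] / params["k15"],
        K12=params["k-12"] / params["k12"],
        kcat_DArb=params["k10"],
    )
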