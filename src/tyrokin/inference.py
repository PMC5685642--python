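"""Fitting and classification of simulated/synthetic rate data.

Initial-rate values v0(S) are fitted to the Michaelis-Menten equation by
nonlinear least squares (the primary estimator); the Lineweaver-Burk double
reciprocal is kept for display and as a sensitivity check, as is standard
practice.  Apparent inhibition is classified from the shift pattern of
(Vmax, KM) between a control and an inhibited fit, and the apparent
competitive inhibition constant is computed from the KM shift:

    K_I^app = [I] / (KM_app / KM - 1)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "RatePoints",
    "MMFit",
    "InhibitionFit",
    "FitError",
    "fit_michaelis_menten",
    "lineweaver_burk",
    "classify_inhibition",
    "ki_app",
    "ki_app_lineweaver_burk",
    "fit_inhibition",
    "estimate_epsilon",
    "recovery_report",
]


class FitError(RuntimeError):
    pass


def RatePoints(S, v0, I=None, replicate=None) -> pd.DataFrame:
    """Assemble a tidy rate table (S_molar, I_molar, v0_molar_per_s, replicate)."""
    S = np.asarray(S, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentrations must be non-negative")
    I = np.zeros_like(S) if I is None else np.broadcast_to(
        np.asarray(I, dtype=float), S.shape)
    rep = np.zeros(len(S), dtype=int) if replicate is None else np.asarray(replicate)
    return pd.DataFrame({"S_molar": S, "I_molar": I,
                         "v0_molar_per_s": v0, "replicate": rep})


@dataclass(frozen=True)
class MMFit:
    Vmax: float          # M/s
    KM: float            # M
    kcat: float          # s^-1, w.r.t. the supplied effective enzyme
    Vmax_stderr: float
    KM_stderr: float
    E_effective: float   # M
    residual_rms: float
    n_points: int
    warnings: tuple[str, ...] = ()


def _mm(S, Vmax, KM):
    return Vmax * S / (KM + S)


def fit_michaelis_menten(points: pd.DataFrame, E_effective: float) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit of v0 against S.

    Initialisation is deterministic: Vmax0 = max v0, KM0 = S at half-max by
    interpolation, so identical data always give identical fits.
    """
    S = points["S_molar"].to_numpy(dtype=float)
    v = points["v0_molar_per_s"].to_numpy(dtype=float)
    warnings: list[str] = []
    if len(np.unique(S[S > 0])) < 4:
        warnings.append("fewer than 4 distinct substrate levels; "
                        "estimates will be poorly constrained")
    vmax0 = float(v.max())
    order = np.argsort(S)
    km0 = float(np.interp(vmax0 / 2.0, v[order], S[order]))
    km0 = km0 if km0 > 0 else float(np.median(S[S > 0]))

    model = Model(_mm)
    pars = model.make_params(Vmax=dict(value=vmax0, min=0),
                             KM=dict(value=km0, min=0))
    result = model.fit(v, pars, S=S)
    if not result.success:
        raise FitError(f"Michaelis-Menten fit did not converge "
                       f"(init Vmax={vmax0:.3e}, KM={km0:.3e})")
    if len(S) <= 2:
        warnings.append("degenerate design (2 points or fewer)")
    vmax = float(result.params["Vmax"].value)
    km = float(result.params["KM"].value)
    if km > S.max():
        warnings.append("fitted KM above the highest substrate level")
    if km < S[S > 0].min():
        warnings.append("fitted KM below the lowest substrate level")
    return MMFit(
        Vmax=vmax, KM=km, kcat=vmax / E_effective,
        Vmax_stderr=float(result.params["Vmax"].stderr or math.nan),
        KM_stderr=float(result.params["KM"].stderr or math.nan),
        E_effective=E_effective,
        residual_rms=float(np.sqrt(np.mean(result.residual ** 2))),
        n_points=len(S), warnings=tuple(warnings))


def lineweaver_burk(points: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least squares on (1/S, 1/v0), one line per inhibitor level.

    Display/diagnostic companion to the nonlinear fit: for exact hyperbolic
    data intercept = 1/Vmax and slope = KM/Vmax.
    """
    if np.any(points["v0_molar_per_s"] <= 0):
        raise ValueError("Lineweaver-Burk requires strictly positive rates")
    if np.any(points["S_molar"] <= 0):
        raise ValueError("Lineweaver-Burk requires strictly positive substrate")
    rows = []
    for level, grp in points.groupby("I_molar"):
        x = 1.0 / grp["S_molar"].to_numpy()
        y = 1.0 / grp["v0_molar_per_s"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        rows.append({"I_molar": float(level), "slope": float(slope),
                     "intercept": float(intercept),
                     "KM_over_Vmax": float(slope), "one_over_Vmax": float(intercept)})
    return pd.DataFrame(rows)


def classify_inhibition(control: MMFit, inhibited: MMFit,
                        tol: float = 0.05) -> str:
    """Classify the (Vmax, KM) shift pattern.

    competitive: Vmax unchanged within ``tol``, KM increased; uncompetitive:
    Vmax and KM reduced in proportion; none: both unchanged; anything else
    (including ambiguous overlaps) is mixed.
    """
    v_ratio = inhibited.Vmax / control.Vmax
    k_ratio = inhibited.KM / control.KM
    v_same = abs(v_ratio - 1.0) <= tol
    k_same = abs(k_ratio - 1.0) <= tol
    if v_same and k_same:
        return "none"
    if v_same and k_ratio > 1.0 + tol:
        return "competitive"
    if v_ratio < 1.0 - tol and abs(k_ratio / v_ratio - 1.0) <= tol:
        return "uncompetitive"
    return "mixed"


def ki_app(control: MMFit, inhibited: MMFit, I: float) -> float:
    """Apparent competitive inhibition constant from the KM shift."""
    if I <= 0:
        raise ValueError("inhibitor concentration must be positive")
    ratio = inhibited.KM / control.KM
    if ratio <= 1.0:
        raise ValueError("KM_app <= KM: no competitive inhibition signal")
    return I / (ratio - 1.0)


def ki_app_lineweaver_burk(points: pd.DataFrame, I: float) -> float:
    """Alternative estimator: double-reciprocal slope ratio,
    slope_I/slope_0 = 1 + [I]/K_I for a competitive inhibitor."""
    lines = lineweaver_burk(points).set_index("I_molar")
    if 0.0 not in lines.index or I not in lines.index:
        raise ValueError("need both a control (I=0) and an inhibited series")
    ratio = lines.loc[I, "slope"] / lines.loc[0.0, "slope"]
    if ratio <= 1.0:
        raise ValueError("slope ratio <= 1: no competitive inhibition signal")
    return I / (ratio - 1.0)


@dataclass(frozen=True)
class InhibitionFit:
    control: MMFit
    inhibited: MMFit
    inhibitor_M: float
    inhibition_type: str
    KI_app: float | None
    KI_app_stderr: float | None
    notes: tuple[str, ...] = ()


def fit_inhibition(points: pd.DataFrame, E_effective: float,
                   tol: float = 0.05) -> InhibitionFit:
    """Fit control and single-inhibitor-level series and classify."""
    levels = sorted(points["I_molar"].unique())
    if levels[0] != 0.0:
        raise ValueError("inhibition analysis needs a control series (I = 0)")
    control = fit_michaelis_menten(points[points["I_molar"] == 0.0], E_effective)
    if len(levels) == 1:
        return InhibitionFit(control, control, 0.0, "none", None, None,
                             ("no inhibitor level supplied",))
    I = levels[-1]
    inhibited = fit_michaelis_menten(points[points["I_molar"] == I], E_effective)
    kind = classify_inhibition(control, inhibited, tol)
    ki = kier = None
    notes: tuple[str, ...] = ()
    if kind == "competitive" or (kind == "mixed" and inhibited.KM > control.KM):
        ki = ki_app(control, inhibited, I)
        # first-order error propagation through the KM ratio
        r = inhibited.KM / control.KM
        var = ((inhibited.KM_stderr / control.KM) ** 2
               + (r * control.KM_stderr / control.KM) ** 2)
        kier = I / (r - 1.0) ** 2 * math.sqrt(var) if math.isfinite(var) else None
        if kind == "mixed":
            notes = ("classified mixed; K_I^app reported from the KM shift",)
    return InhibitionFit(control, inhibited, I, kind, ki, kier, notes)


def estimate_epsilon(endpoints, path_cm: float = 1.0) -> tuple[float, float]:
    """Molar absorptivity from endpoint absorbances of exhausted assays.

    ``endpoints`` is an iterable of (S0_molar, A_final) pairs from runs in
    which the substrate was fully converted; the slope of A_final against
    S0, divided by the path length, is epsilon (M^-1 cm^-1).  Returns
    (epsilon, intercept); the intercept should be ~0.
    """
    pts = list(endpoints)
    if len(pts) < 3:
        raise ValueError("need at least 3 substrate levels")
    S0 = np.array([p[0] for p in pts], dtype=float)
    A = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(A, 0):
        return 0.0, 0.0
    slope, intercept = np.polyfit(S0, A, 1)
    return float(slope / path_cm), float(intercept)


@dataclass(frozen=True)
class RecoveryReport:
    rows: pd.DataFrame = field(repr=False)

    def max_relative_error(self) -> float:
        return float(self.rows["relative_error"].abs().max())


def recovery_report(true_values: dict[str, float],
                    fitted_values: dict[str, float],
                    stderrs: dict[str, float] | None = None) -> RecoveryReport:
    """True-vs-fitted summary table with relative errors and 95% CIs."""
    stderrs = stderrs or {}
    rows = []
    for name, truth in true_values.items():
        fit = fitted_values[name]
        se = stderrs.get(name)
        rows.append({
            "parameter": name, "true": truth, "fitted": fit,
            "relative_error": (fit - truth) / truth if truth != 0 else math.nan,
            "stderr": se,
            "ci95_low": fit - 1.96 * se if se is not None else math.nan,
            "ci95_high": fit + 1.96 * se if se is not None else math.nan,
            "covered": (abs(fit - truth) <= 1.96 * se) if se is not None else None,
        })
    return RecoveryReport(pd.DataFrame(rows))
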