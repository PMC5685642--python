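"""Rate-constant registry for the tyrosinase / deoxyarbutin reaction mechanisms.

Each published simulation experiment prints its own constant set in its
figure legend, and the sets are *not* identical (notably the O2-binding
constant k8 is 0.5e7 M^-1 s^-1 in one legend and 2.3e8 M^-1 s^-1 in the
others).  Constants are therefore registered per experiment id and never
merged globally.

Internal units are molar and seconds throughout: second-order constants in
M^-1 s^-1, first-order constants in s^-1.  A reverse constant is written
with the ``k-N`` label convention.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

__all__ = ["RateConstants", "ConfigurationError", "constant_set", "available_sets"]


class ConfigurationError(KeyError):
    """A scheme builder was handed a constant set missing a required label."""


#: kinetic order (1 = unimolecular, 2 = bimolecular) of every known label,
#: as implied by the units printed in the figure legends.
CONSTANT_ORDERS: dict[str, int] = {
    "k1": 2, "k-1": 1,
    "k2": 2, "k-2": 1,
    "k3": 1,
    "k4": 2, "k-4": 1,
    "k5": 1,
    "k6": 2, "k-6": 1,
    "k7": 1,
    "k8": 2, "k-8": 1,
    "k9": 2, "k-9": 1,
    "k10": 1,
    "k11": 1,
    "k12": 2, "k-12": 1,
    "k13": 2, "k-13": 1,
    "k14": 1,
    "k15": 2, "k-15": 1,
    "k16": 1,
    "k17": 2, "k-17": 1,
    "k18": 1,
    "k19": 1,
    # not printed in any legend: ascorbate reduction of E_m (qualitative
    # activation scheme only; default documented in the mechanism module)
    "k20": 2,
}


def _base_label(label: str) -> str:
    return label.replace("k-", "k", 1) if label.startswith("k-") else label


@dataclass(frozen=True)
class RateConstants(Mapping):
    """Named map from rate-constant label to value, tagged with the
    experiment (figure legend) it reproduces.

    Invariants enforced at construction: values are non-negative, every
    reverse label ``k-N`` is accompanied by its forward ``kN``, and every
    label is a known one (so its kinetic order, hence its unit, is defined).
    """

    values: dict[str, float] = field(default_factory=dict)
    experiment_id: str = "custom"

    def __post_init__(self) -> None:
        for label, value in self.values.items():
            if label not in CONSTANT_ORDERS:
                raise ConfigurationError(f"unknown rate-constant label {label!r}")
            if not value >= 0:
                raise ValueError(f"rate constant {label} must be >= 0, got {value}")
            if label.startswith("k-") and _base_label(label) not in self.values:
                raise ConfigurationError(
                    f"reverse constant {label} present without forward {_base_label(label)}"
                )

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, label: str) -> float:
        try:
            return self.values[label]
        except KeyError:
            raise ConfigurationError(
                f"constant set {self.experiment_id!r} does not define {label!r}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def order(self, label: str) -> int:
        """Kinetic order (1 or 2) implied by the label's printed unit."""
        return CONSTANT_ORDERS[label]

    def require(self, *labels: str) -> None:
        missing = [lab for lab in labels if lab not in self.values]
        if missing:
            raise ConfigurationError(
                f"constant set {self.experiment_id!r} is missing {', '.join(missing)}"
            )

    def updated(self, experiment_id: str | None = None, **labels: float) -> "RateConstants":
        new = dict(self.values)
        new.update({lab.replace("km", "k-") if lab.startswith("km") else lab: v
                    for lab, v in labels.items()})
        return RateConstants(new, experiment_id or self.experiment_id)


# ---------------------------------------------------------------------------
# Legend sets.  The deoxyarbutin pathway constants (k9, k-9, k10, k11, k12,
# k-12, k15, k-15) are common to every legend; k8/k-8 differ between the
# oxygen-exhaustion experiment and the rest.

_DARB_CORE = {
    "k9": 1.6e5, "k-9": 3.8,
    "k10": 1.5,
    "k11": 400.0,
    "k12": 1.6e5, "k-12": 3.8,
    "k15": 2e6, "k-15": 10.0,
}

_K8_SLOW = {"k8": 0.5e7, "k-8": 5e3}
_K8_FAST = {"k8": 2.3e8, "k-8": 1.07e3}

_PHENOLASE_CORE = {
    "k2": 5e5, "k-2": 10.0,
    "k3": 900.0,
    "k4": 4.8e4, "k-4": 0.5,
    "k5": 12.0,
    "k6": 2.16e5, "k-6": 10.0,
    "k7": 108.0,
    "k14": 10.0,
}

_RELEASE = {"k13": 1e5, "k-13": 3.0}

_SETS: dict[str, dict[str, float]] = {
    # oxygen-exhaustion / rate-vs-substrate legend (slow O2 binding)
    "fig4": {**_DARB_CORE, **_K8_SLOW},
    # catalase legend: fast O2 binding plus the H2O2 sink
    "s6": {**_DARB_CORE, **_K8_FAST, "k16": 6.6e-4},
    # release-and-immediate-oxidation variant
    "s8": {**_DARB_CORE, **_K8_FAST, **_RELEASE, "k19": 3e4},
    # release-and-rebind variant
    "s10": {**_DARB_CORE, **_K8_FAST, **_RELEASE,
            "k17": 1e5, "k-17": 3.0, "k18": 400.0},
    # base mechanism over the release-variant time span (legend also prints
    # the unused k13 pair; registered as printed)
    "s11": {**_DARB_CORE, **_K8_FAST, **_RELEASE},
    # monophenolase competition (L-tyrosine + L-dopa + D-Arb); this legend
    # prints no k15/k-15 (no H2O2 pathway in the competition schemes)
    "s18a": {**{k: v for k, v in _DARB_CORE.items() if k not in ("k15", "k-15")},
             **_K8_FAST, **_PHENOLASE_CORE, "k1": 2e5, "k-1": 10.0},
    # diphenolase competition (L-dopa + D-Arb); the legend also prints the
    # monophenol constants k2/k-2/k3, unused without monophenol species
    "s18b": {**{k: v for k, v in _DARB_CORE.items() if k not in ("k15", "k-15")},
             **_K8_FAST, **_PHENOLASE_CORE},
    # simulated recordings / enzyme- and substrate-dependence legends
    "s22": {**_DARB_CORE, **_K8_FAST},
    "s23": {**_DARB_CORE, **_K8_FAST},
    "s24": {**_DARB_CORE, **_K8_FAST},
}


def constant_set(experiment_id: str) -> RateConstants:
    """Return the rate-constant set printed in the given figure legend."""
    try:
        values = _SETS[experiment_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown experiment id {experiment_id!r}; known: {sorted(_SETS)}"
        ) from None
    return RateConstants(dict(values), experiment_id)


def available_sets() -> list[str]:
    return sorted(_SETS)
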