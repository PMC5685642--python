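"""Reaction schemes for the tyrosinase catalytic cycle on deoxyarbutin.

The enzyme shuttles between three forms: oxytyrosinase (E_ox, the only form
able to hydroxylate the monophenol), metatyrosinase (E_m, resting; binds
monophenols in a dead-end complex and is converted to E_ox by H2O2) and
deoxytyrosinase (E_d, reduced; binds O2 to regenerate E_ox).  Deoxyarbutin
(D-Arb) is hydroxylated on E_ox and, uniquely, the resulting o-diphenol
(D-ArbOH) is oxidised to the quinone P without ever being released.

A scheme here is data: a species list plus elementary mass-action steps,
each step referencing a rate-constant label.  Builders assemble every
mechanism variant studied: the base cycle, the two product-release variants
used to argue that D-ArbOH is *not* released, the catalase extension, the
monophenolase/diphenolase competition schemes, and the activation schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ConfigurationError, RateConstants

__all__ = [
    "Species",
    "Reaction",
    "MechanismScheme",
    "SchemeError",
    "build_deoxyarbutin_scheme",
    "build_release_oxidize_variant",
    "build_release_rebind_variant",
    "build_monophenolase_competition_scheme",
    "build_diphenolase_competition_scheme",
    "build_activation_scheme",
    "with_catalase",
    "validate_scheme",
    "format_scheme",
]

ROLES = ("enzyme-form", "enzyme-complex", "ligand", "product", "cosubstrate")


class SchemeError(ValueError):
    """Structural defect in a reaction scheme."""


@dataclass(frozen=True)
class Species:
    """A chemical species.  ``role`` decides conservation bookkeeping:
    enzyme-forms and enzyme-complexes each carry one enzyme moiety."""

    name: str
    role: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemeError(f"unknown species role {self.role!r}")
        if not self.label:
            object.__setattr__(self, "label", self.name)

    @property
    def enzyme_moieties(self) -> int:
        return 1 if self.role in ("enzyme-form", "enzyme-complex") else 0


@dataclass(frozen=True)
class Reaction:
    """One elementary direction-counted step.

    ``rate_species`` defaults to the reactants and is only overridden for
    documented kinetic shortcuts (the dopaquinone disproportionation, whose
    rate is limited by first-order cyclisation while consuming two quinones).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_label: str
    rate_species: tuple[str, ...] | None = None

    @staticmethod
    def make(reactants: dict[str, int], products: dict[str, int], rate_label: str,
             rate_species: tuple[str, ...] | None = None) -> "Reaction":
        return Reaction(tuple(sorted(reactants.items())),
                        tuple(sorted(products.items())), rate_label, rate_species)

    @property
    def molecularity(self) -> int:
        species = self.rate_species
        if species is not None:
            return len(species)
        return sum(n for _, n in self.reactants)

    def kinetic_species(self) -> tuple[str, ...]:
        if self.rate_species is not None:
            return self.rate_species
        out: list[str] = []
        for name, n in self.reactants:
            out.extend([name] * n)
        return tuple(out)


@dataclass(frozen=True)
class MechanismScheme:
    """Species + elementary reactions + the constant set that prices them."""

    scheme_id: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    params: RateConstants

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise SchemeError(f"duplicate species names in scheme {self.scheme_id}")
        known = set(names)
        for rxn in self.reactions:
            if rxn.molecularity > 2:
                raise SchemeError(
                    f"{self.scheme_id}: step {rxn.rate_label} has molecularity "
                    f"{rxn.molecularity} > 2 (elementary steps only)")
            for name, _ in rxn.reactants + rxn.products:
                if name not in known:
                    raise SchemeError(
                        f"{self.scheme_id}: step {rxn.rate_label} references "
                        f"unknown species {name!r}")
            self.params.require(rxn.rate_label)

    # -- lookups -----------------------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise SchemeError(f"scheme {self.scheme_id} has no species {name!r}") from None

    def has_species(self, name: str) -> bool:
        return name in self.species_names

    def enzyme_species(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.enzyme_moieties)

    # -- compilation -------------------------------------------------------
    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, species x reactions."""
        idx = {name: i for i, name in enumerate(self.species_names)}
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for name, n in rxn.reactants:
                N[idx[name], j] -= n
            for name, n in rxn.products:
                N[idx[name], j] += n
        return N

    def compile_rhs(self):
        """Compile to a mass-action right-hand side f(t, y) for the ODE solver."""
        N = self.stoichiometry_matrix()
        rates = np.array([self.params[r.rate_label] for r in self.reactions])
        idx = {name: i for i, name in enumerate(self.species_names)}
        kin = [tuple(idx[name] for name in r.kinetic_species()) for r in self.reactions]
        uni = np.array([k[0] if len(k) == 1 else -1 for k in kin])
        bi_a = np.array([k[0] if len(k) == 2 else -1 for k in kin])
        bi_b = np.array([k[1] if len(k) == 2 else -1 for k in kin])
        is_uni = uni >= 0
        is_bi = bi_a >= 0

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            v = np.zeros(len(rates))
            v[is_uni] = rates[is_uni] * y[uni[is_uni]]
            v[is_bi] = rates[is_bi] * y[bi_a[is_bi]] * y[bi_b[is_bi]]
            return N @ v

        return rhs

    def with_reactions(self, extra: tuple[Reaction, ...],
                       extra_species: tuple[Species, ...] = (),
                       scheme_id: str | None = None,
                       params: RateConstants | None = None) -> "MechanismScheme":
        return MechanismScheme(
            scheme_id or self.scheme_id,
            self.species + extra_species,
            self.reactions + extra,
            params or self.params,
        )


# ---------------------------------------------------------------------------
# species vocabulary

_SP = {
    "E_m": Species("E_m", "enzyme-form", "metatyrosinase"),
    "E_d": Species("E_d", "enzyme-form", "deoxytyrosinase"),
    "E_ox": Species("E_ox", "enzyme-form", "oxytyrosinase"),
    "E_oxD-Arb": Species("E_oxD-Arb", "enzyme-complex"),
    "E_mD-ArbOH": Species("E_mD-ArbOH", "enzyme-complex"),
    "E_mD-Arb": Species("E_mD-Arb", "enzyme-complex"),
    "E_oxD-ArbOH": Species("E_oxD-ArbOH", "enzyme-complex"),
    "E_mM": Species("E_mM", "enzyme-complex"),
    "E_oxM": Species("E_oxM", "enzyme-complex"),
    "E_mD": Species("E_mD", "enzyme-complex"),
    "E_oxD": Species("E_oxD", "enzyme-complex"),
    "D-Arb": Species("D-Arb", "ligand", "deoxyarbutin"),
    "D-ArbOH": Species("D-ArbOH", "ligand", "hydroxylated deoxyarbutin"),
    "P": Species("P", "product", "quinone of D-ArbOH"),
    "M": Species("M", "ligand", "monophenol (L-tyrosine)"),
    "D": Species("D", "ligand", "o-diphenol (L-dopa)"),
    "Q": Species("Q", "product", "o-dopaquinone"),
    "Cr": Species("Cr", "product", "dopachrome"),
    "TBC": Species("TBC", "ligand", "tert-butylcatechol"),
    "TBQ": Species("TBQ", "product", "o-tert-butylquinone"),
    "E_mTBC": Species("E_mTBC", "enzyme-complex"),
    "E_oxTBC": Species("E_oxTBC", "enzyme-complex"),
    "AH2": Species("AH2", "cosubstrate", "ascorbic acid"),
    "A": Species("A", "product", "dehydroascorbate"),
    "O2": Species("O2", "cosubstrate"),
    "H2O2": Species("H2O2", "cosubstrate"),
}


def _r(reactants: dict[str, int], products: dict[str, int], label: str,
       rate_species: tuple[str, ...] | None = None) -> Reaction:
    return Reaction.make(reactants, products, label, rate_species)


def _reversible(reactants: dict[str, int], products: dict[str, int],
                fwd: str, rev: str) -> tuple[Reaction, Reaction]:
    return _r(reactants, products, fwd), _r(products, reactants, rev)


# ---------------------------------------------------------------------------
# builders

def build_deoxyarbutin_scheme(params: RateConstants) -> MechanismScheme:
    """The base catalytic cycle on deoxyarbutin.

    Steps: E_m + H2O2 = E_ox (k15/k-15); E_d + O2 = E_ox (k8/k-8);
    E_ox + D-Arb = E_oxD-Arb (k9/k-9); internal hydroxylation
    E_oxD-Arb -> E_mD-ArbOH (k10); internal oxidation and quinone release
    E_mD-ArbOH -> E_d + P (k11); dead-end E_m + D-Arb = E_mD-Arb (k12/k-12).
    No step releases D-ArbOH: that is the defining feature of this substrate.
    """
    params.require("k8", "k-8", "k9", "k-9", "k10", "k11", "k12", "k-12", "k15", "k-15")
    species = tuple(_SP[n] for n in (
        "E_m", "E_d", "E_ox", "E_oxD-Arb", "E_mD-ArbOH", "E_mD-Arb",
        "D-Arb", "P", "O2", "H2O2"))
    reactions = (
        *_reversible({"E_m": 1, "H2O2": 1}, {"E_ox": 1}, "k15", "k-15"),
        *_reversible({"E_d": 1, "O2": 1}, {"E_ox": 1}, "k8", "k-8"),
        *_reversible({"E_ox": 1, "D-Arb": 1}, {"E_oxD-Arb": 1}, "k9", "k-9"),
        _r({"E_oxD-Arb": 1}, {"E_mD-ArbOH": 1}, "k10"),
        _r({"E_mD-ArbOH": 1}, {"E_d": 1, "P": 1}, "k11"),
        *_reversible({"E_m": 1, "D-Arb": 1}, {"E_mD-Arb": 1}, "k12", "k-12"),
    )
    return MechanismScheme("deoxyarbutin", species, reactions, params)


def build_release_oxidize_variant(params: RateConstants) -> MechanismScheme:
    """Base scheme plus release of D-ArbOH from E_mD-ArbOH (k-13, rebinding
    k13) and its immediate non-enzymatic oxidation D-ArbOH -> P (k19).

    The k19 step is modelled first-order in D-ArbOH with no O2 bookkeeping,
    a simplification of "oxidised immediately" consistent with the printed
    s^-1 unit.  Under the published conditions the cycle starves: every
    release event strands the enzyme as E_m and activity ceases.
    """
    params.require("k13", "k-13", "k19")
    base = build_deoxyarbutin_scheme(params)
    extra = (
        _r({"E_mD-ArbOH": 1}, {"E_m": 1, "D-ArbOH": 1}, "k-13"),
        _r({"E_m": 1, "D-ArbOH": 1}, {"E_mD-ArbOH": 1}, "k13"),
        _r({"D-ArbOH": 1}, {"P": 1}, "k19"),
    )
    return base.with_reactions(extra, (_SP["D-ArbOH"],), "release-oxidize")


def build_release_rebind_variant(params: RateConstants) -> MechanismScheme:
    """Base scheme plus release of D-ArbOH (k-13/k13) and its oxidation by
    E_ox via E_oxD-ArbOH (k17/k-17, then k18 -> E_m + P)."""
    params.require("k13", "k-13", "k17", "k-17", "k18")
    base = build_deoxyarbutin_scheme(params)
    extra = (
        _r({"E_mD-ArbOH": 1}, {"E_m": 1, "D-ArbOH": 1}, "k-13"),
        _r({"E_m": 1, "D-ArbOH": 1}, {"E_mD-ArbOH": 1}, "k13"),
        *_reversible({"E_ox": 1, "D-ArbOH": 1}, {"E_oxD-ArbOH": 1}, "k17", "k-17"),
        _r({"E_oxD-ArbOH": 1}, {"E_m": 1, "P": 1}, "k18"),
    )
    return base.with_reactions(
        extra, (_SP["D-ArbOH"], _SP["E_oxD-ArbOH"]), "release-rebind")


def with_catalase(scheme: MechanismScheme, k16: float | None = None) -> MechanismScheme:
    """Add the catalase-mediated first-order H2O2 sink (k16)."""
    if not scheme.has_species("H2O2"):
        raise SchemeError(f"scheme {scheme.scheme_id} has no H2O2 to consume")
    params = scheme.params
    if k16 is not None:
        params = params.updated(k16=k16)
    params.require("k16")
    extra = (_r({"H2O2": 1}, {}, "k16"),)
    return scheme.with_reactions(extra, (), scheme.scheme_id + "+catalase", params)


def _phenolase_core(params: RateConstants, mono: bool,
                    dopaquinone_disproportionation: bool) -> tuple[tuple[Species, ...], tuple[Reaction, ...]]:
    """Shared diphenolase cycle + dopaquinone evolution (+ monophenol steps)."""
    species = [_SP[n] for n in ("E_m", "E_d", "E_ox", "E_mD", "E_oxD", "D", "Q", "Cr", "O2")]
    reactions: list[Reaction] = [
        *_reversible({"E_m": 1, "D": 1}, {"E_mD": 1}, "k4", "k-4"),
        _r({"E_mD": 1}, {"E_d": 1, "Q": 1}, "k5"),
        *_reversible({"E_ox": 1, "D": 1}, {"E_oxD": 1}, "k6", "k-6"),
        _r({"E_oxD": 1}, {"E_m": 1, "Q": 1}, "k7"),
        *_reversible({"E_d": 1, "O2": 1}, {"E_ox": 1}, "k8", "k-8"),
    ]
    if mono:
        species += [_SP["M"], _SP["E_mM"], _SP["E_oxM"]]
        reactions += [
            *_reversible({"E_m": 1, "M": 1}, {"E_mM": 1}, "k1", "k-1"),
            *_reversible({"E_ox": 1, "M": 1}, {"E_oxM": 1}, "k2", "k-2"),
            _r({"E_oxM": 1}, {"E_mD": 1}, "k3"),
        ]
    if dopaquinone_disproportionation:
        # 2Q -> D + Cr at rate k14*[Q]: cyclisation-limited classical
        # dopachrome chemistry (kinetic shortcut; see module docs).
        reactions.append(_r({"Q": 2}, {"D": 1, "Cr": 1}, "k14", rate_species=("Q",)))
    else:
        reactions.append(_r({"Q": 1}, {"Cr": 1}, "k14"))
    return tuple(species), tuple(reactions)


def _darb_branch() -> tuple[tuple[Species, ...], tuple[Reaction, ...]]:
    species = tuple(_SP[n] for n in ("E_oxD-Arb", "E_mD-ArbOH", "E_mD-Arb", "D-Arb", "P"))
    reactions = (
        *_reversible({"E_ox": 1, "D-Arb": 1}, {"E_oxD-Arb": 1}, "k9", "k-9"),
        _r({"E_oxD-Arb": 1}, {"E_mD-ArbOH": 1}, "k10"),
        _r({"E_mD-ArbOH": 1}, {"E_d": 1, "P": 1}, "k11"),
        *_reversible({"E_m": 1, "D-Arb": 1}, {"E_mD-Arb": 1}, "k12", "k-12"),
    )
    return species, reactions


def build_monophenolase_competition_scheme(
        params: RateConstants, *,
        dopaquinone_disproportionation: bool = False) -> MechanismScheme:
    """Canonical monophenolase cycle on L-tyrosine merged with the
    deoxyarbutin pathway: D-Arb competes for E_ox (productively) and E_m
    (dead-end), producing the apparent competitive inhibition pattern."""
    params.require("k1", "k-1", "k2", "k-2", "k3", "k4", "k-4", "k5", "k6", "k-6",
                   "k7", "k8", "k-8", "k9", "k-9", "k10", "k11", "k12", "k-12", "k14")
    sp, rx = _phenolase_core(params, mono=True,
                             dopaquinone_disproportionation=dopaquinone_disproportionation)
    dsp, drx = _darb_branch()
    return MechanismScheme("monophenolase-competition", sp + dsp, rx + drx, params)


def build_diphenolase_competition_scheme(
        params: RateConstants, *,
        dopaquinone_disproportionation: bool = False) -> MechanismScheme:
    """Diphenolase (L-dopa) two-site ping-pong cycle merged with the
    deoxyarbutin pathway; no monophenol species."""
    params.require("k4", "k-4", "k5", "k6", "k-6", "k7", "k8", "k-8",
                   "k9", "k-9", "k10", "k11", "k12", "k-12", "k14")
    sp, rx = _phenolase_core(params, mono=False,
                             dopaquinone_disproportionation=dopaquinone_disproportionation)
    dsp, drx = _darb_branch()
    return MechanismScheme("diphenolase-competition", sp + dsp, rx + drx, params)


#: default constants for the activation steps no legend prices (documented
#: qualitative defaults; the H2O2 variant needs none).
AH2_REDUCTION_DEFAULT = 1e4   # M^-1 s^-1, E_m + AH2 -> E_d + A

def build_activation_scheme(variant: str, params: RateConstants) -> MechanismScheme:
    """Base deoxyarbutin scheme extended by an E_ox-regenerating pathway.

    variant "H2O2": identical topology to the base scheme (activation is
    realised by raising [H2O2]0).  variant "AH2": ascorbate reduces E_m to
    E_d, which O2 then re-oxidises.  variant "TBC": tert-butylcatechol runs
    the o-diphenol cycle, regenerating E_ox and adding a second chromophore.
    Qualitative use only; unpriced steps take documented defaults.
    """
    base = build_deoxyarbutin_scheme(params)
    if variant == "H2O2":
        return base.with_reactions((), (), "activation-H2O2")
    if variant == "AH2":
        params2 = params.updated(
            k20=params.values.get("k20", AH2_REDUCTION_DEFAULT))
        extra = (_r({"E_m": 1, "AH2": 1}, {"E_d": 1, "A": 1}, "k20"),)
        return MechanismScheme(
            "activation-AH2",
            base.species + (_SP["AH2"], _SP["A"]),
            base.reactions + extra,
            params2,
        )
    if variant == "TBC":
        params2 = RateConstants(
            {**params.values,
             "k4": params.values.get("k4", 4.8e4), "k-4": params.values.get("k-4", 0.5),
             "k5": params.values.get("k5", 12.0),
             "k6": params.values.get("k6", 2.16e5), "k-6": params.values.get("k-6", 10.0),
             "k7": params.values.get("k7", 108.0)},
            params.experiment_id)
        extra = (
            *_reversible({"E_m": 1, "TBC": 1}, {"E_mTBC": 1}, "k4", "k-4"),
            _r({"E_mTBC": 1}, {"E_d": 1, "TBQ": 1}, "k5"),
            *_reversible({"E_ox": 1, "TBC": 1}, {"E_oxTBC": 1}, "k6", "k-6"),
            _r({"E_oxTBC": 1}, {"E_m": 1, "TBQ": 1}, "k7"),
        )
        return MechanismScheme(
            "activation-TBC",
            base.species + (_SP["TBC"], _SP["TBQ"], _SP["E_mTBC"], _SP["E_oxTBC"]),
            base.reactions + extra,
            params2,
        )
    raise SchemeError(f"unknown activation variant {variant!r}; pick H2O2, AH2 or TBC")


# ---------------------------------------------------------------------------
# diagnostics

@dataclass(frozen=True)
class SchemeDiagnostics:
    conservation_ok: bool
    conservation_violations: tuple[str, ...]
    unit_ok: bool
    unit_violations: tuple[str, ...]
    reachable: tuple[str, ...] = ()
    unreachable: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.conservation_ok and self.unit_ok


def validate_scheme(scheme: MechanismScheme,
                    initial_species: tuple[str, ...] | None = None) -> SchemeDiagnostics:
    """Structural diagnostics: per-reaction enzyme-moiety conservation, unit
    consistency of each rate constant with its step's molecularity, and
    (optionally) reachability of every species from a nonzero initial set."""
    moiety = {s.name: s.enzyme_moieties for s in scheme.species}
    cons_bad, unit_bad = [], []
    for rxn in scheme.reactions:
        left = sum(moiety[n] * c for n, c in rxn.reactants)
        right = sum(moiety[n] * c for n, c in rxn.products)
        if left != right:
            cons_bad.append(f"{rxn.rate_label}: enzyme moieties {left} -> {right}")
        if scheme.params.order(rxn.rate_label) != rxn.molecularity:
            unit_bad.append(
                f"{rxn.rate_label}: order-{scheme.params.order(rxn.rate_label)} "
                f"constant on a molecularity-{rxn.molecularity} step")
    reachable: tuple[str, ...] = ()
    unreachable: tuple[str, ...] = ()
    if initial_species is not None:
        seen = set(initial_species)
        changed = True
        while changed:
            changed = False
            for rxn in scheme.reactions:
                if all(n in seen for n in rxn.kinetic_species()):
                    new = {n for n, _ in rxn.products} - seen
                    if new:
                        seen |= new
                        changed = True
        reachable = tuple(n for n in scheme.species_names if n in seen)
        unreachable = tuple(n for n in scheme.species_names if n not in seen)
    return SchemeDiagnostics(not cons_bad, tuple(cons_bad),
                             not unit_bad, tuple(unit_bad),
                             reachable, unreachable)


# ---------------------------------------------------------------------------
# text serialization: one reaction per line, "A + B <-> C : k9/k-9"

def format_scheme(scheme: MechanismScheme) -> str:
    """Render a scheme in the one-reaction-per-line text form, pairing
    forward/reverse steps into '<->' lines where both directions exist."""
    def side(stoich: tuple[tuple[str, int], ...]) -> str:
        if not stoich:
            return "0"
        return " + ".join(name if n == 1 else f"{n} {name}" for name, n in stoich)

    lines = []
    used: set[int] = set()
    rxns = scheme.reactions
    for i, rxn in enumerate(rxns):
        if i in used:
            continue
        partner = None
        for j in range(i + 1, len(rxns)):
            if j in used:
                continue
            other = rxns[j]
            if other.reactants == rxn.products and other.products == rxn.reactants:
                partner = j
                break
        if partner is not None:
            used.add(partner)
            lines.append(f"{side(rxn.reactants)} <-> {side(rxn.products)} : "
                         f"{rxn.rate_label}/{rxns[partner].rate_label}")
        else:
            lines.append(f"{side(rxn.reactants)} -> {side(rxn.products)} : {rxn.rate_label}")
    return "\n".join(lines)


def to_dict(scheme: MechanismScheme) -> dict:
    """JSON/YAML-ready representation of a scheme."""
    return {
        "scheme_id": scheme.scheme_id,
        "constants": {"experiment_id": scheme.params.experiment_id,
                      "values": dict(scheme.params.values)},
        "species": [{"name": s.name, "role": s.role, "label": s.label}
                    for s in scheme.species],
        "reactions": [{"reactants": dict(r.reactants), "products": dict(r.products),
                       "rate": r.rate_label,
                       **({"rate_species": list(r.rate_species)}
                          if r.rate_species is not None else {})}
                      for r in scheme.reactions],
    }


def from_dict(payload: dict) -> MechanismScheme:
    params = RateConstants(dict(payload["constants"]["values"]),
                           payload["constants"].get("experiment_id", "custom"))
    species = tuple(Species(s["name"], s["role"], s.get("label", ""))
                    for s in payload["species"])
    reactions = tuple(
        Reaction.make(dict(r["reactants"]), dict(r["products"]), r["rate"],
                      tuple(r["rate_species"]) if "rate_species" in r else None)
        for r in payload["reactions"])
    return MechanismScheme(payload["scheme_id"], species, reactions, params)
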