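# Methods

## The mechanism and its assumptions

Tyrosinase cycles through three forms: met (E_m, resting Cu²⁺Cu²⁺), deoxy
(E_d, Cu⁺Cu⁺) and oxy (E_ox, Cu²⁺Cu²⁺ with bound peroxide).  Only E_ox
hydroxylates monophenols.  Deoxyarbutin (S) binds E_ox productively
(k9/k-9), is hydroxylated on-enzyme (k10), and the bound *o*-diphenol is
oxidised in place (k11), releasing only the quinone P and leaving E_d,
which O2 re-oxidises to E_ox (k8/k-8).  E_m binds the substrate in a
dead-end complex (k12/k-12) and interconverts with E_ox through the H2O2
equilibrium (k15/k-15).  All steps are elementary mass action with
molecularity ≤ 2; water is left out of the bookkeeping and the
E_m + H2O2 ⇌ E_ox step is treated as elementary and mass-balancing (the
reverse regenerates H2O2).  Internal units are molar and seconds; figure
legends quoted in mM/µM/nM are converted at the boundary.

Variants: (a) release-and-immediate-oxidation — E_m·SOH ⇌ E_m + SOH
(k-13/k13) with SOH → P first order (k19), O2 deliberately *not* consumed
by that shortcut step (the printed unit is s⁻¹); (b) release-and-rebind —
the released SOH also binds E_ox (k17/k-17) and is oxidised to E_m + P
(k18); (c) catalase — a first-order H2O2 sink (k16); (d) competition
schemes — the canonical monophenolase/diphenolase cycle (dead-end E_m·M,
hydroxylation via E_ox·M → E_m·D, oxidation via E_m·D → E_d + Q and
E_ox·D → E_m + Q, dopachrome formation Q → Cr at k14) merged with the
D-Arb branch.  Q → Cr is first order by default, matching the printed s⁻¹
unit of k14; the classical disproportionation 2Q → D + Cr (cyclisation-
limited, rate k14[Q], consuming two quinones and regenerating one
diphenol) is an opt-in flag on the competition builders.  Where the
quinone-evolution topology could not be read from the figures it was
reconstructed from the constant lists and the group's canonical cycle;
whether k5 releases Q directly from E_m·D or via an E_d·Q intermediate is
not resolvable from the text and is implemented as direct release.

Rate-constant sets are registered per experiment id (fig4, s6, s8, s10,
s11, s18a, s18b, s22, s23, s24) because the legends disagree — most
notably k8 is 0.5×10⁷ M⁻¹s⁻¹ in the oxygen-exhaustion legend and
2.3×10⁸ M⁻¹s⁻¹ everywhere else.  No global merge is ever performed.

## Steady-state rate law

Exact elimination of the six enzyme-form balances (a linear solve with
ligand concentrations as parameters) gives the full rate law implemented
in `steady_state.eq1_coefficients` / `v0_full`.  The published closed form
prints no total-enzyme factor; it is restored so every rate in the package
has units of M/s.  Two reductions are kept separate and testable: the
oxygen-saturated limit (with and without the k11 ≫ k10 simplification,
since k11/k10 ≈ 267 leaves a 0.4% gap) and the Michaelis form, which
additionally assumes K_M ≈ K12.  That last assumption is a user-visible
choice, not a fact: with the published constants K_M/K12 = 1.39, and the
package treats the reduction as a limiting form (the test suite verifies
the chain in parameter regimes where each limit actually holds).

## Initial rates

The default window policy mimics bench practice: the longest interval
inside the depletion horizon (≤ 2% of any consumed substrate used up, with
a total-enzyme-sized allowance so reversible binding is not mistaken for
consumption) on which a straight line fits with relative rms residual
≤ 10⁻³.  If the pre-steady-state transient defeats the gate at t = 0 the
search may trim a short warm-up, preferring the longest admissible window.
For the lag-prone monophenolase traces the drivers use the field's
convention instead: the post-lag maximum slope of the dopachrome trace
("max_slope" policy) inside the same depletion horizon.  Oxygen is always
a dynamic species; "saturating O2" assays simply measure early at
[O2]0 = 0.26 mM, the air-saturated buffer value.

## Numerical choices

LSODA with rtol 10⁻⁸ and atol 10⁻¹² M is the default integrator (the
constants span twelve orders of magnitude); an explicit adaptive
Runge-Kutta cross-check agrees to 10⁻⁶ relative on the oxygen-exhaustion
problem at tightened tolerances.  Negative concentrations are clipped only
within atol, otherwise the run aborts.  Oxygen exhaustion uses event
detection at [O2] ≤ 10⁻⁹ M.  Pre-incubation protocols are two-phase
integrations: enzyme (+ agent) first, substrate added instantaneously at
phase 2.  Michaelis–Menten fits are nonlinear least squares with
deterministic initialisation (Vmax₀ = max v₀, K_M₀ = S at half-max by
interpolation); the double-reciprocal line fit is diagnostic only.  The
apparent competitive constant is K_I = [I]/(K_M,app/K_M − 1) from the
nonlinear fits, with the Lineweaver–Burk slope-ratio estimator exposed as
a sensitivity alternative.  Inhibition classification uses a 5% tolerance
on Vmax equality (configurable).

## Synthetic data

Recordings are Beer–Lambert readouts of simulated curves
(A = ε·ℓ·c + i.i.d. Gaussian noise, default σ = 0.002 AU — typical bench
spectrophotometer noise; the study states no noise model).  The quinone
channel is 485 nm with ε = 2300 M⁻¹cm⁻¹ and a 1 cm path.  A dopachrome
absorptivity is deliberately *not* defaulted (the study prints none);
rate-level noise in the inhibition generator is multiplicative Gaussian on
v₀.  Designs mirror the published protocols: the printed substrate series
(0.05–1 mM), enzyme series (0–750 nM), 1 min H2O2 pre-incubations,
catalase pre-incubation times, and the substrate × inhibitor factorial at
[D-Arb] = 0.2 mM with R = [L-dopa]₀/[L-tyrosine]₀ = 0.042.  Generators are
bit-reproducible under a fixed seed.  What the synthetic data do *not*
emulate: instrument drift, photobleaching, thermal/photo degradation of
the substrate, replicate-to-replicate enzyme-activity variation — so
passing recovery tests demonstrate estimator correctness, not robustness
to real-instrument artefacts.

## Problem sizes

The shipped drivers use 6–9 substrate levels per curve, 2 inhibitor
levels, 60 s assay horizons (36 000 s cap for the exhaustion run, 1200 s
for the variant comparison) and 1000–2000-point output grids; these match
the published designs and keep every driver in the seconds-to-a-minute
range on one core.

## Known discrepancies

Two families of published simulation-derived numbers are *not* reproduced
by the mechanism as printed, and the package reports its own computed
values rather than matching them.

1. **kcat/K_M recovery (reported kcat = 1.5 s⁻¹, K_M = 0.033 mM).**  The
   identification kcat = k10 holds only under K_M ≈ K12.  With the printed
   constants K_M/K12 = 1.39, so as [S] grows the dead-end E_m·S (tighter
   than the productive site) drains the active pool and the true
   saturating rate is k10·[E]0/(1 + R_E·K_M/K12) — an apparent kcat of
   1.14 s⁻¹ on the 0.2·[E]0 basis, confirmed independently by the exact
   rate law and by ODE simulation (fitted 1.15 s⁻¹).  The fitted K_M
   (0.048 mM with the oxygen-exhaustion legend's k8, for which
   K8 = 1 mM makes 0.26 mM O2 sub-saturating; 0.025 mM with the fast-k8
   sets) brackets but does not equal the analytic 0.033 mM.

2. **Apparent inhibition constants (reported 0.070 / 0.062 mM).**  At
   steady state the apparent competitive K_I of the D-Arb branch is
   (1+γ)/(1/K_M^D-Arb + γ/K12) with γ the met/oxy partition ratio, which
   is bounded above by max(K_M^D-Arb, K12) = 0.033 mM for every γ — both
   reported values exceed that ceiling.  Transient protocols (rates taken
   before the inhibitor fully redistributes the enzyme) inflate the
   apparent K_I; the max-slope protocol used here yields 0.042 mM
   (monophenolase) and 0.041 mM (diphenolase), reproducing the
   competitive *pattern*, the ordering, and the mono/diph ratio, but not
   the absolute reported scale, which evidently depends on unstated
   details of the original recording spans.  The diphenolase case
   classifies as borderline mixed (Vmax ratio 0.91 at the 5% gate); its
   K_I is still reported from the K_M shift, with a note.

These are properties of the published constant sets, not tunables; the
acceptance tests that assert the reported values are left failing with
this analysis as their documentation.

## Limitations

No thermodynamic-consistency enforcement (the constant sets are
phenomenological); no stochastic simulation (the analysis is purely
deterministic ODE); no SBML import/export; activation schemes for
ascorbate and tert-butylcatechol are qualitative (their unprinted
constants take documented defaults); catalase is modelled only through
k16 in s⁻¹ — the mapping from U/ml is not given and is not invented.
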