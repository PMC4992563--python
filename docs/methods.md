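# Methods

This note documents the model, the numerical choices and the scaling
decisions behind the `evofba` simulator, in enough detail to judge what
its tests do and do not demonstrate.

## The metabolic chassis

The ancestor is the *E. coli* core metabolic reconstruction (95
reactions, 72 metabolites, 20 exchange reactions), vendored as a cleaned
constraint-based JSON file (`evofba/data/e_coli_core.json`: identifiers,
stoichiometry, bounds and the biomass objective; annotations stripped).
SBML (Level 3 + FBC) input is supported through the same loader. On
loading, exchange bounds are normalised: uptake is closed by default and
granted only through per-step kinetic caps, secretion is open, and the
five mineral exchanges (phosphate, ammonia, water, protons, CO2) are
unbounded in both directions — carbon and oxygen are the only limiting
resources. Internal bounds, including the ATP maintenance flux
(ATPM = 8.39 mmol/gDW/h), are kept as published.

A hand-built toy overflow model (glucose respiration 3 precursor/glc,
overflow 1 precursor + 1 acetate/glc, acetate respiration 0.8
precursor/ac, biomass 100 precursor per unit growth) provides an
analytically tractable fixture: its optima are checkable by hand and by
an independently coded LP, its parsimonious optimum is unique for
generic caps (3 > 1.8 precursor per glucose), and its declared carbon
contents (glc 6, ac 2, precursor 2) support closed carbon accounting in
tests.

## Two-stage budgeted FBA

Each solve maximises biomass flux subject to steady state, bounds,
Michaelis–Menten uptake caps and an explicit LP row
`Σ(mutable uptakes) ≤ C_total = 40 mmol/gDW/h`; the budget is thus
enforced both structurally (mutation keeps `Σ v_max = 40`) and on
realised fluxes. At the growth optimum (fixed to within 1e-9), total
absolute flux is minimised (L1 tie-break via forward/reverse variable
splitting). The implementation builds one persistent GLPK problem per
(model, mutable set, budget) and re-solves it warm-started with updated
bounds — ~0.3–0.6 ms per two-stage solve on the core model, which is
what makes minute-resolution dFBA over hundreds of cycles affordable on
one CPU. An infeasible stage 1 (e.g. maintenance unsatisfiable with no
carbon) is reported as zero growth with zero fluxes: the organism simply
does not grow that step.

Sign conventions: fluxes are stored in the toolchain convention
(negative exchange flux = uptake); the simulator-facing view
(`FBASolution.exchange_fluxes`, uptake positive) is produced in exactly
one adapter. Alternate optima on the full core model beyond the L1
tie-break are accepted; only the toy fixture's optima are pinned.

## Batch-cycle dynamics

Per Euler step of `dt` minutes (default 1):

* per-substrate caps `v_j = v_max,j [S_j]/(K_m + [S_j])`, with a single
  global, non-evolvable K_m = 0.01 mmol/l; oxygen is non-depleting (a
  shaken 10-ml flask is effectively aerated), so its cap is `v_max,O2`;
* biomass update `BM ← BM (1 + μ dt/(ln2·60))` — the framework's
  linearised form, kept verbatim (the ln 2 divisor makes μ behave as
  doublings/hour; `growth_update="exponential"` provides
  `exp(μ dt/60)` but is non-default);
* medium update `[S_j] ← [S_j] − Σ_i BM_i v_{j,i} dt/(60 V)` with BM in
  absolute gDW (the only dimensionally consistent reading), secretion
  entering with negative `v`;
* overshoot rule: if a substrate would go negative, all consumers' caps
  for it are scaled by available/demand, those genotypes are re-solved
  once, and the concentration is clamped at exactly 0.

All update rules carry an explicit `dt` factor (including the mutation
expectation below) and reduce to the printed per-minute forms at dt = 1.
Halving dt changes the ancestor's 24-h biomass by < 1 % (tested).

Two emergent numerical facts worth knowing. First, below ~5e-4 mmol/l
glucose the maintenance flux becomes infeasible at the capped uptake, so
consumption stops: "exhaustion" means > 99 % consumed, not numerical
zero. Second, once the glucose cap falls below the level that saturates
the fixed oxygen capacity (~0.11 mmol/l glucose for the ancestor's
10/20 glucose/oxygen split), acetate uptake strictly increases μ, so
growth-maximising FBA co-utilises the secreted acetate alongside
residual glucose — plain FBA has no catabolite repression. The diauxie
detector therefore reports the first switch from net acetate secretion
to net uptake (minute 232 for the ancestor under the worked example's
conditions); a stricter sequential reading (acetate uptake only after
glucose uptake has collapsed below a fraction of its maximum) is
available via `glucose_fraction` and applies cleanly to evolved
genotypes with high glucose capacity, whose co-utilisation window is
narrow.

## Mutation and selection

Mutational supply per genotype per step is
`N_m = N μ dt/(ln2·60) · rate` with rate 1e-6 per cell per generation;
N_m < 1 acts as a Bernoulli probability and N_m ≥ 1 introduces exactly
one mutant (never more). A mutation picks one of the 15 mutable
exchanges uniformly, shifts it by `a ~ U(−A, A)` (A = 10 by default, 1
in the small-step variant), clamps into [0, 40] *before* renormalising
the other entries to the leftover budget (the only order that keeps the
leftover non-negative; a degenerate all-zero remainder is spread
uniformly). Mutants with numerically identical capacity vectors remain
distinct genotypes. The founding cell of a mutant is debited from its
parent, conserving biomass.

Serial transfer draws each genotype's survivors as Binomial(N, 1 %) —
drift at the bottleneck is real — and mixes 99 % fresh with 1 % spent
medium, so secreted byproducts carry over. Day 1 starts from the
dilution of one un-evolved burn-in cycle seeded with a configurable
founding population (default 1e6 cells at full scale, scaled with
reactor volume in the presets), making the first recorded cycle part of
a steady transfer regime. A single seeded generator drives all
randomness; runs are bit-reproducible given (config, seed).

## Scale presets and what the tests show

* `paper`: the full-scale protocol (V = 0.01 l, 550 cycles, rate 1e-6).
  A full run costs hours on one CPU and is configured, not executed, in
  the test suite.
* `desk`: V = 1e-4 l, 150 cycles — same medium dynamics (cell densities
  and concentrations are scale-invariant) but 100× fewer cells, hence
  ~100× lower mutational supply and stronger bottleneck drift. The
  emergence test and the acceptance script run this preset with 5-min
  steps.
* `smoke`: toy model, V = 1e-6 l, 10 cycles, mutation rate raised to
  1e-3 so that the end-to-end path (mutation, selection, transfer,
  output) is exercised in seconds at a mutational supply comparable,
  relative to population size, to the larger presets.

Consequences, as measured by the test suite: desk-scale evolution
reliably produces coexisting lineages — a glucose specialist with
elevated glucose and reduced oxygen capacity (strong overflow) alongside
an acetate-consuming partner — and draws the end-of-day acetate down to
near zero, but within 150 cycles the partner typically remains a
glucose/acetate co-utiliser rather than a full acetate specialist, so
the strict specialist-pair check in the acceptance suite fails at that
horizon. This is the expected supply-limited behaviour: with ~2
establishment-relevant mutants per cycle, refining near-neutral
differences in acetate capacity takes several hundred cycles, and the
desk outcome mirrors the co-utiliser endpoint that the small-mutation-step variant of the
protocol converges to. Runs at larger volume or
longer horizon move the outcome toward the full specialist pair; the
package's presets keep the full-scale rates and thresholds untouched so
that this limitation is visible rather than calibrated away.

## What the synthetic fixtures do and do not emulate

The toy overflow model reproduces the *structure* that matters for the
evolutionary story (efficient respiration vs overflow vs byproduct
respiration under a shared budget) but none of E. coli's pathway
detail; quantitative conclusions about fluxes only ever come from the
core model. The simulator idealises biology in the ways the framework
itself does: no regulation or lag phases (metabolic reallocation is
instantaneous), no mutation of internal reactions or K_m, oxygen never
depletes, and growth follows the linearised update above. Passing tests
therefore validate the algorithmic contract and the model's qualitative
ecology, not quantitative prediction of laboratory populations.

## Known limitations

* Alternate parsimonious optima on the core model are solver-dependent
  in degenerate corners; only μ, not the full flux vector, is oracle-
  checked there.
* The 1-min Euler scheme with the linearised growth factor overshoots
  exponential growth within a step by design fidelity; comparisons
  across `growth_update` settings should hold dt fixed.
* Desk-scale emergence statistics are supply-limited (above); treat the
  strict specialist-pair check as a scale-sensitive integration test,
  not a property of the algorithm.
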