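# evofba

In silico experimental evolution of metabolic uptake strategies: a
simulator that couples **dynamic flux balance analysis** (dFBA) of a
stoichiometric model with an **evolutionary algorithm** over substrate
uptake capacities, under a fixed total-uptake budget, in a daily
serial-transfer (LTEE-style) glucose environment.

It is written for microbial ecologists and systems biologists who want to
ask: *given only a metabolic network and a resource budget, which uptake
strategies evolve, and do cross-feeding specialists emerge?*

## The model

Each genotype *i* is the fixed *E. coli* core metabolic network plus an
evolvable vector of maximum uptake rates `v_max,j` over 15 exchange
reactions (14 carbon sources and oxygen), constrained to a constant total

```
Σ_j v_max,j = C_total = 40 mmol/gDW/h
```

Within a 24-h batch cycle (1-min Euler steps), each step solves a
two-stage FBA:

1. maximise biomass flux μ subject to steady state `S·v = 0`, default
   bounds, Michaelis–Menten uptake caps
   `v_j = v_max,j · [S_j] / (K_m + [S_j])` (K_m = 0.01 mmol/l), and an
   explicit budget row `Σ uptake ≤ C_total`;
2. at fixed μ, minimise `Σ|v|` (parsimonious tie-break).

Biomass and medium then update as

```
BM(t+1) = BM(t) · (1 + μ/(ln2·60))        [gDW, per minute]
[S_j](t+1) = [S_j](t) − Σ_i BM_i v_{j,i} / (60·V)   [mmol/l]
```

Mutations arrive at rate 10⁻⁶ per cell per generation
(`N_m = N μ /(ln2·60·10⁶)` per minute, at most one mutant per genotype
per step), pick one uptake at random, shift it by `a ~ U(−10, 10)`,
clamp to `[0, 40]` and rescale the rest to keep the budget. After 24 h,
1 % of cells (binomial per genotype) and 1 % of spent medium carry over
into fresh glucose medium (0.1389 mmol/l, 10-ml reactor), for 550 cycles.

## Worked example

One serial-transfer day of the ancestor (capacities 10/10/20 for
glucose/acetate/oxygen) in LTEE-strength glucose:

```
$ python examples/ancestor_diauxie.py
final population: 2.86e+08 cells
glucose consumed: 99.70 %
acetate peak: 0.00105 mmol/l at minute 231
diauxic switch to net acetate uptake at minute 232
```

While glucose saturates the oxygen capacity the organism ferments the
surplus and the acetate pool grows; once glucose becomes limiting it
switches to consuming that acetate — the overflow/diauxie behaviour whose
evolutionary amplification produces cross-feeding. Evolving populations
(`examples/scaled_evolution.py`, `evofba run --scale desk`) raise glucose
uptake at the cost of oxygen, secrete more acetate, and open an acetate
niche that other lineages colonise.

Other entry points:

```
evofba run --scale smoke --seed 1 --out out/     # end-to-end in seconds
evofba fluxes --model ecoli_core --genotype 1    # glucose/acetate-phase flux maps
evofba lineage --results out/ --min-pop 1e5      # lineage graph (GraphML/DOT)
python examples/budgeted_fba.py                  # two-stage budgeted FBA, toy model
python examples/flux_snapshots.py                # glyoxylate-shunt flux rearrangement
```

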