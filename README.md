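# collapsim

An agent-based network model of societal complexity and collapse, with a
deterministic mean-field approximation and right-censored survival-time
experiments.

The model is aimed at researchers in social-ecological systems and
complexity science who want a minimal, fully reproducible testbed for the
hypothesis that societies collapse through an *energy–complexity spiral*:
problem solving grows a costly administrative class, returns on that
complexity diminish, and the society is eventually driven into a state
where nobody produces energy any more.

## The model

A society of `N` nodes on an Erdős–Rényi graph `G(N, ρ)`. Each node is an
**administrator** (A), a **coordinated laborer** (C — a non-administrator
adjacent to ≥ 1 administrator) or an **uncoordinated laborer** (L). Each
time step:

1. *Social mobility*: every node switches sides (A ↔ L/C) with probability
   `p_e`.
2. *Shock*: the per-node resource is `R = R_max (1 − B)` with
   `B ~ Beta(α, β)`; `R_max = N/N^a` calibrates the unperturbed per-capita
   output to 1.
3. *Production*: `E = R (N_L^a + c N_C^b)`. Administrators produce
   nothing; coordinated laborers enjoy a productivity premium `c > 1`.
4. *Problem solving*: if `E/N < ε`, the best-connected eligible node
   (coordinated laborer; or any connected laborer if there are no
   administrators yet) is promoted to administrator.

Collapse is the absorbing state `N_A = N` (then `E = 0`). Societal
complexity is measured as `S = N_A`, so the return on complexity after a
recruitment reduces to `ROC(t) = E(t) − E(t−1)`.

For large `N` the expected administrator count follows the mean-field
dynamics

```
dN_A/dt = p_e (N − 2 N_A) + F(N^a ε / e ; β, α),
e = N_L^a + c N_C^b,   N_L = (N − N_A)(1 − ρ)^N_A,   N_C = (N − N_A) − N_L
```

with `F` the Beta CDF. The collapse state `N_A = N` attracts these
dynamics exactly when `p_e < 1/N`: roughly one random status change per
time step is enough to keep a society out of the spiral.

## Worked example

```python
from collapsim import (ModelParams, run_simulation, integrate_macro,
                       critical_exploration, find_fixed_points)

p = ModelParams(seed=1)           # N=400, Beta(1,15) shocks, c=1.05, rho=0.02
res = run_simulation(p)
print(res.survival_time, res.censored, res.terminal_cause)
# 834 False all-administrators

tr = integrate_macro(p)
print(tr.survival_time)           # 710  (mean-field, slightly faster collapse)
print(critical_exploration(p))    # 0.0025 = 1/N

hi = run_simulation(p.replace(p_e=0.02, t_max=5000))
print(hi.columns["N_A"][3000:].mean() / 400)          # 0.564
print(hi.columns["E_per_capita"][3000:].mean())       # 0.535
print(find_fixed_points(p.replace(p_e=0.02)))
# [FixedPoint(n_a=225.0, stable=True), FixedPoint(n_a=400.0, stable=False, boundary=True)]
```

Reading: without mobility the seed-1 society collapses after 834 steps,
its per-capita energy peaking at 1.175 around t = 176 before the decline —
the rise-then-fall arc of diminishing returns. At `p_e = 0.02` (above the
critical `1/N = 0.0025`) the collapse state is repelling and the society
settles at the stable equilibrium `N_A* = N/2 + 1/(2 p_e) = 225`: a slight
administrator majority (share 0.56) producing about half the per-capita
energy of the initial state, indefinitely.

The same experiments are available from the shell:

```bash
collapsim simulate --seed 1 --out runs/ref
collapsim macro --pe 0.02 --out runs/macro
collapsim ensemble --runs 100 --base-seed 0 --out runs/ens
collapsim sweep --pe-grid 0.0:0.2:21 --out runs/sweep
```

Each command writes CSV tables plus a JSON manifest (full parameter set,
seeds, package version) sufficient to reproduce the outputs byte-for-byte.

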