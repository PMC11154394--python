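# Methods

## Model

The simulator couples three mechanisms on a static Erdős–Rényi graph
`G(N, ρ)` with nodes `0..N−1`:

* **Shocks.** The per-node resource at each step is `R = R_max (1 − B)`,
  `B ~ Beta(α, β)`. With the default shapes (1, 15) most draws are mild
  (`E[B] = 1/16`) with a thin tail of severe shocks
  (`P(B > 0.2) = 0.8^15 ≈ 0.035`). `R_max = N/N^a` is derived, never
  user-set: it normalizes the unshocked all-laborer society to a
  per-capita output of exactly 1, so the threshold `ε = 1` means "the
  society sits exactly at its subsistence level before any shock".
* **Production.** `E = R (N_L^a + c N_C^b)` with `0^a := 0`. The class
  split is purely structural: a non-administrator is *coordinated* iff it
  has at least one administrator neighbour (multiple administrator links
  give no extra premium). Administrators produce nothing — that is the
  carrying cost of complexity.
* **Recruitment.** When `E/N < ε` (strict comparison), exactly one node is
  promoted: the best-connected laborer with degree ≥ 1 if there are no
  administrators yet, otherwise the best-connected coordinated laborer.
  Degree ties are broken uniformly at random with the run RNG — the
  alternative (lowest node id) would silently couple outcomes to the
  arbitrary node labelling. If the eligible pool is empty (edgeless or
  fragmented networks), no recruitment happens that step; this is what
  makes `ρ = 0` a stasis case and produces the rare long-lived runs on
  fragmented networks that the mean-field cannot represent.
* **Exploration (social mobility).** At the beginning of each step every
  node independently changes side (A → labor force, or L/C → A) with
  probability `p_e`. Flips are decided in one Bernoulli draw per node and
  committed synchronously, avoiding any order dependence. Only the
  admin/non-admin distinction is stochastic; the C-vs-L label of a
  demoted administrator follows from adjacency to the post-flip
  administrator set.

Step order is exploration → shock → production → recruitment check. A
promotion at step `t` changes production from step `t+1` on; the recorded
state of step `t` is therefore post-exploration, pre-recruitment. The run
stops when a step's classification shows `N_A = N` (the recorded energy is
then 0 and would remain 0) or at `t_max`, in which case the survival time
is right-censored.

One `numpy.random.Generator` seeded from `ModelParams.seed` drives network
construction, exploration, shocks and tie-breaks in a fixed draw order, so
trajectories are bit-reproducible from `(params, seed)`. When `p_e = 0`
the exploration draw is skipped entirely (the per-node Bernoulli vector
would change the stream but never the state).

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `n` | nodes | 400 | fixed over a run |
| `t_max` | censoring horizon (steps) | 10 000 | |
| `alpha`, `beta` | shock shapes | 1, 15 | mild-but-occasionally-severe regime |
| `epsilon` | per-capita demand | 1.0 | equals the calibrated unshocked output |
| `a`, `b` | output elasticities | 0.75, 0.75 | decreasing returns to scale; `0 < a,b ≤ 1` accepted |
| `c` | coordination premium | 1.05 | ≥ 1; sweep range 1–3 |
| `rho` | link probability | 0.02 | mean degree ≈ 8; sweep range 0–0.1 |
| `p_e` | mobility probability | 0.0 | sweep range 0–0.2; critical value 1/N |
| `seed` | RNG seed | 0 | |

## Mean-field approximation

Assuming homogeneous link density, a non-administrator avoids all `N_A`
administrators with probability `(1−ρ)^N_A`, giving closed-form group
sizes and the one-dimensional dynamics

```
dN_A/dt = p_e (N − 2 N_A) + F(N^a ε / e ; β, α)
```

with `F` the Beta CDF (shapes swapped because `1 − B ~ Beta(β, α)`; the
argument is clamped to [0, 1], with `e = 0` meaning certain recruitment).
Two numerical choices:

* **Eligibility gate.** The recruitment term is set to zero at `ρ = 0`:
  targeted promotion needs a network connection, so an edgeless society
  can never recruit, exactly as in the micro-model. For `ρ > 0` the gate
  never binds (the mean-field coordinated count is strictly positive for
  `0 < N_A < N`).
* **Expected-shock energy.** The mean-field per-capita energy curve uses
  `E[1 − B] = β/(α+β)` (15/16 at defaults) as the shock factor — the
  natural mean-field reading of the stochastic resource.

The reference integrator is explicit Euler with `dt = 1`: the micro-model
is a discrete-time map recruiting at most about one administrator per
step, so the unit-step map is the faithful deterministic counterpart (an
adaptive RK45 alternative is available behind a flag). The continuous
state is clipped to `[0, N]` and declared collapsed at `N_A ≥ N − 0.5`
(half-count rounding of the discrete absorbing state, which the ODE only
reaches asymptotically).

Fixed points are located by sign-change bracketing on a 2001-point grid
with Brent polishing; stability is the sign of a central-difference
derivative. The boundary `N_A = N` is always reported as a fixed point of
the capped dynamics, attracting iff the rhs is positive just inside the
boundary — analytically iff `p_e < 1/N`, and the numerical bisection on
the boundary rhs recovers `1/N` to better than 1e-9. Note that a genuine
interior *root* near `N/2` in the large-`c` regime requires `p_e > 0`:
with `p_e = 0` the rhs equals the recruitment probability, which is
strictly positive for `ρ > 0` and only tends to zero as `c` grows, so the
half-administration state is then a slow passage, not an equilibrium.

## Experiments and problem sizes

* **Ensembles** run `n_runs` independent simulations with seeds
  `base_seed + i`. Survival medians treat censored runs at `t_max` (even
  samples: midpoint of the two central order statistics — censored
  midpoints are convention-dependent, so the convention is fixed here);
  a median at the cap is flagged as "≥ t_max, potentially infinite".
  Histograms use 250-step bins with a terminal right-censored bar
  collecting everything at or beyond the display cap (default 5000).
* **Sweeps** over `(ρ, c, p_e)` use the mean-field integration from
  `N_A(0) = 0`, vectorised over all grid cells (no RNG involved; the
  default grids are 21 points per axis over ρ ∈ [0, 0.1], c ∈ [1, 3],
  p_e ∈ [0, 0.2]). Stochastic ensembles serve as spot checks: on a
  3×3×2 subgrid with mean degree ≥ 6 the macro and micro survival
  orderings agree with rank correlation > 0.99. Below mean degree ≈ 4
  the comparison degrades by design — network fragmentation leaves
  admin-free components that the homogeneous mean-field cannot see.
* **Metastability probe**: sojourn time of the administrator share inside
  `[0.5 − δ, 0.5 + δ]` (default δ = 0.1), contrasting the fast
  pass-through at the reference configuration with the long plateau at
  large `c` and `p_e` just below `1/N`.

Test and acceptance workloads are scaled to desk size as the package's own
defaults: micro/mean-field path comparisons use 100 runs over a 3000-step
horizon (collapsed runs held at the absorbing share 1), high-mobility
steady-state statistics use ≥ 10 seeds with a 2000-step post-transient
window, and the ordering spot check uses 10 seeds per cell at `N = 200`.

## What the generator does and does not emulate

All data are synthetic by construction — the model *is* the study object.
The simulator reproduces the mechanism (shock-driven ratchet growth of a
non-producing class, diminishing returns, collapse or mobility-stabilised
equilibrium) on one network family (Erdős–Rényi) with fixed population,
static topology, a single hierarchy layer and i.i.d. shocks. Passing tests
therefore demonstrate internal consistency of the mechanism and agreement
between the stochastic model and its mean-field reduction — not realism of
any particular historical society. No population growth, resource
depletion, competition between societies, dynamic rewiring or heavy-tailed
degree distributions are modelled; the mean-field's known bias (it
slightly overestimates collapse speed at `p_e = 0` because it ignores the
above-average degree of early recruits) is accepted rather than corrected.

## Known limitations

* Degree heterogeneity is ignored by the mean-field; discrepancies at
  `p_e = 0` and at low mean degree are expected and documented above.
* The turning point `p_e0 < 1/N` at which median survival is minimal is
  exposed only as a sweepable observable (argmin over a `p_e` grid), with
  no closed form claimed.
* Collapse is hard-wired for `p_e = 0`: administrators never return to
  the labor force, so every connected society eventually collapses; this
  ratchet is a modelling assumption, not an empirical claim.
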