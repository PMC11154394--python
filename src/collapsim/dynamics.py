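"""Stochastic micro-dynamics of the networked society.

Each time step proceeds in a fixed order:

1. **exploration** — every node independently switches between the
   administrator and non-administrator side with probability ``p_e``
   (synchronous commit);
2. **shock** — the per-node resource is drawn as ``R = R_max * (1 - B)``
   with ``B ~ Beta(alpha, beta)``;
3. **production** — roles are classified on the post-flip network and the
   total energy ``E = R * (N_L**a + c * N_C**b)`` is computed;
4. **return on complexity** — recorded as ``E(t) - E(t-1)`` (the complexity
   increment per recruitment is exactly one administrator, so the
   denominator of the return-on-complexity ratio is identically 1);
5. **recruitment** — if ``E/N < epsilon``, the best-connected eligible node
   is promoted; the promotion affects production only from the next step.

The run terminates when every node is an administrator (collapse: no labor,
hence E = 0 from then on) or at ``t_max`` (right-censored).

A single seeded :class:`numpy.random.Generator` drives network construction,
exploration flips, shock draws and recruitment tie-breaks, in that fixed
order, so a run is fully reproducible from ``(params, seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .society import (
    ModelParams,
    SocietyState,
    ValidationError,
    build_network,
    classify_roles,
)

__all__ = [
    "StepRecord",
    "SimulationResult",
    "draw_shock",
    "compute_energy",
    "select_recruit",
    "exploration_step",
    "step",
    "run_simulation",
    "roc_curve",
]

logger = logging.getLogger(__name__)

CAUSE_COLLAPSE = "all-administrators"
CAUSE_CENSORED = "reached-t_max"

#: fixed public column order of the trajectory table
TRAJECTORY_COLUMNS = (
    "t",
    "R",
    "N_L",
    "N_C",
    "N_A",
    "E",
    "E_per_capita",
    "roc",
    "n_flips",
    "recruited",
)


@dataclass(frozen=True)
class StepRecord:
    """Observables of one time step (pre-recruitment state of that step)."""

    t: int
    r: float
    n_l: int
    n_c: int
    n_a: int
    e: float
    e_per_capita: float
    roc: float | None
    n_flips: int
    recruited: bool


@dataclass
class SimulationResult:
    """Full trajectory of one run plus its survival outcome.

    ``survival_time`` is the index of the last simulated step; ``censored``
    is true iff the run reached ``t_max`` without collapsing, in which case
    the survival time is only a lower bound on the society's lifetime.
    """

    params: ModelParams
    columns: dict  # column name (TRAJECTORY_COLUMNS) -> numpy array
    survival_time: int
    censored: bool
    terminal_cause: str

    @cached_property
    def records(self) -> list[StepRecord]:
        c = self.columns
        roc = c["roc"]
        return [
            StepRecord(
                t=int(c["t"][i]),
                r=float(c["R"][i]),
                n_l=int(c["N_L"][i]),
                n_c=int(c["N_C"][i]),
                n_a=int(c["N_A"][i]),
                e=float(c["E"][i]),
                e_per_capita=float(c["E_per_capita"][i]),
                roc=None if np.isnan(roc[i]) else float(roc[i]),
                n_flips=int(c["n_flips"][i]),
                recruited=bool(c["recruited"][i]),
            )
            for i in range(len(c["t"]))
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.columns[k] for k in TRAJECTORY_COLUMNS})

    @property
    def admin_share(self) -> np.ndarray:
        return self.columns["N_A"] / self.params.n


def draw_shock(params: ModelParams, rng: np.random.Generator) -> float:
    """One realized per-node resource ``R = R_max * (1 - B)``.

    ``B ~ Beta(alpha, beta)`` is the shock magnitude: at the default
    Beta(1, 15), most draws leave R close to R_max with a rare chance of a
    severe reduction.  R always lies in [0, R_max].
    """
    if params.alpha <= 0 or params.beta <= 0:
        raise ValidationError(["alpha/beta: Beta shape parameters must be > 0"])
    b = rng.beta(params.alpha, params.beta)
    return params.r_max * (1.0 - b)


def compute_energy(n_l: int, n_c: int, r: float, params: ModelParams) -> float:
    """Total energy ``E = R * (N_L**a + c * N_C**b)`` (0**a taken as 0)."""
    if n_l < 0 or n_c < 0:
        raise ValueError(f"role counts must be non-negative, got ({n_l}, {n_c})")
    if r < 0:
        raise ValueError(f"resource must be non-negative, got {r}")
    labor = 0.0 if n_l == 0 else float(n_l) ** params.a
    coord = 0.0 if n_c == 0 else float(n_c) ** params.b
    return r * (labor + params.c * coord)


def select_recruit(state: SocietyState, rng: np.random.Generator) -> int | None:
    """Pick the node to promote, or ``None`` when nobody is eligible.

    With no administrators yet, the best-connected laborer (degree >= 1)
    becomes the sole administrator; afterwards only coordinated laborers are
    eligible, and the best-connected one is promoted.  Degree ties are
    broken uniformly at random with the run RNG.
    """
    if state.n_admin == 0:
        mask = state.laborer_mask & (state.degrees > 0)
    else:
        mask = state.coordinated_mask
    if not mask.any():
        return None
    deg = np.where(mask, state.degrees, -1)
    top = deg.max()
    candidates = np.flatnonzero(deg == top)
    if len(candidates) == 1:
        return int(candidates[0])
    return int(candidates[rng.integers(len(candidates))])


def exploration_step(
    state: SocietyState, params: ModelParams, rng: np.random.Generator
) -> int:
    """Random social mobility: each node flips sides with probability p_e.

    All nodes are flagged in one synchronous Bernoulli draw and the flips
    are committed simultaneously: flagged administrators leave the
    administration, flagged non-administrators join it, and the C/L labels
    follow from adjacency to the final administrator set.  Returns the
    number of flipped nodes.
    """
    if params.p_e == 0.0:
        return 0
    flagged = np.flatnonzero(rng.random(state.n) < params.p_e)
    for v in flagged:
        state.toggle(v)  # toggling commutes, so sequential == synchronous
    return len(flagged)


def step(
    state: SocietyState,
    prev_e: float | None,
    params: ModelParams,
    rng: np.random.Generator,
    t: int = 0,
) -> StepRecord:
    """Advance the society by one time step and return its observables.

    The record reflects the post-exploration, pre-recruitment state: a
    promotion triggered this step changes production only from the next
    step onward.
    """
    n_flips = exploration_step(state, params, rng)
    r = draw_shock(params, rng)
    n_l, n_c, n_a = classify_roles(state)
    e = compute_energy(n_l, n_c, r, params)
    roc = None if prev_e is None else e - prev_e
    recruited = False
    if e / params.n < params.epsilon:
        v = select_recruit(state, rng)
        if v is not None:
            state.promote(v)
            recruited = True
    return StepRecord(
        t=t,
        r=r,
        n_l=n_l,
        n_c=n_c,
        n_a=n_a,
        e=e,
        e_per_capita=e / params.n,
        roc=roc,
        n_flips=n_flips,
        recruited=recruited,
    )


def run_simulation(params: ModelParams) -> SimulationResult:
    """Run the micro-model from a fresh network until collapse or t_max.

    Deterministic given ``params`` (including the seed).  The final record
    of a collapsed run shows ``N_A = N`` and ``E = 0``.
    """
    rng = np.random.default_rng(params.seed)
    state = build_network(params, rng)

    t_max = params.t_max
    col_t = np.empty(t_max, dtype=np.int64)
    col_r = np.empty(t_max)
    col_nl = np.empty(t_max, dtype=np.int64)
    col_nc = np.empty(t_max, dtype=np.int64)
    col_na = np.empty(t_max, dtype=np.int64)
    col_e = np.empty(t_max)
    col_roc = np.full(t_max, np.nan)
    col_flips = np.empty(t_max, dtype=np.int64)
    col_recr = np.empty(t_max, dtype=bool)

    prev_e: float | None = None
    steps_done = 0
    collapsed = False
    for t in range(1, t_max + 1):
        rec = step(state, prev_e, params, rng, t=t)
        i = t - 1
        col_t[i] = rec.t
        col_r[i] = rec.r
        col_nl[i] = rec.n_l
        col_nc[i] = rec.n_c
        col_na[i] = rec.n_a
        col_e[i] = rec.e
        if rec.roc is not None:
            col_roc[i] = rec.roc
        col_flips[i] = rec.n_flips
        col_recr[i] = rec.recruited
        prev_e = rec.e
        steps_done = t
        if rec.n_a == params.n:
            collapsed = True
            break

    sl = slice(0, steps_done)
    columns = {
        "t": col_t[sl].copy(),
        "R": col_r[sl].copy(),
        "N_L": col_nl[sl].copy(),
        "N_C": col_nc[sl].copy(),
        "N_A": col_na[sl].copy(),
        "E": col_e[sl].copy(),
        "E_per_capita": (col_e[sl] / params.n).copy(),
        "roc": col_roc[sl].copy(),
        "n_flips": col_flips[sl].copy(),
        "recruited": col_recr[sl].copy(),
    }
    result = SimulationResult(
        params=params,
        columns=columns,
        survival_time=steps_done,
        censored=not collapsed,
        terminal_cause=CAUSE_COLLAPSE if collapsed else CAUSE_CENSORED,
    )
    logger.info(
        "run seed=%d survival_time=%d censored=%s",
        params.seed,
        result.survival_time,
        result.censored,
    )
    return result


def roc_curve(result: SimulationResult, window: int = 50) -> pd.DataFrame:
    """Smoothed energy as a function of administration size.

    A centred moving average of E(t) (window length ``window``, in steps)
    is paired with N_A(t); plotting the two columns against each other
    reproduces the rise-then-fall arc of diminishing marginal returns on
    complexity.  ``window=1`` returns the raw energy series.
    """
    if len(result.columns["t"]) == 0:
        raise ValueError("empty trajectory")
    if window < 1:
        raise ValueError("window must be >= 1")
    e = pd.Series(result.columns["E"])
    smooth = e.rolling(window, center=True, min_periods=1).mean()
    return pd.DataFrame(
        {"N_A": result.columns["N_A"], "E_smooth": smooth.to_numpy()}
    )
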