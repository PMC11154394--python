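"""Ensemble runs, censored survival statistics and parameter sweeps.

Survival times are right-censored at ``t_max``: a run that never collapses
only gives a lower bound on the society's lifetime.  Central tendency is
therefore reported as the sample median (censored entries counted at
``t_max`` and flagged when the median itself sits at the cap), and
histograms accumulate censored runs in a terminal right-censored bar.

The (rho, c, p_e) survival maps are computed from the deterministic
mean-field approximation — one Euler integration per grid cell, vectorised
over the whole grid — with stochastic ensembles reserved for spot checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc

from .dynamics import run_simulation
from .macro import COLLAPSE_MARGIN
from .society import ModelParams

__all__ = [
    "EnsembleResult",
    "SweepResult",
    "run_ensemble",
    "ensemble_mean_share",
    "median_survival",
    "survival_histogram",
    "parameter_sweep",
    "metastability_probe",
    "DEFAULT_RHO_GRID",
    "DEFAULT_C_GRID",
    "DEFAULT_PE_GRID",
]

# default sweep ranges of the reference configuration (21 points per axis)
DEFAULT_RHO_GRID = np.linspace(0.0, 0.1, 21)
DEFAULT_C_GRID = np.linspace(1.0, 3.0, 21)
DEFAULT_PE_GRID = np.linspace(0.0, 0.2, 21)


@dataclass
class EnsembleResult:
    """Survival outcomes of independent runs at one parameter set.

    ``share_paths`` / ``energy_paths`` (kept on request) hold the per-step
    administrator share and per-capita energy of each run, padded after a
    collapse with the absorbing values 1 and 0.
    """

    params: ModelParams
    n_runs: int
    seeds: list[int]
    survival_times: np.ndarray
    censored_flags: np.ndarray
    share_paths: np.ndarray | None = None
    energy_paths: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": self.seeds,
                "survival_time": self.survival_times,
                "censored": self.censored_flags,
            }
        )


def run_ensemble(
    params: ModelParams,
    n_runs: int,
    base_seed: int,
    keep_paths: bool = False,
) -> EnsembleResult:
    """Run ``n_runs`` independent simulations with seeds base_seed + i.

    Deterministic and order-stable given ``base_seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [base_seed + i for i in range(n_runs)]
    survival = np.empty(n_runs, dtype=np.int64)
    censored = np.empty(n_runs, dtype=bool)
    shares = np.ones((n_runs, params.t_max)) if keep_paths else None
    energies = np.zeros((n_runs, params.t_max)) if keep_paths else None
    for i, seed in enumerate(seeds):
        res = run_simulation(params.replace(seed=seed))
        survival[i] = res.survival_time
        censored[i] = res.censored
        if keep_paths:
            m = res.survival_time
            shares[i, :m] = res.columns["N_A"] / params.n
            energies[i, :m] = res.columns["E_per_capita"]
            # collapsed runs stay absorbed at share 1, energy 0 after the end
    return EnsembleResult(
        params=params,
        n_runs=n_runs,
        seeds=seeds,
        survival_times=survival,
        censored_flags=censored,
        share_paths=shares,
        energy_paths=energies,
    )


def ensemble_mean_share(result: EnsembleResult) -> np.ndarray:
    """Per-step ensemble mean of the administrator share (paths required)."""
    if result.share_paths is None:
        raise ValueError("ensemble was run without keep_paths=True")
    return result.share_paths.mean(axis=0)


def median_survival(result: EnsembleResult) -> tuple[float, bool]:
    """Censored sample median of the survival times.

    Censored runs enter at ``t_max``; an even-length sample uses the
    midpoint of the two central order statistics.  ``at_cap`` is true when
    the median sits at ``t_max`` and is therefore only a lower bound
    ("potentially infinite").
    """
    if result.n_runs < 1:
        raise ValueError("empty ensemble")
    med = float(np.median(result.survival_times))
    return med, med >= result.params.t_max


def survival_histogram(
    result: EnsembleResult,
    bins: np.ndarray | None = None,
    bin_width: int = 250,
    display_cap: int = 5000,
) -> pd.DataFrame:
    """Binned collapse frequencies with a terminal right-censored bar.

    Runs that collapsed before ``display_cap`` are binned normally
    (default width 250 steps); censored runs and any survival at or beyond
    the cap are accumulated in the terminal ``[display_cap, inf)`` bar.
    Explicit ``bins`` (edges up to the cap) override the default width.
    """
    if result.n_runs < 1:
        raise ValueError("empty ensemble")
    if bins is None:
        bins = np.arange(0, display_cap + bin_width, bin_width)
    bins = np.asarray(bins, dtype=float)
    display_cap = float(bins[-1])

    times = result.survival_times.astype(float)
    in_bar = result.censored_flags | (times >= display_cap)
    counts, _ = np.histogram(times[~in_bar], bins=bins)
    table = pd.DataFrame(
        {
            "bin_start": bins[:-1],
            "bin_end": bins[1:],
            "count": counts,
            "is_censored_bin": False,
        }
    )
    bar = pd.DataFrame(
        {
            "bin_start": [display_cap],
            "bin_end": [np.inf],
            "count": [int(in_bar.sum())],
            "is_censored_bin": [True],
        }
    )
    return pd.concat([table, bar], ignore_index=True)


@dataclass
class SweepResult:
    """Mean-field survival times over a (rho, c, p_e) grid.

    ``survival`` has shape (len(rho_values), len(c_values), len(pe_values));
    ``censored`` flags cells that never collapsed within ``t_max`` (their
    survival entry is the cap and a lower bound only).
    """

    base_params: ModelParams
    rho_values: np.ndarray
    c_values: np.ndarray
    pe_values: np.ndarray
    survival: np.ndarray
    censored: np.ndarray
    t_max: int

    def to_dataframe(self) -> pd.DataFrame:
        r, c, p = np.meshgrid(
            self.rho_values, self.c_values, self.pe_values, indexing="ij"
        )
        return pd.DataFrame(
            {
                "rho": r.ravel(),
                "c": c.ravel(),
                "p_e": p.ravel(),
                "survival_time": self.survival.ravel(),
                "censored": self.censored.ravel(),
            }
        )

    def median_over_rho(self) -> pd.DataFrame:
        """Median survival over the rho axis, per (p_e, c) pair."""
        med = np.median(self.survival, axis=0)
        c, p = np.meshgrid(self.c_values, self.pe_values, indexing="ij")
        return pd.DataFrame(
            {
                "p_e": p.ravel(),
                "c": c.ravel(),
                "median_survival": med.ravel(),
            }
        )


def parameter_sweep(
    base_params: ModelParams,
    rho_values: np.ndarray | None = None,
    c_values: np.ndarray | None = None,
    pe_values: np.ndarray | None = None,
    t_max: int | None = None,
) -> SweepResult:
    """Mean-field survival time for every (rho, c, p_e) grid cell.

    Each cell integrates the deterministic administrator dynamics from
    N_A(0) = 0 with unit Euler steps (the same recursion as
    :func:`collapsim.macro.integrate_macro`, vectorised over all cells) and
    records the first step at which N_A >= N - 0.5, capped at ``t_max``.
    The sweep is a pure function of its inputs — no RNG is involved.
    """
    rho_values = DEFAULT_RHO_GRID if rho_values is None else np.asarray(rho_values, float)
    c_values = DEFAULT_C_GRID if c_values is None else np.asarray(c_values, float)
    pe_values = DEFAULT_PE_GRID if pe_values is None else np.asarray(pe_values, float)
    if rho_values.size == 0 or c_values.size == 0 or pe_values.size == 0:
        raise ValueError("sweep grids must be non-empty")
    if (rho_values < 0).any() or (rho_values > 1).any():
        raise ValueError("rho grid must lie in [0, 1]")
    if (pe_values < 0).any() or (pe_values > 1).any():
        raise ValueError("p_e grid must lie in [0, 1]")
    if t_max is None:
        t_max = base_params.t_max

    p = base_params
    n = float(p.n)
    rho_f, c_f, pe_f = (
        g.ravel()
        for g in np.meshgrid(rho_values, c_values, pe_values, indexing="ij")
    )
    m = rho_f.size
    n_a = np.zeros(m)
    survival = np.full(m, t_max, dtype=np.int64)
    done = np.zeros(m, dtype=bool)
    demand = n**p.a * p.epsilon
    for t in range(1, t_max + 1):
        rest = n - n_a
        avoid = np.power(1.0 - rho_f, n_a)
        n_l = rest * avoid
        n_c = rest - n_l
        e = n_l**p.a + c_f * n_c**p.b
        x = np.where(e > 0.0, demand / np.where(e > 0.0, e, 1.0), np.inf)
        np.clip(x, 0.0, 1.0, out=x)
        prob = betainc(p.beta, p.alpha, x)
        prob[rho_f == 0.0] = 0.0  # no link, no eligible recruit (same gate as macro_rhs)
        n_a = np.clip(n_a + pe_f * (n - 2.0 * n_a) + prob, 0.0, n)
        hit = (n_a >= n - COLLAPSE_MARGIN) & ~done
        if hit.any():
            survival[hit] = t
            done |= hit
            if done.all():
                break

    shape = (len(rho_values), len(c_values), len(pe_values))
    return SweepResult(
        base_params=p,
        rho_values=rho_values,
        c_values=c_values,
        pe_values=pe_values,
        survival=survival.reshape(shape),
        censored=(~done).reshape(shape),
        t_max=t_max,
    )


def metastability_probe(
    params: ModelParams,
    n_runs: int,
    base_seed: int = 0,
    delta: float = 0.1,
) -> pd.DataFrame:
    """Sojourn time of stochastic runs near the half-administration state.

    For each run, counts the steps whose administrator share lies within
    ``[0.5 - delta, 0.5 + delta]`` together with the survival outcome.
    Intended for the metastable regime (p_e just below 1/N with large c),
    where runs linger near N_A = N/2 before a large shock pushes them into
    the collapse basin; at the reference configuration the band is crossed
    almost instantly.
    """
    ens = run_ensemble(params, n_runs, base_seed, keep_paths=True)
    rows = []
    for i in range(n_runs):
        lived = ens.survival_times[i]
        share = ens.share_paths[i, :lived]
        sojourn = int(
            np.count_nonzero((share >= 0.5 - delta) & (share <= 0.5 + delta))
        )
        rows.append(
            {
                "seed": ens.seeds[i],
                "sojourn_steps": sojourn,
                "survival_time": int(lived),
                "censored": bool(ens.censored_flags[i]),
            }
        )
    return pd.DataFrame(rows)
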