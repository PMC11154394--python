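"""Deterministic mean-field approximation of the stochastic micro-model.

For large N the expected administrator count follows the one-dimensional
dynamics

    dN_A/dt = p_e * (N - 2 N_A) + P(N_A),

where the first term is the net exploration balance (p_e * N_A leave, and
p_e * (N - N_A) join the administration per unit time) and P(N_A) is the
probability that the per-capita energy falls below the threshold and one
administrator is recruited.  Under the homogeneous-density assumption, a
non-administrator avoids all N_A administrators with probability
(1 - rho)**N_A, giving the closed-form group sizes

    N_L = (N - N_A) * (1 - rho)**N_A,
    N_C = (N - N_A) * (1 - (1 - rho)**N_A),

an energy factor e = N_L**a + c * N_C**b, and — because 1 - B follows a
Beta(beta, alpha) law — the recruitment probability

    P = F(N**a * eps / e; beta, alpha)

with F the Beta CDF (argument clamped to [0, 1]; e = 0 means recruitment is
certain).  The all-administrator boundary N_A = N is the collapse state; it
attracts the capped dynamics exactly when p_e < 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import betainc

from .society import ModelParams

__all__ = [
    "FixedPoint",
    "MacroTrajectory",
    "macro_counts",
    "energy_factor",
    "recruitment_probability",
    "macro_rhs",
    "integrate_macro",
    "find_fixed_points",
    "critical_exploration",
    "rescale_density",
]

#: a continuous administrator count this close to N counts as collapsed
COLLAPSE_MARGIN = 0.5


@dataclass(frozen=True)
class FixedPoint:
    """A root of the mean-field rhs with its linear stability."""

    n_a: float
    stable: bool
    boundary: bool = False  # True for the capped collapse state N_A = N


@dataclass
class MacroTrajectory:
    """Deterministic N_A(t) path with its predicted energy and survival."""

    params: ModelParams
    times: np.ndarray
    n_a_path: np.ndarray
    e_per_capita: np.ndarray
    survival_time: int
    censored: bool

    @property
    def admin_share(self) -> np.ndarray:
        return self.n_a_path / self.params.n


def _check_range(n_a: float, n: float) -> None:
    if not (0.0 <= n_a <= n):
        raise ValueError(f"N_A must lie in [0, {n}], got {n_a}")


def macro_counts(n_a: float, params: ModelParams) -> tuple[float, float]:
    """Mean-field laborer and coordinated-laborer counts at a given N_A.

    Exact algebraic identity: the two counts always sum to N - N_A.
    """
    _check_range(n_a, params.n)
    avoid = (1.0 - params.rho) ** n_a
    rest = params.n - n_a
    return rest * avoid, rest * (1.0 - avoid)


def energy_factor(n_a: float, params: ModelParams) -> float:
    """Deterministic energy factor e = N_L**a + c * N_C**b at a given N_A."""
    n_l, n_c = macro_counts(n_a, params)
    labor = 0.0 if n_l == 0 else n_l**params.a
    coord = 0.0 if n_c == 0 else n_c**params.b
    return labor + params.c * coord


def recruitment_probability(n_a: float, params: ModelParams) -> float:
    """Probability that the per-capita energy shortfall triggers recruitment.

    ``P = F(N**a * eps / e; beta, alpha)`` with F the Beta CDF — the shape
    order is swapped relative to the shock because ``1 - B ~ Beta(beta,
    alpha)``.  The argument is clamped to [0, 1]: when even the unshocked
    energy cannot meet demand (x > 1) recruitment is certain, and e = 0
    (all administrators) likewise gives P = 1.
    """
    _check_range(n_a, params.n)
    e = energy_factor(n_a, params)
    if e <= 0.0:
        return 1.0
    x = params.n**params.a * params.epsilon / e
    x = min(max(x, 0.0), 1.0)
    return float(betainc(params.beta, params.alpha, x))


def macro_rhs(n_a: float, params: ModelParams) -> float:
    """Right-hand side of the mean-field administrator dynamics.

    The recruitment term is gated on the existence of an eligible
    candidate: targeted promotion requires a network connection, so in the
    edgeless limit ``rho = 0`` the term vanishes and only exploration moves
    the administrator count — matching the micro-model, where an
    unconnected society can never convert a node in response to shocks.
    """
    _check_range(n_a, params.n)
    recruit = 0.0 if params.rho == 0.0 else recruitment_probability(n_a, params)
    return params.p_e * (params.n - 2.0 * n_a) + recruit


def integrate_macro(
    params: ModelParams,
    n_a0: float = 0.0,
    t_end: int | None = None,
    method: str = "euler",
) -> MacroTrajectory:
    """Integrate the mean-field dynamics forward from ``n_a0``.

    The reference integrator is explicit Euler with unit time step: the
    micro-model is a discrete-time map recruiting at most about one
    administrator per step, so the unit-step map is the faithful reading of
    the rate equation.  ``method="rk45"`` offers an adaptive higher-order
    alternative evaluated on the same integer grid.

    The path is clipped to [0, N]; survival is the first step at which
    N_A >= N - 0.5 (half-count rounding of the discrete collapse state),
    censored at ``t_end`` (default ``params.t_max``) otherwise.  The
    per-capita energy path uses the expected shock factor
    E[1 - B] = beta / (alpha + beta).
    """
    _check_range(n_a0, params.n)
    if t_end is None:
        t_end = params.t_max
    n = params.n
    times = np.arange(0, t_end + 1)

    if method == "euler":
        path = np.empty(t_end + 1)
        path[0] = n_a0
        x = n_a0
        for i in range(1, t_end + 1):
            x = min(max(x + macro_rhs(x, params), 0.0), float(n))
            path[i] = x
            if x >= n - COLLAPSE_MARGIN:
                path[i + 1 :] = x
                break
    elif method == "rk45":
        sol = solve_ivp(
            lambda _t, y: [macro_rhs(min(max(y[0], 0.0), float(n)), params)],
            (0.0, float(t_end)),
            [n_a0],
            t_eval=times,
            rtol=1e-8,
            atol=1e-8,
        )
        path = np.clip(sol.y[0], 0.0, float(n))
    else:
        raise ValueError(f"unknown integration method {method!r}")

    collapsed = path >= n - COLLAPSE_MARGIN
    if collapsed.any():
        survival = int(times[collapsed.argmax()])
        censored = False
    else:
        survival = t_end
        censored = True

    mean_shock = params.beta / (params.alpha + params.beta)
    e_path = np.array([energy_factor(v, params) for v in path])
    e_per_capita = params.r_max * mean_shock * e_path / n
    return MacroTrajectory(
        params=params,
        times=times,
        n_a_path=path,
        e_per_capita=e_per_capita,
        survival_time=survival,
        censored=censored,
    )


def find_fixed_points(
    params: ModelParams, resolution: int = 2001
) -> list[FixedPoint]:
    """Locate all equilibria of the mean-field dynamics on [0, N].

    Interior roots are found by sign-change bracketing on a uniform grid
    followed by Brent polishing; each is labelled stable when the numerical
    derivative of the rhs is negative.  The capped boundary state N_A = N
    is always reported, with its stability decided by the sign of the rhs
    just inside the boundary: attracting iff p_e < 1/N.
    """
    n = float(params.n)
    delta = 1e-9 * n
    grid = np.linspace(0.0, n - delta, resolution)
    vals = np.array([macro_rhs(x, params) for x in grid])

    roots: list[float] = []
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0:
            roots.append(float(grid[i]))
        elif lo * hi < 0.0:
            roots.append(
                float(
                    brentq(
                        lambda x: macro_rhs(x, params),
                        grid[i],
                        grid[i + 1],
                        xtol=1e-10,
                    )
                )
            )
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    out: list[FixedPoint] = []
    h = max(1e-6, 1e-9 * n)
    for r in roots:
        lo = max(0.0, r - h)
        hi = min(n, r + h)
        slope = (macro_rhs(hi, params) - macro_rhs(lo, params)) / (hi - lo)
        out.append(FixedPoint(n_a=r, stable=slope < 0.0))

    boundary_attracting = macro_rhs(n - delta, params) > 0.0
    out.append(FixedPoint(n_a=n, stable=boundary_attracting, boundary=True))
    return out


def critical_exploration(params: ModelParams, method: str = "closed") -> float:
    """Exploration probability at which the collapse state loses stability.

    In the limit N_A -> N the recruitment term tends to 1, so the boundary
    rhs is 1 - p_e * N: it changes sign at exactly p_e = 1/N.
    ``method="numeric"`` recovers the same value by bisecting the sign of
    the boundary rhs over p_e in [0, 1].
    """
    n = params.n
    if method == "closed":
        return 1.0 / n
    if method == "numeric":

        def boundary_rhs(p_e: float) -> float:
            return macro_rhs(float(n), params.replace(p_e=p_e))

        if n == 1:
            return 1.0
        return float(brentq(boundary_rhs, 0.0, 1.0, xtol=1e-14))
    raise ValueError(f"unknown method {method!r}")


def rescale_density(sigma: float, n: int) -> float:
    """Size-invariant link density ``rho_N = 1 - sigma**(1/N)``.

    With this choice the avoidance probability satisfies
    ``(1 - rho_N)**N = sigma`` for every N, making the mean-field per-capita
    energy effectively independent of the system size.
    """
    if not (0.0 < sigma < 1.0):
        raise ValueError(f"sigma must lie in (0, 1), got {sigma}")
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    return 1.0 - sigma ** (1.0 / n)
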