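"""Domain types, random-network construction and role classification.

The model society is an Erdős–Rényi random graph :math:`G(N, \\rho)` whose
nodes carry one of three roles:

* **administrator (A)** — produces no energy, but raises the productivity of
  every non-administrator it is directly linked to;
* **coordinated laborer (C)** — a non-administrator adjacent to at least one
  administrator; produces with productivity factor ``c`` and output
  elasticity ``b``;
* **laborer (L)** — a non-administrator with no administrator neighbour;
  produces with output elasticity ``a``.

Only the administrator set is free state.  The C/L split is always *derived*
from adjacency to the current administrator set, so the three classes
partition the node set by construction.  The network itself is static: nodes
are the integers ``0..N-1`` and edges never change over a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "ModelParams",
    "SocietyState",
    "ValidationError",
    "build_network",
    "classify_roles",
    "load_state",
    "save_state",
    "validate_params",
]

ROLE_ADMIN = "A"
ROLE_COORDINATED = "C"
ROLE_LABORER = "L"


class ValidationError(ValueError):
    """A parameter set violates its admissible ranges.

    ``problems`` lists every violated constraint, not only the first one
    encountered, so a user can fix a config file in one pass.
    """

    def __init__(self, problems):
        self.problems = [str(p) for p in problems]
        super().__init__("; ".join(self.problems))


def validate_params(values: dict) -> list[str]:
    """Return a list of human-readable constraint violations (empty if valid)."""
    problems = []

    def _num(key):
        v = values.get(key)
        if not isinstance(v, (int, float, np.integer, np.floating)) or isinstance(v, bool):
            problems.append(f"{key}: expected a number, got {v!r}")
            return None
        return float(v)

    n = _num("n")
    if n is not None and (n < 1 or n != int(n)):
        problems.append(f"n: node count must be an integer >= 1, got {values['n']}")
    t_max = _num("t_max")
    if t_max is not None and (t_max < 1 or t_max != int(t_max)):
        problems.append(f"t_max: must be an integer >= 1, got {values['t_max']}")
    for key in ("alpha", "beta"):
        v = _num(key)
        if v is not None and v <= 0:
            problems.append(f"{key}: Beta shape must be > 0, got {v}")
    eps = _num("epsilon")
    if eps is not None and eps < 0:
        problems.append(f"epsilon: per-capita energy threshold must be >= 0, got {eps}")
    for key in ("a", "b"):
        v = _num(key)
        if v is not None and not (0 < v <= 1):
            problems.append(f"{key}: output elasticity must lie in (0, 1], got {v}")
    c = _num("c")
    if c is not None and c < 1:
        problems.append(f"c: productivity factor must be >= 1, got {c}")
    for key in ("rho", "p_e"):
        v = _num(key)
        if v is not None and not (0 <= v <= 1):
            problems.append(f"{key}: probability must lie in [0, 1], got {v}")
    seed = values.get("seed")
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool) or seed < 0:
        problems.append(f"seed: must be a non-negative integer, got {seed!r}")
    return problems


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of a run; the single source of truth.

    Defaults are the reference configuration of the model: a society of 400
    nodes, rare-but-occasionally-severe shocks (Beta(1, 15)), per-capita
    energy demand of 1, equal elasticities a = b = 0.75, a 5% productivity
    premium for coordinated labor, 2% link density and no social mobility.

    Parameters
    ----------
    n : int
        Number of nodes; fixed for the whole run.
    t_max : int
        Maximum number of simulated time steps (censoring horizon).
    alpha, beta : float
        Shape parameters of the Beta-distributed shock ``B``.
    epsilon : float
        Per-capita energy threshold below which one administrator is
        recruited.
    a, b : float
        Output elasticities to scale of uncoordinated / coordinated labor.
    c : float
        Total-factor-productivity premium of coordinated labor (>= 1).
    rho : float
        Erdős–Rényi link probability.
    p_e : float
        Per-node, per-step exploration (social-mobility) probability.
    seed : int
        Seed of the single RNG that drives network build, shocks,
        exploration and tie-breaks.
    """

    n: int = 400
    t_max: int = 10_000
    alpha: float = 1.0
    beta: float = 15.0
    epsilon: float = 1.0
    a: float = 0.75
    b: float = 0.75
    c: float = 1.05
    rho: float = 0.02
    p_e: float = 0.0
    seed: int = 0

    def __post_init__(self):
        problems = validate_params(dataclasses.asdict(self))
        if problems:
            raise ValidationError(problems)

    @property
    def r_max(self) -> float:
        """Per-node resource ceiling ``N / N**a = N**(1-a)``.

        This scaling calibrates the unshocked all-laborer society to produce
        exactly one energy unit per capita; it is derived, never user-set.
        """
        return float(self.n) ** (1.0 - self.a)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


class SocietyState:
    """Static network plus the mutable administrator set.

    Neighbour lists and degrees are precomputed once at build time (the
    graph never changes).  The number of administrator neighbours of every
    node is maintained incrementally on promotion/demotion, so role
    classification costs O(N) per step instead of a full graph traversal.
    """

    def __init__(self, graph: nx.Graph):
        n = graph.number_of_nodes()
        if n < 1:
            raise ValidationError(["n: society needs at least one node"])
        if sorted(graph.nodes) != list(range(n)):
            raise ValueError("nodes must be labelled 0..N-1")
        if any(u == v for u, v in graph.edges):
            raise ValueError("self-loops are not allowed")
        self.n = n
        self.graph = graph
        self._nbrs = [
            np.fromiter(graph.neighbors(v), dtype=np.int64) for v in range(n)
        ]
        self.degrees = np.array([len(a) for a in self._nbrs], dtype=np.int64)
        self._admin = np.zeros(n, dtype=bool)
        self._admin_nbr = np.zeros(n, dtype=np.int64)

    # ------------------------------------------------------------------ #
    # role views (C/L always derived from adjacency to the admin set)
    # ------------------------------------------------------------------ #
    @property
    def admin_mask(self) -> np.ndarray:
        return self._admin

    @property
    def coordinated_mask(self) -> np.ndarray:
        return ~self._admin & (self._admin_nbr > 0)

    @property
    def laborer_mask(self) -> np.ndarray:
        return ~self._admin & (self._admin_nbr == 0)

    @property
    def admin_set(self) -> set[int]:
        return set(np.flatnonzero(self._admin).tolist())

    @property
    def coordinated_set(self) -> set[int]:
        return set(np.flatnonzero(self.coordinated_mask).tolist())

    @property
    def laborer_set(self) -> set[int]:
        return set(np.flatnonzero(self.laborer_mask).tolist())

    @property
    def n_admin(self) -> int:
        return int(self._admin.sum())

    def neighbors(self, v: int) -> np.ndarray:
        return self._nbrs[v]

    # ------------------------------------------------------------------ #
    # mutations
    # ------------------------------------------------------------------ #
    def promote(self, v: int) -> None:
        """Make node ``v`` an administrator (no-op if it already is one)."""
        if not self._admin[v]:
            self._admin[v] = True
            self._admin_nbr[self._nbrs[v]] += 1

    def demote(self, v: int) -> None:
        """Return node ``v`` to the labor force; its C/L label is derived."""
        if self._admin[v]:
            self._admin[v] = False
            self._admin_nbr[self._nbrs[v]] -= 1

    def toggle(self, v: int) -> None:
        if self._admin[v]:
            self.demote(v)
        else:
            self.promote(v)

    def set_admin_set(self, admins) -> None:
        """Replace the administrator set wholesale (counts recomputed)."""
        self._admin[:] = False
        self._admin[list(admins)] = True
        self._admin_nbr = self.recount_admin_neighbors()

    def recount_admin_neighbors(self) -> np.ndarray:
        """Recompute admin-neighbour counts from scratch (verification path)."""
        cnt = np.zeros(self.n, dtype=np.int64)
        for v in np.flatnonzero(self._admin):
            cnt[self._nbrs[v]] += 1
        return cnt

    def roles(self) -> np.ndarray:
        """Per-node role labels 'A'/'C'/'L' as a numpy string array."""
        out = np.full(self.n, ROLE_LABORER, dtype="<U1")
        out[self.coordinated_mask] = ROLE_COORDINATED
        out[self._admin] = ROLE_ADMIN
        return out


def build_network(params: ModelParams, rng=None) -> SocietyState:
    """Draw a fresh G(N, rho) society with everybody a laborer.

    Each of the N(N-1)/2 node pairs is linked independently with probability
    ``rho``.  ``rho = 0`` is legal and yields the degenerate stasis case (no
    node can ever be recruited); ``rho = 1`` yields the complete graph.

    Parameters
    ----------
    params : ModelParams
    rng : numpy.random.Generator, optional
        Source of randomness; a fresh generator seeded from ``params.seed``
        is created when omitted.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if 1.0 - params.rho == 1.0 and params.rho > 0.0:
        # rho below float resolution of 1-rho: the geometric skipping trick
        # divides by log(1-rho) = 0, so fall back to pairwise sampling
        graph = nx.gnp_random_graph(params.n, params.rho, seed=rng)
    else:
        graph = nx.fast_gnp_random_graph(params.n, params.rho, seed=rng)
    return SocietyState(graph)


def classify_roles(state: SocietyState) -> tuple[int, int, int]:
    """Count (N_L, N_C, N_A) for the current administrator set.

    A non-administrator adjacent to two or more administrators still counts
    once as coordinated — multiple administrator links give no extra
    productivity.  The three counts always sum to N.
    """
    n_a = state.n_admin
    n_c = int(np.count_nonzero(state.coordinated_mask))
    return state.n - n_a - n_c, n_c, n_a


# ---------------------------------------------------------------------- #
# plain-text serialization: node/role section + whitespace edge list
# ---------------------------------------------------------------------- #

def save_state(state: SocietyState, path) -> None:
    """Write a society to a plain-text file.

    Format: a ``*nodes N`` header followed by one ``<id> <role>`` line per
    node, then ``*edges`` followed by one ``<u> <v>`` line per edge.  Roles
    are stored for readability; on load only 'A' is authoritative (C/L are
    re-derived and cross-checked).
    """
    lines = [f"*nodes {state.n}"]
    roles = state.roles()
    lines.extend(f"{v} {roles[v]}" for v in range(state.n))
    lines.append("*edges")
    lines.extend(f"{u} {v}" for u, v in sorted(state.graph.edges()))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_state(path) -> SocietyState:
    """Read a society written by :func:`save_state` (round-trip safe)."""
    with open(path) as fh:
        tokens = [ln.split() for ln in fh if ln.strip()]
    if not tokens or tokens[0][0] != "*nodes":
        raise ValueError("missing *nodes header")
    n = int(tokens[0][1])
    roles = {}
    i = 1
    while i < len(tokens) and tokens[i][0] != "*edges":
        v, role = int(tokens[i][0]), tokens[i][1]
        roles[v] = role
        i += 1
    if len(roles) != n:
        raise ValueError(f"expected {n} node lines, found {len(roles)}")
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for tok in tokens[i + 1 :]:
        graph.add_edge(int(tok[0]), int(tok[1]))
    state = SocietyState(graph)
    state.set_admin_set([v for v, r in roles.items() if r == ROLE_ADMIN])
    derived = state.roles()
    for v, r in roles.items():
        if derived[v] != r:
            raise ValueError(
                f"stored role {r!r} of node {v} contradicts adjacency-derived "
                f"role {derived[v]!r}"
            )
    return state
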