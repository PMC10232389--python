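"""Synthetic food-web topologies and competition–colonization parameterization.

Food webs here are directed acyclic predation graphs over a basal/consumer
partition: basal species occupy the first trophic level and have no prey;
every consumer is reachable from at least one basal species through feeding
links; loops and cannibalism are excluded.

Because published island food webs are rarely printed as adjacency lists,
:func:`generate_web` produces random webs matching their aggregate
structure (species count, basal count, link count) via a layered-DAG
construction: each consumer is assigned a trophic layer, wired to at least
one prey in a strictly lower layer, and the remaining links are placed at
random among valid lower-layer targets. Unequal chain lengths — hence
omnivory — arise naturally.

:func:`assign_cc_tradeoff` equips a web's basal guild with a
competition–colonization tradeoff: colonization rates strictly increase
with species index, while the competitive hierarchy (handled separately in
:mod:`webpatch.competition`) ranks species 1 as the best competitor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .params import ParamSet

__all__ = [
    "FoodWeb",
    "generate_web",
    "assign_cc_tradeoff",
    "max_links",
    "read_web_tsv",
    "write_web_tsv",
]

#: Fig.-caption default rates shared by all consumers.
DEFAULT_E_BASAL = 0.2
DEFAULT_C_CONSUMER = 0.625
DEFAULT_E_CONSUMER = 0.05
DEFAULT_TOPDOWN = 0.05


class WebParameterError(ValueError):
    """Infeasible (n_P, n_A, L) combination or invalid web parameters."""


@dataclass(frozen=True)
class FoodWeb:
    """A directed acyclic predation graph with a basal/consumer partition.

    Attributes
    ----------
    basal_ids : tuple of str
        Labels of the n_P basal species, in competitive-rank order
        (species 1 = best competitor = lowest colonization rate under the
        competition–colonization tradeoff).
    consumer_ids : tuple of str
        Labels of the n_A consumers.
    theta : ndarray, shape (n_P, n_A)
        Binary feeding matrix; ``theta[i, k] = 1`` iff consumer k feeds on
        basal species i.
    delta : ndarray, shape (n_A, n_A)
        Binary feeding matrix among consumers; ``delta[k, i] = 1`` iff
        consumer i feeds on consumer k (prey row, predator column).
    """

    basal_ids: tuple
    consumer_ids: tuple
    theta: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "basal_ids", tuple(self.basal_ids))
        object.__setattr__(self, "consumer_ids", tuple(self.consumer_ids))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=int))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=int))
        self.validate()

    # -- sizes ---------------------------------------------------------
    @property
    def n_basal(self) -> int:
        return len(self.basal_ids)

    @property
    def n_consumers(self) -> int:
        return len(self.consumer_ids)

    @property
    def n_species(self) -> int:
        """Total species richness S = n_P + n_A."""
        return self.n_basal + self.n_consumers

    @property
    def species_ids(self) -> tuple:
        return self.basal_ids + self.consumer_ids

    @property
    def n_links(self) -> int:
        """Number of trophic links L."""
        return int(self.theta.sum() + self.delta.sum())

    @property
    def edges(self) -> list:
        """Feeding links as (prey_id, predator_id) pairs."""
        out = []
        for i, k in zip(*np.nonzero(self.theta)):
            out.append((self.basal_ids[i], self.consumer_ids[k]))
        for k, i in zip(*np.nonzero(self.delta)):
            out.append((self.consumer_ids[k], self.consumer_ids[i]))
        return out

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_P, n_A = self.n_basal, self.n_consumers
        if n_P < 1 and n_A > 0:
            raise WebParameterError("consumers cannot exist without basal species")
        if len(set(self.species_ids)) != n_P + n_A:
            raise WebParameterError("species labels must be unique")
        if self.theta.shape != (n_P, n_A):
            raise WebParameterError(f"theta must have shape {(n_P, n_A)}")
        if self.delta.shape != (n_A, n_A):
            raise WebParameterError(f"delta must have shape {(n_A, n_A)}")
        if not np.isin(self.theta, (0, 1)).all() or not np.isin(self.delta, (0, 1)).all():
            raise WebParameterError("theta and delta must be binary")
        if np.any(np.diag(self.delta) != 0):
            raise WebParameterError("cannibalism (self-loops) is excluded")
        if n_A and not nx.is_directed_acyclic_graph(self._consumer_digraph()):
            raise WebParameterError("the predation graph must be acyclic")
        # every consumer reachable from a basal species via feeding links
        reach = self.theta.any(axis=0)
        order = self.consumer_topological_order()
        for i in order:
            if not reach[i]:
                reach[i] = bool((self.delta[:, i] & reach).any())
        if n_A and not reach.all():
            bad = [self.consumer_ids[i] for i in np.nonzero(~reach)[0]]
            raise WebParameterError(
                f"consumers without a basal-rooted feeding path: {bad}"
            )

    def _consumer_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_consumers))
        g.add_edges_from(zip(*np.nonzero(self.delta)))
        return g

    def consumer_topological_order(self) -> list:
        """Consumer indices sorted prey-before-predator (stable within ties)."""
        if not self.n_consumers:
            return []
        return list(
            nx.lexicographical_topological_sort(self._consumer_digraph())
        )

    # -- interchange ---------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        """The full predation graph with prey→predator edges and a ``role`` attribute."""
        g = nx.DiGraph()
        for sid in self.basal_ids:
            g.add_node(sid, role="basal")
        for sid in self.consumer_ids:
            g.add_node(sid, role="consumer")
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "FoodWeb":
        basal = [n for n, d in g.nodes(data=True) if d.get("role") == "basal"]
        consumers = [n for n, d in g.nodes(data=True) if d.get("role") != "basal"]
        return cls.from_edges(basal, consumers, list(g.edges()))

    @classmethod
    def from_edges(cls, basal_ids, consumer_ids, edges) -> "FoodWeb":
        """Build a web from explicit (prey_id, predator_id) pairs."""
        basal_ids, consumer_ids = list(basal_ids), list(consumer_ids)
        bidx = {s: i for i, s in enumerate(basal_ids)}
        cidx = {s: i for i, s in enumerate(consumer_ids)}
        theta = np.zeros((len(basal_ids), len(consumer_ids)), dtype=int)
        delta = np.zeros((len(consumer_ids), len(consumer_ids)), dtype=int)
        for prey, pred in edges:
            if pred not in cidx:
                raise WebParameterError(f"predator {pred!r} is not a consumer")
            if prey in bidx:
                theta[bidx[prey], cidx[pred]] = 1
            elif prey in cidx:
                delta[cidx[prey], cidx[pred]] = 1
            else:
                raise WebParameterError(f"unknown species {prey!r} in edge list")
        return cls(tuple(basal_ids), tuple(consumer_ids), theta, delta)


def max_links(n_P: int, n_A: int) -> int:
    """Maximum link count of a loop-free web: basal→consumer complete plus a
    transitive tournament among consumers."""
    return n_P * n_A + n_A * (n_A - 1) // 2


def generate_web(
    n_P: int,
    n_A: int,
    L: int,
    seed: int,
    n_layers: int | None = None,
) -> FoodWeb:
    """Generate a random layered-DAG food web with exactly ``L`` links.

    Each consumer is assigned a random trophic layer in 1..n_layers (basal
    species occupy layer 0); it receives one mandatory prey link from a
    strictly lower layer, after which the remaining ``L - n_A`` links are
    drawn uniformly without replacement from all remaining lower-layer
    pairs. Deterministic for a fixed ``seed``.

    Parameters
    ----------
    n_P, n_A : int
        Numbers of basal species and consumers.
    L : int
        Total number of feeding links; must satisfy
        ``n_A <= L <= max_links(n_P, n_A)``.
    seed : int
        Seed for the layer assignment and link placement.
    n_layers : int, optional
        Number of consumer trophic layers; default ``min(n_A, 4)``.

    Raises
    ------
    WebParameterError
        If the (n_P, n_A, L) combination is infeasible.
    """
    if n_P < 1 or n_A < 0:
        raise WebParameterError("need n_P >= 1 and n_A >= 0")
    if L < n_A:
        raise WebParameterError(
            f"L={L} < n_A={n_A}: every consumer needs at least one prey"
        )
    if L > max_links(n_P, n_A):
        raise WebParameterError(
            f"L={L} exceeds the maximum {max_links(n_P, n_A)} for "
            f"n_P={n_P}, n_A={n_A}"
        )
    basal_ids = tuple(f"P{i + 1}" for i in range(n_P))
    consumer_ids = tuple(f"A{k + 1}" for k in range(n_A))
    if n_A == 0:
        if L != 0:
            raise WebParameterError("a web without consumers has no links")
        return FoodWeb(basal_ids, (), np.zeros((n_P, 0)), np.zeros((0, 0)))

    rng = np.random.default_rng(seed)
    if n_layers is None:
        n_layers = min(n_A, 4)
    n_layers = max(1, min(n_layers, n_A))

    # draw layers until the layering can host L links; fall back to the
    # maximal-capacity layering (all-distinct layers) if needed
    layers = None
    for _ in range(200):
        cand = rng.integers(1, n_layers + 1, size=n_A)
        capacity = sum(
            n_P + int(np.sum(cand < cand[i])) for i in range(n_A)
        )
        if capacity >= L:
            layers = cand
            break
    if layers is None:
        layers = rng.permutation(n_A) + 1

    theta = np.zeros((n_P, n_A), dtype=int)
    delta = np.zeros((n_A, n_A), dtype=int)

    def lower_prey(i):
        """(kind, index) candidates strictly below consumer i's layer."""
        cands = [("b", j) for j in range(n_P)]
        cands += [("c", k) for k in range(n_A) if layers[k] < layers[i]]
        return cands

    # one mandatory basal-rooted prey link per consumer
    for i in range(n_A):
        cands = lower_prey(i)
        kind, j = cands[rng.integers(len(cands))]
        if kind == "b":
            theta[j, i] = 1
        else:
            delta[j, i] = 1

    # remaining links, uniformly among unused lower-layer pairs
    remaining = L - n_A
    if remaining:
        pool = []
        for i in range(n_A):
            for kind, j in lower_prey(i):
                if kind == "b" and not theta[j, i]:
                    pool.append(("b", j, i))
                elif kind == "c" and not delta[j, i]:
                    pool.append(("c", j, i))
        picks = rng.choice(len(pool), size=remaining, replace=False)
        for p in picks:
            kind, j, i = pool[p]
            if kind == "b":
                theta[j, i] = 1
            else:
                delta[j, i] = 1

    return FoodWeb(basal_ids, consumer_ids, theta, delta)


def assign_cc_tradeoff(
    web: FoodWeb,
    c_range: tuple = (0.45, 0.8),
    spacing: str = "even",
    seed: int | None = None,
    U: float = 0.0,
    e_basal: float = DEFAULT_E_BASAL,
    c_consumer: float = DEFAULT_C_CONSUMER,
    e_consumer: float = DEFAULT_E_CONSUMER,
    mu: float = DEFAULT_TOPDOWN,
    phi: float = DEFAULT_TOPDOWN,
) -> ParamSet:
    """Parameterize a web with a competition–colonization tradeoff.

    Basal colonization rates are strictly increasing with species index
    (species 1, the top competitor, colonizes slowest). ``spacing="even"``
    places them at equal intervals spanning ``c_range`` inclusive;
    ``spacing="irregular"`` draws them i.i.d. uniform from ``c_range`` and
    sorts ascending (duplicates redrawn). A single basal species receives
    the upper endpoint.

    Consumer rates are homogeneous scalars; top-down rates ``mu``/``phi``
    are placed uniformly on feeding links only.
    """
    n_P = web.n_basal
    if n_P < 1:
        raise ValueError("web has an empty basal set")
    lo, hi = float(c_range[0]), float(c_range[1])
    if not (0 < lo <= hi <= 1):
        raise ValueError("c_range must lie within (0, 1]")
    if lo == hi and n_P > 1:
        raise ValueError("degenerate c_range cannot order more than one species")
    if spacing == "even":
        cP = np.array([hi]) if n_P == 1 else np.linspace(lo, hi, n_P)
    elif spacing == "irregular":
        rng = np.random.default_rng(seed)
        for _ in range(1000):
            cP = np.sort(rng.uniform(lo, hi, size=n_P))
            if np.all(np.diff(cP) > 0) or n_P == 1:
                break
        else:  # pragma: no cover - measure-zero event
            raise RuntimeError("could not draw distinct colonization rates")
    else:
        raise ValueError(f"unknown spacing {spacing!r}")

    n_A = web.n_consumers
    return ParamSet(
        cP=cP,
        eP=np.full(n_P, e_basal),
        cA=np.full(n_A, c_consumer),
        eA=np.full(n_A, e_consumer),
        mu=mu * web.theta,
        phi=phi * web.delta,
        U=U,
    )


# ---------------------------------------------------------------------------
# Serialization: tab-separated edge list with a basal-species header block
# ---------------------------------------------------------------------------

def write_web_tsv(web: FoodWeb, path) -> None:
    """Write a web as a prey→predator edge list.

    Header lines name the basal and consumer species (so isolated species
    survive a round trip); data lines are ``prey_id<TAB>predator_id``.
    """
    buf = io.StringIO()
    buf.write("# basal:\t" + "\t".join(web.basal_ids) + "\n")
    buf.write("# consumers:\t" + "\t".join(web.consumer_ids) + "\n")
    for prey, pred in web.edges:
        buf.write(f"{prey}\t{pred}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_web_tsv(path) -> FoodWeb:
    """Read a web written by :func:`write_web_tsv`."""
    basal, consumers, edges = None, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# basal:"):
                basal = [s for s in line.split("\t")[1:] if s]
            elif line.startswith("# consumers:"):
                consumers = [s for s in line.split("\t")[1:] if s]
            elif line.startswith("#"):
                continue
            else:
                prey, pred = line.split("\t")
                edges.append((prey, pred))
    if basal is None:
        raise WebParameterError(f"{path}: missing '# basal:' header")
    if consumers is None:
        # infer: any species appearing as predator is a consumer
        preds = {pred for _, pred in edges}
        consumers = sorted(preds - set(basal))
    return FoodWeb.from_edges(basal, consumers, edges)
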