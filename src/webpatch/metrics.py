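"""Structural complexity of realized food webs and basal diversity indices.

A food chain is a directed path from a top predator (a species nothing
feeds on) to a basal species; its length is counted in links by default
(``fcl_convention="nodes"`` counts species instead). An omnivore is a
species with at least two prey whose basal-rooted feeding paths come in
at least two distinct lengths — it feeds on more than one trophic level.
Connectance is C = 2L / [S (S - 1)], the realized fraction of undirected
species pairs that are linked.

Mean/max food-chain length and omnivory are computed by dynamic
programming over the DAG (path counts, length sums and length sets per
species); :func:`food_chains` enumerates the chains explicitly and serves
as the independent oracle on small webs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dynamics import SteadyState
from .webgen import FoodWeb

__all__ = [
    "WebMetrics",
    "realized_web",
    "connectance",
    "food_chains",
    "mean_max_fcl",
    "omnivory_fraction",
    "inverse_simpson",
    "compute_metrics",
]


@dataclass(frozen=True)
class WebMetrics:
    """Complexity metrics of one (realized) food web plus basal diversity."""

    richness: int
    basal_richness: int
    links: int
    connectance: float
    mean_fcl: float
    max_fcl: float
    omnivory: float
    inv_simpson: float

    def as_dict(self) -> dict:
        return asdict(self)


def realized_web(web: FoodWeb, state: SteadyState) -> FoodWeb:
    """Induced subweb on surviving species, with bottom-up cascades applied.

    Consumers left without any surviving prey are removed, and removals
    cascade upward (a consumer whose prey all disappeared this way is
    removed too). The empty web is a valid output.
    """
    n_P = web.n_basal
    basal_alive = ~state.extinct[:n_P]
    cons_alive = ~state.extinct[n_P:]
    cons_alive = cons_alive.copy()
    # cascade in topological order: prey availability is known before
    # any predator is visited
    for i in web.consumer_topological_order():
        if not cons_alive[i]:
            continue
        has_prey = bool((web.theta[:, i] & basal_alive).any()) or bool(
            (web.delta[:, i] & cons_alive).any()
        )
        if not has_prey:
            cons_alive[i] = False
    b_idx = np.nonzero(basal_alive)[0]
    c_idx = np.nonzero(cons_alive)[0]
    return FoodWeb(
        tuple(web.basal_ids[i] for i in b_idx),
        tuple(web.consumer_ids[i] for i in c_idx),
        web.theta[np.ix_(b_idx, c_idx)],
        web.delta[np.ix_(c_idx, c_idx)],
    )


def connectance(S: int, L: int) -> float:
    """C = 2L / [S (S - 1)]; NaN (undefined) for S < 2."""
    if S < 2:
        return float("nan")
    return 2.0 * L / (S * (S - 1))


def _adjacency(web: FoodWeb) -> list:
    """Prey lists per species index (basal first, then consumers)."""
    n_P = web.n_basal
    prey = [[] for _ in range(web.n_species)]
    for i, k in zip(*np.nonzero(web.theta)):
        prey[n_P + k].append(int(i))
    for k, i in zip(*np.nonzero(web.delta)):
        prey[n_P + i].append(n_P + int(k))
    return prey


def _top_predators(web: FoodWeb) -> list:
    """Species indices with no predators (nothing feeds on them)."""
    n_P = web.n_basal
    has_pred = np.zeros(web.n_species, dtype=bool)
    has_pred[:n_P] = web.theta.any(axis=1)
    has_pred[n_P:] = web.delta.any(axis=1)
    return [int(i) for i in np.nonzero(~has_pred)[0]]


def _species_order(web: FoodWeb) -> list:
    """All species indices, prey before predators."""
    return list(range(web.n_basal)) + [
        web.n_basal + i for i in web.consumer_topological_order()
    ]


def food_chains(web: FoodWeb, fcl_convention: str = "links") -> list:
    """Enumerate every food chain as a (top predator … basal) id tuple.

    Returned with the top predator first. An isolated basal species (no
    predators) yields a degenerate single-node chain. Exhaustive DFS —
    intended for webs at empirical scale (S ≲ 30) and as a test oracle.
    """
    _check_convention(fcl_convention)
    prey = _adjacency(web)
    ids = web.species_ids
    n_P = web.n_basal
    chains = []

    def descend(path):
        v = path[-1]
        if v < n_P:
            chains.append(tuple(ids[u] for u in path))
            return
        for u in prey[v]:
            descend(path + [u])

    for top in _top_predators(web):
        descend([top])
    return chains


def chain_length(chain: tuple, fcl_convention: str = "links") -> int:
    _check_convention(fcl_convention)
    return len(chain) - 1 if fcl_convention == "links" else len(chain)


def _check_convention(fcl_convention: str) -> None:
    if fcl_convention not in ("links", "nodes"):
        raise ValueError(f"unknown fcl_convention {fcl_convention!r}")


def mean_max_fcl(web: FoodWeb, fcl_convention: str = "links") -> tuple:
    """(mean, max) food-chain length over all top-predator→basal paths.

    Computed without enumeration: one topological pass accumulates, per
    species, the number of basal-rooted paths, their total length and the
    maximum length; top predators then contribute their tallies.
    Empty web → (nan, nan).
    """
    _check_convention(fcl_convention)
    if web is None or web.n_species == 0:
        return float("nan"), float("nan")
    prey = _adjacency(web)
    n = web.n_species
    n_paths = np.zeros(n, dtype=float)
    sum_len = np.zeros(n, dtype=float)
    max_len = np.zeros(n, dtype=float)
    for v in _species_order(web):
        if not prey[v]:  # basal (consumers always have prey)
            n_paths[v] = 1.0
            continue
        for u in prey[v]:
            n_paths[v] += n_paths[u]
            sum_len[v] += sum_len[u] + n_paths[u]  # each path grows by one link
            max_len[v] = max(max_len[v], max_len[u] + 1.0)
    tops = _top_predators(web)
    total_paths = sum(n_paths[t] for t in tops)
    total_len = sum(sum_len[t] for t in tops)
    if total_paths == 0:
        return float("nan"), float("nan")
    mean = total_len / total_paths
    mx = max(max_len[t] for t in tops)
    if fcl_convention == "nodes":
        mean += 1.0
        mx += 1.0
    return float(mean), float(mx)


def omnivory_fraction(web: FoodWeb) -> float:
    """Fraction of species feeding on ≥2 prey via chains of unequal length.

    Per species, the set of basal-rooted path lengths is propagated up the
    DAG; an omnivore has at least two prey and at least two distinct
    lengths in that set. Basal species are never omnivores but count in
    the denominator S. Empty web → 0.
    """
    if web is None or web.n_species == 0:
        return 0.0
    prey = _adjacency(web)
    n = web.n_species
    lengths: list = [set() for _ in range(n)]
    omnivores = 0
    for v in _species_order(web):
        if not prey[v]:
            lengths[v] = {0}
            continue
        acc = set()
        for u in prey[v]:
            acc.update(l + 1 for l in lengths[u])
        lengths[v] = acc
        if len(prey[v]) >= 2 and len(acc) >= 2:
            omnivores += 1
    return omnivores / n


def inverse_simpson(P: np.ndarray) -> float:
    """Effective number of basal species, 1 / sum_i q_i^2.

    q_i = P_i / sum_j P_j over the positive occupancies; NaN when no
    species survives. Equals the species count iff abundances are even.
    """
    P = np.asarray(P, dtype=float)
    P = P[P > 0]
    if P.size == 0:
        return float("nan")
    q = P / P.sum()
    return float(1.0 / np.sum(q**2))


def compute_metrics(
    web: FoodWeb,
    state: SteadyState,
    fcl_convention: str = "links",
) -> WebMetrics:
    """All complexity metrics of the realized web implied by a steady state."""
    sub = realized_web(web, state)
    mean_fcl, max_fcl = mean_max_fcl(sub, fcl_convention)
    return WebMetrics(
        richness=sub.n_species,
        basal_richness=sub.n_basal,
        links=sub.n_links,
        connectance=connectance(sub.n_species, sub.n_links),
        mean_fcl=mean_fcl,
        max_fcl=max_fcl,
        omnivory=omnivory_fraction(sub),
        inv_simpson=inverse_simpson(state.P),
    )
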