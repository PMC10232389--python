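"""Competitive displacement structures among basal species.

Basal species contest patches through displacement: a colonizer of species
i takes over a patch occupied by species j with probability ``H[i, j]``.
Three structures are provided:

* strict hierarchy — ``H[i, j] = 1`` for i < j, 0 otherwise (species 1 is
  the unbeatable top competitor);
* weakened hierarchy — a one-parameter interpolation between the strict
  hierarchy (w = 1) and fair coin-flip contests (w = 0);
* intransitive tournaments — cyclic dominance (rock–paper–scissors and its
  generalizations), quantified by the relative intransitivity RI, the
  fraction of cyclic triads relative to the maximum attainable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionMatrix",
    "hierarchical_H",
    "weakened_H",
    "intransitive_H",
    "relative_intransitivity",
    "cyclic_triads",
    "max_cyclic_triads",
]


@dataclass(frozen=True)
class CompetitionMatrix:
    """Pairwise displacement probabilities among basal species.

    ``H[i, j]`` is the probability that a colonizer of species i displaces
    a resident of species j. The diagonal is zero. ``RI`` is defined for
    0/1 tournaments only and is NaN otherwise.
    """

    H: np.ndarray
    structure_tag: str = "custom"

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        object.__setattr__(self, "H", H)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ValueError("H must be a square matrix")
        if np.any(np.diag(H) != 0):
            raise ValueError("H must have zero diagonal (no self-displacement)")
        if np.any((H < 0) | (H > 1)):
            raise ValueError("H entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.H.shape[0]

    def is_tournament(self) -> bool:
        """True iff exactly one of H_ij, H_ji equals 1 for every pair."""
        H = self.H
        if not np.isin(H, (0.0, 1.0)).all():
            return False
        off = H + H.T
        return bool(np.all(off[~np.eye(self.n, dtype=bool)] == 1))

    @property
    def RI(self) -> float:
        """Relative intransitivity; NaN for non-tournament matrices or n < 3."""
        if self.n < 3 or not self.is_tournament():
            return float("nan")
        return relative_intransitivity(self.H)

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path, species_ids=None) -> None:
        ids = list(species_ids) if species_ids is not None else [
            f"P{i + 1}" for i in range(self.n)
        ]
        pd.DataFrame(self.H, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, structure_tag: str = "custom") -> "CompetitionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), structure_tag)


def hierarchical_H(n_P: int, rank_order=None) -> CompetitionMatrix:
    """Strict competitive hierarchy: H_ij = 1 for i < j and 0 otherwise.

    ``rank_order`` optionally permutes competitive ranks relative to
    species index (``rank_order[i]`` is the competitive rank of species i,
    lower rank = better competitor), decoupling the hierarchy from the
    colonization-rate ordering. This is a configuration hook for webs
    where the competition–colonization tradeoff holds only locally among
    a subset of species; it is this package's construction, not a
    reproduction of any published variant.
    """
    if n_P < 1:
        raise ValueError("need at least one basal species")
    rank = np.arange(n_P) if rank_order is None else np.asarray(rank_order)
    if sorted(rank.tolist()) != list(range(n_P)):
        raise ValueError("rank_order must be a permutation of 0..n_P-1")
    H = (rank[:, None] < rank[None, :]).astype(float)
    tag = "hierarchical" if rank_order is None else "hierarchical-permuted"
    return CompetitionMatrix(H, tag)


def weakened_H(n_P: int, w: float) -> CompetitionMatrix:
    """Weakened hierarchy: H_ij = (1+w)/2 for i < j, (1-w)/2 for i > j.

    ``w = 1`` recovers the strict hierarchy; ``w = 0`` gives symmetric
    0.5 contests. Minimal one-parameter interpolation between the two.
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"w must lie in [0, 1], got {w}")
    if n_P < 1:
        raise ValueError("need at least one basal species")
    upper = np.triu(np.ones((n_P, n_P)), k=1)
    H = (1 + w) / 2 * upper + (1 - w) / 2 * upper.T
    return CompetitionMatrix(H, "weakened")


# ---------------------------------------------------------------------------
# Tournament intransitivity
# ---------------------------------------------------------------------------

def cyclic_triads(H: np.ndarray) -> int:
    """Number of cyclic (rock–paper–scissors) triads of a 0/1 tournament.

    Uses the score-sequence identity: with out-degrees s_i, the number of
    transitive triads is sum_i C(s_i, 2), so the cyclic count is
    C(n, 3) - sum_i C(s_i, 2).
    """
    H = _require_tournament(H)
    n = H.shape[0]
    s = H.sum(axis=1).astype(int)
    return comb(n, 3) - int(sum(comb(int(si), 2) for si in s))


def max_cyclic_triads(n: int) -> int:
    """Maximum cyclic-triad count of any tournament on n nodes.

    (n^3 - n)/24 for odd n, (n^3 - 4n)/24 for even n (Kendall–Babington
    Smith). Equals 1 for n = 3 and 2 for n = 4.
    """
    if n < 3:
        return 0
    return (n**3 - n) // 24 if n % 2 else (n**3 - 4 * n) // 24


def relative_intransitivity(H) -> float:
    """RI = cyclic triads / maximum possible cyclic triads, in [0, 1].

    0 for any transitive (hierarchical) tournament; 1 for maximally
    intransitive tournaments such as rock–paper–scissors at n = 3.
    """
    H = H.H if isinstance(H, CompetitionMatrix) else np.asarray(H, dtype=float)
    n = H.shape[0]
    if n < 3:
        raise ValueError("RI requires at least 3 species")
    return cyclic_triads(H) / max_cyclic_triads(n)


def _require_tournament(H) -> np.ndarray:
    H = H.H if isinstance(H, CompetitionMatrix) else np.asarray(H, dtype=float)
    n = H.shape[0]
    if not np.isin(H, (0.0, 1.0)).all() or np.any(np.diag(H) != 0):
        raise ValueError("H is not a 0/1 tournament")
    off = ~np.eye(n, dtype=bool)
    if not np.all((H + H.T)[off] == 1):
        raise ValueError("H is not a tournament: each pair needs exactly one winner")
    return H


def intransitive_H(
    n_P: int,
    target_RI: float = 1.0,
    seed: int | None = None,
    max_iter: int = 20000,
    n_restarts: int = 20,
) -> CompetitionMatrix:
    """Perturb the strict hierarchy into a tournament with RI near ``target_RI``.

    Randomized hill climbing over single edge reversals, starting from the
    hierarchical tournament: a proposed reversal is kept when it moves the
    cyclic-triad count toward the target (sideways moves allowed to escape
    plateaus). The species labels — and hence the colonization-rate
    ranking — are never permuted. Deterministic for a fixed seed.

    If the exact target count is unreachable the best tournament found is
    returned; inspect ``.RI`` for the achieved value.
    """
    if n_P < 1:
        raise ValueError("need at least one basal species")
    if not (0.0 <= target_RI <= 1.0):
        raise ValueError("target_RI must lie in [0, 1]")
    if n_P < 3:
        if target_RI > 0:
            raise ValueError("RI > 0 requires at least 3 species")
        return CompetitionMatrix(hierarchical_H(n_P).H, "intransitive")

    rng = np.random.default_rng(seed)
    target = round(target_RI * max_cyclic_triads(n_P))
    pairs = [(i, j) for i in range(n_P) for j in range(i + 1, n_P)]

    best_H, best_gap = None, None
    for _ in range(n_restarts):
        H = hierarchical_H(n_P).H.copy()
        cyc = 0  # hierarchy is transitive
        gap = abs(cyc - target)
        stall = 0
        for _ in range(max_iter):
            if gap == 0:
                break
            i, j = pairs[rng.integers(len(pairs))]
            H[i, j], H[j, i] = H[j, i], H[i, j]
            new_cyc = cyclic_triads(H)
            new_gap = abs(new_cyc - target)
            if new_gap < gap or (new_gap == gap and rng.random() < 0.1):
                cyc, gap = new_cyc, new_gap
                stall = 0
            else:
                H[i, j], H[j, i] = H[j, i], H[i, j]  # revert
                stall += 1
                if stall > 50 * len(pairs):
                    break
        if best_gap is None or gap < best_gap:
            best_H, best_gap = H.copy(), gap
        if best_gap == 0:
            break
    return CompetitionMatrix(best_H, "intransitive")
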