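"""Demographic and interaction rates for the patch-occupancy model.

A :class:`ParamSet` collects every rate entering the basal and consumer
patch-dynamics equations: per-basal colonization ``cP`` and extinction
``eP``, per-consumer colonization ``cA`` and extinction ``eA``, the
top-down extinction rates ``mu`` (consumer pressure on basal species) and
``phi`` (predator pressure on consumers), and the patch-loss fraction
``U`` — the proportion of patches permanently destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

__all__ = ["ParamSet"]


@dataclass(frozen=True)
class ParamSet:
    """Rates of the patch-occupancy equations, in units of 1/time.

    Parameters
    ----------
    cP, eP : ndarray, shape (n_P,)
        Colonization and intrinsic extinction rates of basal species.
    cA, eA : ndarray, shape (n_A,)
        Colonization and intrinsic extinction rates of consumers.
    mu : ndarray, shape (n_P, n_A)
        Top-down extinction rate of basal species i due to over-predation
        by consumer k; nonzero only on feeding links (theta support).
    phi : ndarray, shape (n_A, n_A)
        Top-down extinction rate of consumer i due to over-predation by
        consumer k; ``phi[i, k]`` nonzero only where k feeds on i
        (delta support, prey-row/predator-column orientation).
    U : float
        Patch-loss fraction in [0, 1).
    """

    cP: np.ndarray
    eP: np.ndarray
    cA: np.ndarray = field(default_factory=lambda: np.zeros(0))
    eA: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mu: np.ndarray | None = None
    phi: np.ndarray | None = None
    U: float = 0.0

    def __post_init__(self):
        for name in ("cP", "eP", "cA", "eA"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n_P, n_A = self.n_basal, self.n_consumers
        if self.mu is None:
            object.__setattr__(self, "mu", np.zeros((n_P, n_A)))
        else:
            object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.phi is None:
            object.__setattr__(self, "phi", np.zeros((n_A, n_A)))
        else:
            object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        self._validate()

    def _validate(self) -> None:
        n_P, n_A = self.n_basal, self.n_consumers
        if self.eP.shape != (n_P,):
            raise ValueError("cP and eP must have the same length")
        if self.eA.shape != (n_A,):
            raise ValueError("cA and eA must have the same length")
        if self.mu.shape != (n_P, n_A):
            raise ValueError(f"mu must have shape {(n_P, n_A)}, got {self.mu.shape}")
        if self.phi.shape != (n_A, n_A):
            raise ValueError(f"phi must have shape {(n_A, n_A)}, got {self.phi.shape}")
        for name in ("cP", "eP", "cA", "eA", "mu", "phi"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.U < 1.0):
            raise ValueError(f"U must lie in [0, 1), got {self.U}")

    @property
    def n_basal(self) -> int:
        return self.cP.size

    @property
    def n_consumers(self) -> int:
        return self.cA.size

    def replace(self, **changes) -> "ParamSet":
        """Return a copy with the given fields replaced (e.g. ``U=0.3``)."""
        return _dc_replace(self, **changes)

    def without_predation(self) -> "ParamSet":
        """Copy with all top-down rates (mu, phi) set to zero."""
        return self.replace(mu=np.zeros_like(self.mu), phi=np.zeros_like(self.phi))

    def basal_only(self) -> "ParamSet":
        """Copy restricted to the basal subsystem (consumers dropped, mu irrelevant)."""
        return ParamSet(
            cP=self.cP.copy(),
            eP=self.eP.copy(),
            cA=np.zeros(0),
            eA=np.zeros(0),
            U=self.U,
        )

    def check_support(self, theta: np.ndarray, delta: np.ndarray) -> None:
        """Raise if mu/phi carry mass off the feeding links of a web."""
        if np.any(self.mu[np.asarray(theta) == 0] != 0):
            raise ValueError("mu has nonzero entries off theta feeding links")
        if np.any(self.phi[np.asarray(delta) == 0] != 0):
            raise ValueError("phi has nonzero entries off delta feeding links")
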