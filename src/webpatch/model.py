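"""Model/Results interface to the patch-occupancy framework.

:class:`PatchOccupancyModel` bundles a food web, a basal competition
matrix and a rate set; ``fit()`` solves the system to steady state and
returns a :class:`SteadyStateResults` carrying occupancies, extinction
flags, realized-web metrics and a printable summary. ``sweep()`` runs the
patch-loss gradient experiment and returns a :class:`~webpatch.sweep.SweepResult`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .competition import CompetitionMatrix, hierarchical_H
from .dynamics import (
    EXTINCTION_THRESHOLD,
    SteadyState,
    run_to_steady_state,
    steady_state_analytic,
)
from .metrics import WebMetrics, compute_metrics, realized_web
from .params import ParamSet
from .sweep import SweepResult, run_sweep
from .webgen import FoodWeb, assign_cc_tradeoff

__all__ = ["PatchOccupancyModel", "SteadyStateResults"]


class PatchOccupancyModel:
    """Patch-dynamic metacommunity model of a food web under habitat loss.

    Parameters
    ----------
    web : FoodWeb
        The potential (regional) food web.
    competition : CompetitionMatrix, optional
        Basal displacement probabilities; defaults to the strict
        hierarchy (species 1 = best competitor).
    params : ParamSet, optional
        Demographic rates; defaults to the competition–colonization
        tradeoff parameterization with even colonization spacing on
        [0.45, 0.8].
    threshold : float
        Extinction cutoff on time-averaged occupancy.
    fcl_convention : {"links", "nodes"}
        Food-chain-length counting convention for derived metrics.

    Examples
    --------
    >>> from webpatch import generate_web, PatchOccupancyModel
    >>> web = generate_web(n_P=3, n_A=11, L=23, seed=7)
    >>> res = PatchOccupancyModel(web).fit()
    >>> res.metrics().richness  # doctest: +SKIP
    """

    def __init__(
        self,
        web: FoodWeb,
        competition: CompetitionMatrix | None = None,
        params: ParamSet | None = None,
        threshold: float = EXTINCTION_THRESHOLD,
        fcl_convention: str = "links",
    ):
        self.web = web
        self.competition = (
            competition if competition is not None else hierarchical_H(web.n_basal)
        )
        if self.competition.n != web.n_basal:
            raise ValueError("competition matrix size must equal n_basal")
        self.params = params if params is not None else assign_cc_tradeoff(web)
        if (self.params.n_basal, self.params.n_consumers) != (
            web.n_basal,
            web.n_consumers,
        ):
            raise ValueError("ParamSet dimensions do not match web")
        self.params.check_support(web.theta, web.delta)
        self.threshold = threshold
        self.fcl_convention = fcl_convention

    # -- construction helpers -----------------------------------------
    @classmethod
    def from_config(cls, path) -> "PatchOccupancyModel":
        """Build a model from a YAML configuration file (see webpatch.config)."""
        from .config import build_model

        return build_model(path)

    # -- solving -------------------------------------------------------
    def fit(self, method: str = "auto", U: float | None = None, **kwargs):
        """Solve to steady state; returns :class:`SteadyStateResults`.

        ``method="auto"`` uses the closed-form equilibria when the
        configuration is predation-free (mu = phi = 0) and the numerical
        burn-in/averaging protocol otherwise. Extra keyword arguments are
        passed to the ODE integrator protocol (t_burnin, t_avg, init,
        rtol, atol).
        """
        params = self.params if U is None else self.params.replace(U=float(U))
        predation_free = not (
            np.any(params.mu != 0) or np.any(params.phi != 0)
        )
        if method == "auto":
            method = "analytic" if predation_free else "ode"
        if method == "analytic":
            if not predation_free:
                raise ValueError("analytic method requires mu = phi = 0")
            state = steady_state_analytic(
                self.web, self.competition, params, self.threshold
            )
        elif method == "ode":
            state = run_to_steady_state(
                self.web, self.competition, params,
                threshold=self.threshold, **kwargs,
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return SteadyStateResults(self, state, params)

    def sweep(self, U_grid=None, mode: str = "full", **kwargs) -> SweepResult:
        """Patch-loss gradient experiment; see :func:`webpatch.sweep.run_sweep`."""
        return run_sweep(
            self.web,
            self.competition,
            self.params,
            U_grid=U_grid,
            mode=mode,
            threshold=self.threshold,
            fcl_convention=self.fcl_convention,
            **kwargs,
        )


class SteadyStateResults:
    """Steady-state solution of a :class:`PatchOccupancyModel`."""

    def __init__(self, model: PatchOccupancyModel, state: SteadyState,
                 params: ParamSet):
        self.model = model
        self.state = state
        self.params = params

    # -- accessors -----------------------------------------------------
    @property
    def P(self) -> np.ndarray:
        """Basal occupancies (0 for extinct species)."""
        return self.state.P

    @property
    def A(self) -> np.ndarray:
        """Consumer occupancies (0 for extinct species)."""
        return self.state.A

    @property
    def q(self) -> np.ndarray:
        """Basal relative abundances at steady state."""
        return self.state.q

    @property
    def extinct(self) -> np.ndarray:
        return self.state.extinct

    @property
    def method(self) -> str:
        return self.state.method

    def occupancy_series(self) -> pd.Series:
        web = self.model.web
        return pd.Series(self.state.occupancies, index=list(web.species_ids),
                         name="occupancy")

    def realized_web(self) -> FoodWeb:
        return realized_web(self.model.web, self.state)

    def metrics(self) -> WebMetrics:
        return compute_metrics(self.model.web, self.state,
                               self.model.fcl_convention)

    # -- output --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        web = self.model.web
        roles = ["basal"] * web.n_basal + ["consumer"] * web.n_consumers
        return pd.DataFrame(
            {
                "species_id": list(web.species_ids),
                "role": roles,
                "occupancy": self.state.occupancies,
                "extinct": self.state.extinct,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        """Printable summary: configuration, survivors, realized-web metrics."""
        web = self.model.web
        m = self.metrics()
        lines = [
            "Patch-occupancy steady state",
            "=" * 46,
            f"method:            {self.state.method}",
            f"patch loss U:      {self.params.U:.3f}",
            f"competition:       {self.model.competition.structure_tag}",
            f"species (potential): {web.n_species}  "
            f"(basal {web.n_basal}, consumers {web.n_consumers})",
            f"species (surviving): {self.state.n_surviving}",
            f"links (realized):  {m.links}",
            f"connectance:       {m.connectance:.4f}"
            if np.isfinite(m.connectance) else "connectance:       n/a",
            f"mean / max FCL:    {m.mean_fcl:.3f} / {m.max_fcl:.0f}"
            if np.isfinite(m.mean_fcl) else "mean / max FCL:    n/a",
            f"omnivory:          {m.omnivory:.3f}",
            f"basal inv. Simpson: {m.inv_simpson:.3f}"
            if np.isfinite(m.inv_simpson) else "basal inv. Simpson: n/a",
            "-" * 46,
        ]
        df = self.to_frame()
        lines.append(df.to_string(index=False,
                                  float_format=lambda x: f"{x:.6f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SteadyStateResults U={self.params.U:g} "
            f"surviving={self.state.n_surviving}/{self.model.web.n_species} "
            f"method={self.state.method}>"
        )
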