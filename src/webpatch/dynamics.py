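"""Patch-occupancy dynamics of food webs on fragmented landscapes.

State variables are patch occupancies: the fraction of habitat patches
holding a subpopulation of each species. Basal species i follows

    dP_i/dt = c_i^P P_i (1 - U - sum_j P_j)                 [colonization]
              - e_i^P P_i                                   [extinction]
              + sum_j (c_i^P P_i H_ij P_j - c_j^P P_j H_ji P_i)
                                                            [displacement]
              - P_i sum_k theta_ik mu_ik A_k                [predation]

where U is the fraction of permanently destroyed patches and H the
displacement-probability matrix: basal species exclude one another within
a patch, so colonizers of a superior competitor take over occupied
patches. Consumer i follows

    dA_i/dt = c_i^A A_i (sum_j theta_ji P_j + sum_k delta_ki A_k)
                        (1 - U - A_i)                       [colonization]
              - e_i^A A_i                                   [extinction]
              - A_i sum_k phi_ik delta_ik A_k               [predation]

— colonizer production is proportional to prey encounter, consumers do
not exclude each other from patches, and top predators lack the predation
loss term.

Without top-down predation (mu = 0) the basal block has Lotka–Volterra
per-capita form r_i = b_i + sum_j M_ij P_j with effective growth
b_i = c_i^P (1 - U) - e_i^P and interactions
M_ij = c_i^P H_ij - c_j^P H_ji - c_i^P, giving the closed-form
equilibrium P* = -M^{-1} b on the feasible (all-positive) surviving set.
Consumer equilibria then follow in topological (prey-before-predator)
order:  A_i* = 1 - U - e_i^A / (c_i^A * available prey at equilibrium).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .competition import CompetitionMatrix
from .params import ParamSet
from .webgen import FoodWeb

__all__ = [
    "SteadyState",
    "basal_rhs",
    "consumer_rhs",
    "effective_rates",
    "run_to_steady_state",
    "basal_equilibrium_analytic",
    "consumer_equilibrium_analytic",
    "steady_state_analytic",
]

#: default steady-state protocol: burn-in, averaging window, extinction cutoff
T_BURNIN = 15000.0
T_AVG = 5000.0
EXTINCTION_THRESHOLD = 1e-6


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced out-of-range occupancies."""


@dataclass(frozen=True)
class SteadyState:
    """Time-averaged patch occupancies at steady state.

    ``P`` and ``A`` hold the occupancies of basal species and consumers
    (0 for species flagged extinct); ``extinct`` concatenates basal then
    consumer flags; ``q`` holds basal relative abundances
    q_i = P_i / sum_j P_j over the surviving basal guild.
    """

    P: np.ndarray
    A: np.ndarray
    extinct: np.ndarray
    U: float
    threshold: float = EXTINCTION_THRESHOLD
    method: str = "ode"

    @property
    def q(self) -> np.ndarray:
        total = self.P.sum()
        if total <= 0:
            return np.zeros_like(self.P)
        return self.P / total

    @property
    def occupancies(self) -> np.ndarray:
        return np.concatenate([self.P, self.A])

    @property
    def n_surviving(self) -> int:
        return int((~self.extinct).sum())


def _check_dims(P, A, web: FoodWeb, params: ParamSet) -> None:
    if len(P) != web.n_basal or len(A) != web.n_consumers:
        raise ValueError(
            f"state dims {(len(P), len(A))} do not match web "
            f"{(web.n_basal, web.n_consumers)}"
        )
    if params.n_basal != web.n_basal or params.n_consumers != web.n_consumers:
        raise ValueError("ParamSet dimensions do not match web")


def basal_rhs(
    P: np.ndarray,
    A: np.ndarray,
    web: FoodWeb,
    H: CompetitionMatrix | np.ndarray,
    params: ParamSet,
) -> np.ndarray:
    """Right-hand side of the basal occupancy equations."""
    P, A = np.asarray(P, dtype=float), np.asarray(A, dtype=float)
    _check_dims(P, A, web, params)
    Hm = H.H if isinstance(H, CompetitionMatrix) else np.asarray(H, dtype=float)
    cP, eP, U = params.cP, params.eP, params.U
    colonization = cP * P * (1.0 - U - P.sum())
    displacement = P * (cP * (Hm @ P) - Hm.T @ (cP * P))
    predation = P * ((params.mu * web.theta) @ A) if web.n_consumers else 0.0
    return colonization - eP * P + displacement - predation


def consumer_rhs(
    P: np.ndarray,
    A: np.ndarray,
    web: FoodWeb,
    params: ParamSet,
) -> np.ndarray:
    """Right-hand side of the consumer occupancy equations."""
    P, A = np.asarray(P, dtype=float), np.asarray(A, dtype=float)
    _check_dims(P, A, web, params)
    if web.n_consumers == 0:
        return np.zeros(0)
    cA, eA, U = params.cA, params.eA, params.U
    prey = web.theta.T @ P + web.delta.T @ A
    colonization = cA * A * prey * (1.0 - U - A)
    predation = A * ((params.phi * web.delta) @ A)
    return colonization - eA * A - predation


def effective_rates(
    web: FoodWeb,
    H: CompetitionMatrix | np.ndarray,
    params: ParamSet,
) -> tuple:
    """Effective growth b and interaction matrix M of the basal subsystem.

    b_i = c_i^P (1 - U) - e_i^P;  M_ij = c_i^P H_ij - c_j^P H_ji - c_i^P
    (note M_ii = -c_i^P). Valid when top-down predation is absent, where
    the basal per-capita growth rate is exactly b_i + (M P)_i.
    """
    Hm = H.H if isinstance(H, CompetitionMatrix) else np.asarray(H, dtype=float)
    cP = params.cP
    b = cP * (1.0 - params.U) - params.eP
    M = cP[:, None] * Hm - cP[None, :] * Hm.T - cP[:, None]
    return b, M


def run_to_steady_state(
    web: FoodWeb,
    H: CompetitionMatrix | np.ndarray,
    params: ParamSet,
    t_burnin: float = T_BURNIN,
    t_avg: float = T_AVG,
    threshold: float = EXTINCTION_THRESHOLD,
    init: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_avg_samples: int = 1001,
    stationarity_tol: float | None = None,
    max_extensions: int = 60,
) -> SteadyState:
    """Integrate the full system and time-average the post-burn-in window.

    The trajectory is integrated for ``t_burnin`` time units, then for a
    further ``t_avg`` over which each species' occupancy is averaged
    (trapezoidal rule on an even grid); species whose window mean falls
    below ``threshold`` are flagged extinct and reported at occupancy 0.

    ``init`` defaults to the uniform state (1 - U) / (2 S) for every
    species, which keeps the basal guild inside its feasible simplex;
    steady states are insensitive to the start within tolerance.

    When ``stationarity_tol`` is set, integration continues in extra
    ``t_avg``-long blocks (at most ``max_extensions``) until two
    successive window means differ by less than the tolerance in every
    species — useful near feasibility boundaries, where the slowest mode
    can outlast the default burn-in.
    """
    _check_dims(
        init[: web.n_basal] if init is not None else np.zeros(web.n_basal),
        init[web.n_basal :] if init is not None else np.zeros(web.n_consumers),
        web,
        params,
    )
    n_P, n_A = web.n_basal, web.n_consumers
    S = n_P + n_A
    if init is None:
        init = np.full(S, (1.0 - params.U) / (2 * S))
    y0 = np.asarray(init, dtype=float)

    Hm = H.H if isinstance(H, CompetitionMatrix) else np.asarray(H, dtype=float)

    def rhs(t, y):
        P, A = y[:n_P], y[n_P:]
        dP = basal_rhs(P, A, web, Hm, params)
        dA = consumer_rhs(P, A, web, params)
        return np.concatenate([dP, dA])

    burn = solve_ivp(rhs, (0.0, t_burnin), y0, method="RK45",
                     rtol=rtol, atol=atol)
    if not burn.success:
        raise IntegrationError(f"ODE solver failed: {burn.message}")
    y, t0 = burn.y[:, -1], t_burnin

    mean, prev = None, None
    n_windows = 1 if stationarity_tol is None else max_extensions + 1
    for _ in range(n_windows):
        t_eval = np.linspace(t0, t0 + t_avg, n_avg_samples)
        sol = solve_ivp(rhs, (t0, t0 + t_avg), y, method="RK45",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise IntegrationError(f"ODE solver failed: {sol.message}")
        prev, mean = mean, np.trapezoid(sol.y, sol.t, axis=1) / t_avg
        y, t0 = sol.y[:, -1], t0 + t_avg
        if (stationarity_tol is not None and prev is not None
                and np.max(np.abs(mean - prev)) < stationarity_tol):
            break
    # integrator undershoot: occupancies decaying to 0 may average slightly
    # negative; anything below -threshold signals a real failure
    if np.any(mean < -threshold):
        raise IntegrationError(
            f"negative occupancies beyond tolerance: min={mean.min():.3e}"
        )
    mean = np.clip(mean, 0.0, None)
    extinct = mean < threshold
    mean[extinct] = 0.0
    return SteadyState(
        P=mean[:n_P],
        A=mean[n_P:],
        extinct=extinct,
        U=params.U,
        threshold=threshold,
        method="ode",
    )


class SingularInteractionError(np.linalg.LinAlgError):
    """Effective interaction matrix became singular during assembly."""


def basal_equilibrium_analytic(
    web: FoodWeb,
    H: CompetitionMatrix | np.ndarray,
    params: ParamSet,
    threshold: float = EXTINCTION_THRESHOLD,
) -> np.ndarray:
    """Closed-form basal equilibrium P* = -M^{-1} b on the feasible subset.

    Valid only without top-down predation (all mu zero). The coexistence
    equilibrium of the full basal guild may contain non-positive entries;
    the surviving community is assembled iteratively: the species with
    the most negative restricted-equilibrium occupancy is removed until
    the solution is strictly positive, after which excluded species are
    checked for invasibility (per-capita growth r_k = b_k + (M P*)_k at
    the candidate equilibrium) — an excluded species that could invade is
    reinstated and the assembly continues. The accepted community is thus
    a saturated equilibrium: survivors positive, excluded species unable
    to grow from rarity. (Under a strict hierarchy M is triangular in
    rank order and the procedure reduces to exact forward substitution.)

    Excluded species are reported at occupancy 0; survivors below the
    extinction threshold are zeroed without re-solving, mirroring the
    numerical protocol's treatment of near-extinct species.
    """
    if np.any(params.mu != 0):
        raise ValueError("analytic basal equilibrium requires mu = 0")
    b, M = effective_rates(web, H, params)
    n_P = web.n_basal
    alive = np.ones(n_P, dtype=bool)
    out = np.zeros(n_P)
    invasion_tol = 1e-12
    for _ in range(20 * n_P + 20):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            # empty community is saturated only if nobody grows from zero
            if np.all(b <= invasion_tol):
                return out
            alive[int(np.argmax(b))] = True
            continue
        try:
            P = np.linalg.solve(M[np.ix_(idx, idx)], -b[idx])
        except np.linalg.LinAlgError as err:
            raise SingularInteractionError(
                "singular effective interaction matrix during feasibility assembly"
            ) from err
        if np.any(P <= 0):
            alive[idx[int(np.argmin(P))]] = False
            continue
        full = np.zeros(n_P)
        full[idx] = P
        r_excluded = b + M @ full
        r_excluded[idx] = -np.inf
        if np.max(r_excluded, initial=-np.inf) > invasion_tol:
            alive[int(np.argmax(r_excluded))] = True
            continue
        full[full < threshold] = 0.0
        return full
    raise SingularInteractionError(
        "feasibility assembly cycled without finding a saturated equilibrium"
    )


def consumer_equilibrium_analytic(
    web: FoodWeb,
    params: ParamSet,
    P_star: np.ndarray,
    threshold: float = EXTINCTION_THRESHOLD,
) -> np.ndarray:
    """Consumer equilibria solved in topological (prey-before-predator) order.

    A_i* = 1 - U - e_i^A / (c_i^A * R_i) with R_i the equilibrium prey
    availability sum_j theta_ji P_j* + sum_k delta_ki A_k*. Valid without
    predation on consumers (phi = 0); acyclicity makes each A_i* depend
    only on species below it, so a single topological pass suffices.
    Consumers with no surviving prey, or a non-positive solution, are set
    extinct (0) before their own predators are evaluated.
    """
    if np.any(params.phi != 0):
        raise ValueError("analytic consumer equilibrium requires phi = 0")
    n_A = web.n_consumers
    A = np.zeros(n_A)
    U = params.U
    for i in web.consumer_topological_order():
        R = float(web.theta[:, i] @ P_star + web.delta[:, i] @ A)
        if R <= 0 or params.cA[i] == 0:
            continue
        Ai = 1.0 - U - params.eA[i] / (params.cA[i] * R)
        if Ai >= threshold:
            A[i] = Ai
    return A


def steady_state_analytic(
    web: FoodWeb,
    H: CompetitionMatrix | np.ndarray,
    params: ParamSet,
    threshold: float = EXTINCTION_THRESHOLD,
) -> SteadyState:
    """Closed-form steady state for predation-free systems (mu = phi = 0).

    Falls back to the numerical protocol (with a warning) if the
    interaction matrix turns singular during feasibility assembly.
    """
    try:
        P = basal_equilibrium_analytic(web, H, params, threshold)
    except SingularInteractionError:
        warnings.warn(
            "singular interaction matrix; falling back to ODE integration",
            RuntimeWarning,
            stacklevel=2,
        )
        return run_to_steady_state(web, H, params, threshold=threshold)
    A = consumer_equilibrium_analytic(web, params, P, threshold)
    occ = np.concatenate([P, A])
    return SteadyState(
        P=P,
        A=A,
        extinct=occ < threshold,
        U=params.U,
        threshold=threshold,
        method="analytic",
    )
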