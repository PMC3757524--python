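"""Coupled plant-resource dynamics in a patchy metacommunity.

The model follows a community of plant species competing for a single
limiting resource across ``N`` discrete patches.  Per-capita mortality of
species ``j`` is ``m_j``; recruitment in patch ``x`` occurs at the
resource-dependent rate ``b_j * g(R_x)`` and consumes ``Q_j`` units of
resource per recruit.  A fraction ``p_j`` of propagules stays in the natal
patch; the remaining ``1 - p_j`` are redistributed uniformly over all
patches (the natal patch included).  Resources are supplied at the
patch-specific rate ``S_x`` and, in the baseline model, are lost only
through plant establishment:

    dn_jx/dt = -m_j n_jx + b_j g(R_x) (p_j n_jx + (1 - p_j) <n_j>_x)
    dR_x/dt  = S_x - loss * R_x - sum_j Q_j b_j g(R_x) (p_j n_jx
                                                        + (1 - p_j) <n_j>_x)

where ``<.>_x`` is an unweighted mean over patches and ``g`` is either the
identity (baseline) or a saturating Monod-type response.

A single species in the baseline model has one stable equilibrium per
patch,

    n*_jx = S_x / (Q_j m_j)
    R*m_jx = m_j S_x / (b_j (p_j S_x + (1 - p_j) <S>_x)),

the dispersal-modified analogue of the classical ``R* = m/b``: widely
dispersing residents leave more resource behind in above-average-supply
patches (net exporters of recruits) and less in below-average patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesTraits",
    "SupplyField",
    "MetacommunityState",
    "ModelVariant",
    "SteadyStateControls",
    "SteadyStateResult",
    "DegenerateEquilibriumError",
    "ode_rhs",
    "integrate_to_steady_state",
    "single_species_equilibrium",
    "rstar_profile",
]


class DegenerateEquilibriumError(ValueError):
    """Raised when a closed-form equilibrium does not exist (m = 0)."""


@dataclass(frozen=True)
class SpeciesTraits:
    """Demographic and resource-use parameters of one species.

    Parameters
    ----------
    m : per-capita mortality rate (1/time), >= 0.
    b : birth coefficient (1/(resource * time)), > 0.
    Q : resource required per recruit, > 0.
    p : retention fraction of propagules staying in the natal patch, in [0, 1].
    species_id : optional label carried through tables and traces.
    """

    m: float
    b: float
    Q: float
    p: float
    species_id: str | None = None

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"birth coefficient b must be > 0, got {self.b}")
        if not self.Q > 0:
            raise ValueError(f"establishment requirement Q must be > 0, got {self.Q}")
        if self.m < 0:
            raise ValueError(f"mortality m must be >= 0, got {self.m}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"retention p must lie in [0, 1], got {self.p}")

    @property
    def rstar(self) -> float:
        """Classical break-even resource concentration R* = m / b."""
        return self.m / self.b


@dataclass(frozen=True)
class SupplyField:
    """Patch-specific resource supply rates S_x (> 0)."""

    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 1 or S.size == 0:
            raise ValueError("supply vector must be one-dimensional and non-empty")
        if not np.all(S > 0):
            raise ValueError("all supply rates must be > 0")
        object.__setattr__(self, "S", S)

    @property
    def n_patches(self) -> int:
        return self.S.size

    @property
    def mean_supply(self) -> float:
        return float(self.S.mean())

    @property
    def s(self) -> np.ndarray:
        """Mean-zero relative supply deviations s_x = S_x/<S> - 1."""
        return self.S / self.mean_supply - 1.0

    @property
    def var_s(self) -> float:
        """Spatial variance of s (population convention, = squared CV of S)."""
        return float(np.mean(self.s**2))


@dataclass
class MetacommunityState:
    """Densities (species x patch) and resource concentrations at time t."""

    n: np.ndarray
    R: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.atleast_2d(np.asarray(self.n, dtype=float))
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 1:
            raise ValueError("resource vector R must be one-dimensional")
        if self.n.shape[1] != self.R.size:
            raise ValueError(
                f"density matrix has {self.n.shape[1]} patches but R has {self.R.size}"
            )
        if np.any(self.n < 0) or np.any(self.R < 0):
            raise ValueError("densities and resources must be non-negative")

    @property
    def n_species(self) -> int:
        return self.n.shape[0]

    @property
    def n_patches(self) -> int:
        return self.R.size


@dataclass(frozen=True)
class ModelVariant:
    """Model variant switches.

    ``resource_loss_rate`` adds a linear resource decay term (maintenance,
    leaching); ``establishment_response`` selects the recruitment response
    g(R): ``"linear"`` gives g(R) = R, ``"saturating"`` gives the
    slope-preserving Monod form g(R) = R / (1 + R/k) with half-saturation
    constant k shared by all species (linear model recovered as k -> inf).
    """

    resource_loss_rate: float = 0.0
    establishment_response: str = "linear"
    half_saturation: float = 1.0

    def __post_init__(self) -> None:
        if self.resource_loss_rate < 0:
            raise ValueError("resource loss rate must be >= 0")
        if self.establishment_response not in ("linear", "saturating"):
            raise ValueError(
                "establishment_response must be 'linear' or 'saturating'"
            )
        if self.establishment_response == "saturating" and not self.half_saturation > 0:
            raise ValueError("half-saturation constant must be > 0")

    @property
    def is_baseline(self) -> bool:
        return self.resource_loss_rate == 0.0 and self.establishment_response == "linear"

    def g(self, R: np.ndarray | float) -> np.ndarray | float:
        """Establishment response g(R)."""
        if self.establishment_response == "linear":
            return R
        return R / (1.0 + R / self.half_saturation)


BASELINE = ModelVariant()


def _trait_arrays(traits: Sequence[SpeciesTraits]) -> tuple[np.ndarray, ...]:
    m = np.array([t.m for t in traits])
    b = np.array([t.b for t in traits])
    Q = np.array([t.Q for t in traits])
    p = np.array([t.p for t in traits])
    return m, b, Q, p


def _rhs_arrays(
    n: np.ndarray,
    R: np.ndarray,
    m: np.ndarray,
    b: np.ndarray,
    Q: np.ndarray,
    p: np.ndarray,
    S: np.ndarray,
    variant: ModelVariant,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised right-hand side on raw arrays (no validation)."""
    gR = variant.g(R)  # (N,)
    nbar = n.mean(axis=1, keepdims=True)  # (J, 1)
    recruit_pool = p[:, None] * n + (1.0 - p)[:, None] * nbar  # (J, N)
    births = b[:, None] * gR[None, :] * recruit_pool
    dn = -m[:, None] * n + births
    consumption = (Q[:, None] * births).sum(axis=0)
    dR = S - variant.resource_loss_rate * R - consumption
    return dn, dR


def ode_rhs(
    state: MetacommunityState,
    traits: Sequence[SpeciesTraits],
    field: SupplyField,
    variant: ModelVariant = BASELINE,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dn/dt, dR/dt) of the coupled system.

    Rejects dimension mismatches and negative states; the propagule pool in
    every patch mixes retained local seeds with the uniform 1/N share of the
    dispersed seeds of all patches (natal patch included).
    """
    if state.n_species != len(traits):
        raise ValueError(
            f"state has {state.n_species} species but {len(traits)} trait sets given"
        )
    if state.n_patches != field.n_patches:
        raise ValueError(
            f"state has {state.n_patches} patches but supply field has {field.n_patches}"
        )
    m, b, Q, p = _trait_arrays(traits)
    return _rhs_arrays(state.n, state.R, m, b, Q, p, field.S, variant)


@dataclass(frozen=True)
class SteadyStateControls:
    """Integrator and convergence controls.

    Convergence is judged on the resource field — max_x |dR_x/dt| / S_x
    below ``tolerance`` — rather than on densities, because zero-mortality
    parameterisations grow without bound while the resource field stabilises,
    and invasion analysis consumes only the resource field.  Densities below
    ``extinction_floor`` times the metacommunity mean density are zeroed in
    the returned state.
    """

    horizon: float = 1e5
    tolerance: float = 1e-8
    rtol: float = 1e-8
    atol: float = 1e-10
    extinction_floor: float = 1e-9
    first_chunk: float = 10.0
    chunk_growth: float = 4.0
    method: str = "LSODA"
    density_tolerance: float | None = None
    prune_during_integration: bool = False


@dataclass
class SteadyStateResult:
    state: MetacommunityState
    converged: bool
    message: str = ""


def _apply_extinction_floor(n: np.ndarray, floor: float) -> np.ndarray:
    n = n.copy()
    mean_density = n.mean()
    if mean_density > 0:
        n[n < floor * mean_density] = 0.0
    return n


def integrate_to_steady_state(
    initial: MetacommunityState,
    traits: Sequence[SpeciesTraits],
    field: SupplyField,
    variant: ModelVariant = BASELINE,
    controls: SteadyStateControls = SteadyStateControls(),
) -> SteadyStateResult:
    """Integrate the coupled ODEs until the resource field is stationary.

    The system is advanced in geometrically growing chunks with a stiff-safe
    adaptive integrator; after each chunk the convergence criterion
    ``max_x |dR_x/dt| / S_x < tolerance`` is evaluated.  A hard horizon
    bounds total integration time; hitting it returns the final state with
    ``converged=False``.  Non-finite states abort with the failure time.
    """
    J, N = initial.n.shape
    m, b, Q, p = _trait_arrays(traits)
    if len(traits) != J:
        raise ValueError("trait list does not match state")
    if field.n_patches != N:
        raise ValueError("supply field does not match state")
    S = field.S

    def flat_rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = y[: J * N].reshape(J, N)
        R = y[J * N :]
        dn, dR = _rhs_arrays(n, R, m, b, Q, p, S, variant)
        return np.concatenate([dn.ravel(), dR])

    def flat_jac(t: float, y: np.ndarray) -> np.ndarray:
        n = y[: J * N].reshape(J, N)
        R = y[J * N :]
        gR = np.asarray(variant.g(R), dtype=float)
        if variant.establishment_response == "linear":
            gprime = np.ones(N)
        else:
            k = variant.half_saturation
            gprime = 1.0 / (1.0 + R / k) ** 2
        pool = p[:, None] * n + (1.0 - p)[:, None] * n.mean(axis=1)[:, None]
        Jm = np.zeros((J * N + N, J * N + N))
        diag = np.arange(N)
        for j in range(J):
            r0 = j * N
            blk = np.full((N, N), b[j] * (1.0 - p[j]) / N) * gR[:, None]
            blk[diag, diag] += b[j] * p[j] * gR - m[j]
            Jm[r0 : r0 + N, r0 : r0 + N] = blk
            Jm[r0 + diag, J * N + diag] = b[j] * gprime * pool[j]
            # consumption block lacks the mortality term of the growth block
            cons = np.full((N, N), Q[j] * b[j] * (1.0 - p[j]) / N) * gR[:, None]
            cons[diag, diag] += Q[j] * b[j] * p[j] * gR
            Jm[J * N :, r0 : r0 + N] = -cons
        Jm[J * N + diag, J * N + diag] = -variant.resource_loss_rate - (
            Q[:, None] * b[:, None] * gprime[None, :] * pool
        ).sum(axis=0)
        return Jm

    y = np.concatenate([initial.n.ravel(), initial.R])
    t = initial.t
    t_end = initial.t + controls.horizon
    chunk = controls.first_chunk
    converged = False
    message = ""
    while t < t_end:
        t_next = min(t + chunk, t_end)
        sol = solve_ivp(
            flat_rhs,
            (t, t_next),
            y,
            method=controls.method,
            rtol=controls.rtol,
            atol=controls.atol,
            jac=flat_jac if controls.method in ("LSODA", "BDF", "Radau") else None,
            t_eval=[t_next],
            dense_output=False,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise RuntimeError(
                f"integration failed at t={sol.t[-1]:.6g}: {sol.message}"
            )
        y = sol.y[:, -1]
        # clip integrator undershoot below zero
        np.clip(y, 0.0, None, out=y)
        t = sol.t[-1]
        if controls.prune_during_integration:
            n_now = y[: J * N].reshape(J, N)
            y[: J * N] = _apply_extinction_floor(n_now, controls.extinction_floor).ravel()
        dy = flat_rhs(t, y)
        dR = dy[J * N :]
        ok = np.max(np.abs(dR) / S) < controls.tolerance
        if ok and controls.density_tolerance is not None:
            totals = y[: J * N].reshape(J, N).sum(axis=1)
            dtotals = dy[: J * N].reshape(J, N).sum(axis=1)
            alive = totals > 0
            if np.any(alive):
                rel = np.abs(dtotals[alive]) / totals[alive]
                ok = bool(np.max(rel) < controls.density_tolerance)
        if ok:
            converged = True
            break
        chunk *= controls.chunk_growth
    if not converged:
        message = f"horizon {controls.horizon:g} reached before resource stationarity"
    n = _apply_extinction_floor(y[: J * N].reshape(J, N), controls.extinction_floor)
    state = MetacommunityState(n=n, R=y[J * N :], t=t)
    return SteadyStateResult(state=state, converged=converged, message=message)


def single_species_equilibrium(
    traits: SpeciesTraits, field: SupplyField
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form single-species equilibrium (n*_x, R*m_x), baseline model.

    ``n*_x = S_x / (Q m)`` is independent of dispersal;
    ``R*m_x = m S_x / (b (p S_x + (1-p) <S>))`` pivots around R* = m/b at
    the mean-supply patch.  Refuses m = 0, which has no finite equilibrium.
    """
    if traits.m == 0:
        raise DegenerateEquilibriumError(
            "m = 0 has no finite single-species equilibrium; integrate the "
            "dynamics over a finite horizon instead"
        )
    S = field.S
    nstar = S / (traits.Q * traits.m)
    rstar_m = traits.m * S / (traits.b * (traits.p * S + (1.0 - traits.p) * field.mean_supply))
    return nstar, rstar_m


def rstar_profile(
    traits: SpeciesTraits,
    field: SupplyField,
    supply_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium residual resource R*m as a function of local supply rate.

    Tabulates R*m over a supply gradient holding the metacommunity mean
    supply at ``field.mean_supply``.  All profiles cross at R* = m/b where
    the local supply equals the mean; lower retention raises the residual
    resource in above-average patches and lowers it in below-average ones.
    """
    if traits.m == 0:
        raise DegenerateEquilibriumError("m = 0 has no equilibrium profile")
    if supply_grid is None:
        supply_grid = np.linspace(field.S.min(), field.S.max(), 101)
    supply_grid = np.asarray(supply_grid, dtype=float)
    rm = traits.m * supply_grid / (
        traits.b * (traits.p * supply_grid + (1.0 - traits.p) * field.mean_supply)
    )
    return supply_grid, rm


def uniform_initial_state(
    traits: Sequence[SpeciesTraits],
    field: SupplyField,
    density_scale: float | None = None,
) -> MetacommunityState:
    """Equal-density starting state with resources at their supply values.

    Default density is <S>/Q per species per patch, an unbiased start for
    competition experiments.
    """
    J, N = len(traits), field.n_patches
    n = np.empty((J, N))
    for j, tr in enumerate(traits):
        scale = density_scale if density_scale is not None else field.mean_supply / tr.Q
        n[j, :] = scale
    return MetacommunityState(n=n, R=field.S.copy(), t=0.0)
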