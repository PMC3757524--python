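"""Low-density invasion analysis on a frozen resident resource field.

An invader at vanishing density has no feedback on the resource, so its
patch densities obey the linear system ``dn_i/dt = A n_i`` with

    A[x, y] = delta_xy (-m_i + b_i p_i g(Rhat_x)) + b_i (1 - p_i) g(Rhat_x) / N,

the resident steady-state field ``Rhat`` held fixed.  ``A`` is Metzler
(non-negative off-diagonal), so a real dominant eigenvalue with a
non-negative eigenvector exists; that eigenvalue is the metacommunity-scale
low-density growth rate and the eigenvector (scaled to mean one) is the
invader's stationary spatial distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    BASELINE,
    MetacommunityState,
    ModelVariant,
    SpeciesTraits,
    SteadyStateControls,
    SteadyStateResult,
    SupplyField,
    integrate_to_steady_state,
    single_species_equilibrium,
    uniform_initial_state,
)

__all__ = [
    "InvasionOutcome",
    "invasion_matrix",
    "dominant_eigenpair",
    "resident_steady_state",
    "invasion_growth_rate",
    "mutual_invasion",
    "pairwise_invasibility_grid",
]

_TIE_RTOL = 1e-9


@dataclass
class InvasionOutcome:
    """Result of a low-density invasion calculation."""

    growth_rate: float  # dominant eigenvalue, per unit time
    per_generation: float  # growth_rate / b_i
    distribution: np.ndarray  # nu_i, mean 1, entries >= 0
    resident_field_checksum: float
    method: str = "eigenvalue"
    degenerate_dominant: bool = False


def invasion_matrix(
    invader: SpeciesTraits,
    resident_field_R: np.ndarray,
    variant: ModelVariant = BASELINE,
) -> np.ndarray:
    """N x N linearised growth operator of a rare invader on a fixed field."""
    R = np.asarray(resident_field_R, dtype=float)
    if R.ndim != 1:
        raise ValueError("resident field must be a one-dimensional vector")
    if np.any(R < 0):
        raise ValueError("resident field has negative resource concentrations")
    N = R.size
    gR = np.asarray(variant.g(R), dtype=float)
    A = np.full((N, N), 0.0)
    A += invader.b * (1.0 - invader.p) * gR[:, None] / N
    A[np.diag_indices(N)] += -invader.m + invader.b * invader.p * gR
    return A


def dominant_eigenpair(A: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Largest-real-part eigenvalue and its mean-one non-negative eigenvector.

    Asserts the Perron structure expected of a Metzler matrix; returns a
    flag marking a (numerically) non-unique dominant eigenvalue.
    """
    offdiag = A - np.diag(np.diag(A))
    if np.any(offdiag < -1e-12):
        raise ValueError("invasion matrix is not Metzler (negative off-diagonals)")
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(vals.real)[::-1]
    lam = vals[order[0]]
    if abs(lam.imag) > 1e-9 * (1.0 + abs(lam.real)):
        raise ValueError("dominant eigenvalue of the invasion matrix is not real")
    degenerate = False
    if len(order) > 1:
        gap = vals[order[0]].real - vals[order[1]].real
        degenerate = gap <= _TIE_RTOL * (1.0 + abs(lam.real))
    v = vecs[:, order[0]].real
    # Perron vector has one sign; orient positive and rescale to mean 1.
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    if v.mean() <= 0:
        raise ValueError("dominant eigenvector is not positive")
    return float(lam.real), v / v.mean(), degenerate


def resident_steady_state(
    residents: Sequence[SpeciesTraits],
    field: SupplyField,
    variant: ModelVariant = BASELINE,
    controls: SteadyStateControls = SteadyStateControls(),
    initial: MetacommunityState | None = None,
) -> SteadyStateResult:
    """Steady state of the resident community.

    A single baseline resident with m > 0 uses the closed-form equilibrium;
    anything else is integrated with the finite-horizon steady-state rule
    (the achieved field of zero-mortality residents feeds invasion analysis,
    mirroring a run-to-steady-state-then-invade procedure).
    """
    if len(residents) == 1 and variant.is_baseline and residents[0].m > 0:
        nstar, rm = single_species_equilibrium(residents[0], field)
        state = MetacommunityState(n=nstar[None, :], R=rm, t=0.0)
        return SteadyStateResult(state=state, converged=True, message="closed form")
    if initial is None:
        initial = uniform_initial_state(residents, field)
    return integrate_to_steady_state(initial, residents, field, variant, controls)


def invasion_growth_rate(
    invader: SpeciesTraits,
    residents: Sequence[SpeciesTraits],
    field: SupplyField,
    variant: ModelVariant = BASELINE,
    controls: SteadyStateControls = SteadyStateControls(),
    resident_state: MetacommunityState | None = None,
    require_convergence: bool = True,
) -> InvasionOutcome:
    """Metacommunity-scale low-density growth rate of ``invader``.

    The residents are brought to steady state first (or a precomputed
    resident state is supplied); the invader's dominant eigenvalue and
    stationary distribution are read off the frozen resource field.
    """
    if resident_state is None:
        res = resident_steady_state(residents, field, variant, controls)
        if require_convergence and not res.converged:
            raise RuntimeError(f"resident community did not converge: {res.message}")
        resident_state = res.state
    A = invasion_matrix(invader, resident_state.R, variant)
    lam, nu, degenerate = dominant_eigenpair(A)
    return InvasionOutcome(
        growth_rate=lam,
        per_generation=lam / invader.b,
        distribution=nu,
        resident_field_checksum=float(resident_state.R.sum()),
        method="eigenvalue",
        degenerate_dominant=degenerate,
    )


def mutual_invasion(
    pair: tuple[SpeciesTraits, SpeciesTraits],
    field: SupplyField,
    variant: ModelVariant = BASELINE,
    controls: SteadyStateControls = SteadyStateControls(),
    zero_tolerance: float = 1e-9,
) -> dict:
    """Reciprocal-invasion verdict for a species pair.

    Returns a dict with the two growth rates and a verdict: ``"coexist"``
    when both reciprocal rates are positive, ``"exclusion"`` with the winner
    when exactly one is, ``"contingent"`` (founder control) when both are
    negative, and ``"neutral"`` on the boundary.
    """
    a, b = pair
    lam_a = invasion_growth_rate(a, [b], field, variant, controls).growth_rate
    lam_b = invasion_growth_rate(b, [a], field, variant, controls).growth_rate
    pos_a = lam_a > zero_tolerance
    pos_b = lam_b > zero_tolerance
    neg_a = lam_a < -zero_tolerance
    neg_b = lam_b < -zero_tolerance
    if pos_a and pos_b:
        verdict, winner = "coexist", None
    elif pos_a and neg_b:
        verdict, winner = "exclusion", 0
    elif pos_b and neg_a:
        verdict, winner = "exclusion", 1
    elif neg_a and neg_b:
        verdict, winner = "contingent", None
    else:
        verdict, winner = "neutral", None
    return {
        "growth_rate_a": lam_a,
        "growth_rate_b": lam_b,
        "verdict": verdict,
        "winner": winner,
    }


def pairwise_invasibility_grid(
    strategy_grid: np.ndarray,
    traits_of,
    field: SupplyField,
    variant: ModelVariant = BASELINE,
    controls: SteadyStateControls = SteadyStateControls(),
    fixed_residents: Sequence[SpeciesTraits] = (),
) -> dict:
    """Invasion growth rate lambda(p_i; p_r) over a strategy grid.

    ``traits_of`` maps a strategy value to :class:`SpeciesTraits` (typically
    a tradeoff manifold).  Each column is a resident strategy (plus optional
    ``fixed_residents`` for multi-resident plots); each row an invader.
    Residents whose community fails to converge are marked in
    ``resident_converged`` rather than silently skipped.
    """
    grid = np.asarray(strategy_grid, dtype=float)
    n = grid.size
    lam = np.full((n, n), np.nan)
    resident_converged = np.zeros(n, dtype=bool)
    for c, pr in enumerate(grid):
        residents = list(fixed_residents) + [traits_of(pr)]
        res = resident_steady_state(residents, field, variant, controls)
        resident_converged[c] = res.converged
        if not res.converged:
            continue
        for r, pi in enumerate(grid):
            A = invasion_matrix(traits_of(pi), res.state.R, variant)
            lam[r, c], _, _ = dominant_eigenpair(A)
    return {
        "grid": grid,
        "lambda": lam,
        "sign": np.sign(lam),
        "resident_converged": resident_converged,
    }
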