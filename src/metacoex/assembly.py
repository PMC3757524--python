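"""Sequential-invasion community assembly on a competition-dispersal tradeoff.

Strategies live on a one-parameter manifold trading competitive ability
(R*) against propagule retention (p): ``R*(p) = Z + p^tau`` in the
retention orientation (better competitors disperse more), or
``R*(p) = Z + (1 - p)^tau`` in the dispersed-fraction orientation.  The
linear retention-orientation manifold with Z = 0 (``R* = p``, equivalently
R* = 1 - dispersed fraction) is available as the ``"linear"`` preset.

Assembly follows adaptive dynamics: starting from a monoculture, the
strategy grid is scanned for invaders with positive metacommunity-scale
growth rate into the current residents' steady state; a candidate is
admitted only if it can coexist with every current resident (mutual
invasion) and resists exclusion by its neighbouring grid strategies.  When
no strategy can be added, residents are refined by neighbour substitution
(a resident is replaced by an adjacent strategy that invades the community
the resident cannot re-enter), and the procedure terminates when neither
addition nor substitution is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .invasion import dominant_eigenpair, invasion_matrix, resident_steady_state
from .model import (
    BASELINE,
    ModelVariant,
    SpeciesTraits,
    SteadyStateControls,
    SupplyField,
)

__all__ = [
    "TradeoffManifold",
    "AssemblyTrace",
    "tradeoff_rstar",
    "sequential_assembly",
    "count_coexisting",
]


@dataclass(frozen=True)
class TradeoffManifold:
    """Competition-dispersal tradeoff R*(p) = Z + p^tau (retention) or
    Z + (1-p)^tau (dispersed-fraction orientation)."""

    Z: float = 0.0
    tau: float = 1.0
    orientation: str = "retention"
    b: float = 1.0
    Q: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tradeoff exponent tau must be > 0")
        if self.orientation not in ("retention", "dispersed"):
            raise ValueError("orientation must be 'retention' or 'dispersed'")
        if not (self.b > 0 and self.Q > 0):
            raise ValueError("b and Q must be > 0")

    @classmethod
    def linear(cls, **kwargs) -> "TradeoffManifold":
        """The linear retention-orientation tradeoff R* = p (Z=0, tau=1):
        in terms of the dispersed fraction d = 1 - p this is R* = 1 - d."""
        return cls(Z=0.0, tau=1.0, orientation="retention", **kwargs)

    def rstar(self, p: float) -> float:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"strategy p must lie in [0, 1], got {p}")
        base = p if self.orientation == "retention" else 1.0 - p
        r = self.Z + base**self.tau
        if r < 0:
            raise ValueError(f"strategy p={p} is inadmissible: R*={r} < 0")
        return r

    def admissible(self, p: float) -> bool:
        base = p if self.orientation == "retention" else 1.0 - p
        return self.Z + base**self.tau >= 0

    def traits(self, p: float) -> SpeciesTraits:
        """Species traits induced by strategy p (m = b R*(p))."""
        return SpeciesTraits(
            m=self.b * self.rstar(p), b=self.b, Q=self.Q, p=p,
            species_id=f"p={p:.6g}",
        )


def tradeoff_rstar(p: float, manifold: TradeoffManifold) -> float:
    """R* induced by strategy ``p`` on the manifold."""
    return manifold.rstar(p)


@dataclass
class AssemblyTrace:
    """Record of one sequential-invasion run."""

    grid: np.ndarray
    steps: list = dc_field(default_factory=list)
    final_residents: list = dc_field(default_factory=list)
    terminated: bool = False
    termination_reason: str = ""
    max_external_growth: float = float("nan")


class _Assembler:
    def __init__(self, manifold, field, variant, grid, controls, invasion_tol):
        self.manifold = manifold
        self.field = field
        self.variant = variant
        self.grid = grid
        self.controls = controls
        self.tol = invasion_tol
        self.traits = [manifold.traits(p) for p in grid]
        self._eq_cache: dict[tuple[int, ...], object] = {}

    def equilibrium(self, idx: tuple[int, ...]):
        key = tuple(sorted(idx))
        if key not in self._eq_cache:
            residents = [self.traits[i] for i in key]
            self._eq_cache[key] = resident_steady_state(
                residents, self.field, self.variant, self.controls
            )
        return self._eq_cache[key]

    def lam(self, invader_idx: int, field_R: np.ndarray) -> float:
        A = invasion_matrix(self.traits[invader_idx], field_R, self.variant)
        val, _, _ = dominant_eigenpair(A)
        return val

    def growth_curve(self, field_R: np.ndarray) -> np.ndarray:
        return np.array([self.lam(i, field_R) for i in range(len(self.grid))])

    def mutually_coexists(self, residents: tuple[int, ...], c: int) -> bool:
        """Every current resident must invade the steady state of the set
        with itself removed and the candidate added."""
        for r in residents:
            others = tuple(i for i in residents if i != r) + (c,)
            eq = self.equilibrium(others)
            if not eq.converged:
                return False
            if self.lam(r, eq.state.R) <= self.tol:
                return False
        return True

    def resists_neighbours(self, residents: tuple[int, ...], c: int) -> bool:
        """Candidate must not be invadable-and-unable-to-return against its
        adjacent grid strategies in the would-be community."""
        eq_with_c = self.equilibrium(residents + (c,))
        if not eq_with_c.converged:
            return True  # cannot evaluate; do not block admission on it
        for v in (c - 1, c + 1):
            if v < 0 or v >= len(self.grid) or v in residents:
                continue
            if not self.manifold.admissible(self.grid[v]):
                continue
            if self.lam(v, eq_with_c.state.R) > self.tol:
                eq_with_v = self.equilibrium(residents + (v,))
                if eq_with_v.converged and self.lam(c, eq_with_v.state.R) <= self.tol:
                    return False
        return True

    def eviction(self, residents: tuple[int, ...], S: np.ndarray):
        """Replace a resident by an adjacent strategy that invades the
        current community the resident cannot re-enter; the swap must keep
        every member of the swapped set alive at its joint steady state."""
        for u in residents:
            for v in (u - 1, u + 1):
                if v < 0 or v >= len(self.grid) or v in residents:
                    continue
                if not self.manifold.admissible(self.grid[v]):
                    continue
                if S[v] <= self.tol:
                    continue
                swapped = tuple(i for i in residents if i != u) + (v,)
                eq_sw = self.equilibrium(swapped)
                if not eq_sw.converged:
                    continue
                if np.any(eq_sw.state.n.sum(axis=1) <= 0):
                    continue  # swap would collapse the community
                if self.lam(u, eq_sw.state.R) <= self.tol:
                    return u, v
        return None


def sequential_assembly(
    manifold: TradeoffManifold,
    field: SupplyField,
    variant: ModelVariant = BASELINE,
    grid: np.ndarray | int = 101,
    controls: SteadyStateControls = SteadyStateControls(),
    initial: float | None = None,
    max_steps: int = 200,
    invasion_tol: float = 1e-7,
) -> AssemblyTrace:
    """Assemble a community by sequential invasion over the strategy grid.

    ``initial`` is the starting monoculture strategy (nearest grid point is
    used); by default the grid's best classical competitor (lowest R* among
    strategies with positive mortality).  Returns an :class:`AssemblyTrace`
    whose ``final_residents`` are the strategy values of the terminal
    community; ``max_external_growth`` records the largest invasion rate
    left on the grid at termination (positive entries can remain only for
    strategies that invade but cannot form a coexisting community).
    """
    if isinstance(grid, (int, np.integer)):
        grid = np.linspace(0.0, 1.0, int(grid))
    grid = np.asarray(grid, dtype=float)
    asm = _Assembler(manifold, field, variant, grid, controls, invasion_tol)
    trace = AssemblyTrace(grid=grid)

    admissible = np.array([manifold.admissible(p) for p in grid])
    viable = admissible & np.array([manifold.traits(p).m > 0 for p in grid])
    if initial is None:
        rstars = np.array(
            [manifold.rstar(p) if viable[i] else np.inf for i, p in enumerate(grid)]
        )
        start = int(np.argmin(rstars))
    else:
        candidates = np.where(viable)[0]
        start = int(candidates[np.argmin(np.abs(grid[candidates] - initial))])
    residents: tuple[int, ...] = (start,)

    for step in range(max_steps):
        eq = asm.equilibrium(residents)
        if not eq.converged:
            trace.termination_reason = (
                f"resident equilibrium failed to converge for {grid[list(residents)]}"
            )
            trace.steps.append({"residents": grid[list(residents)].tolist(),
                                "action": "abort"})
            break
        # prune residents extinct at the joint steady state
        alive = tuple(
            r for k, r in enumerate(sorted(residents))
            if eq.state.n[k].sum() > 0
        )
        if len(alive) < len(residents):
            trace.steps.append({
                "residents": grid[list(residents)].tolist(),
                "action": "prune",
                "removed": [grid[r] for r in residents if r not in alive],
            })
            residents = alive
            continue
        S = asm.growth_curve(eq.state.R)
        order = np.argsort(S)[::-1]
        admitted = None
        for c in order:
            c = int(c)
            if c in residents or not admissible[c]:
                continue
            if S[c] <= invasion_tol:
                break
            if not asm.mutually_coexists(residents, c):
                continue
            if not asm.resists_neighbours(residents, c):
                continue
            admitted = c
            break
        if admitted is not None:
            trace.steps.append({
                "residents": grid[list(residents)].tolist(),
                "action": "admit",
                "candidate": float(grid[admitted]),
                "growth_rate": float(S[admitted]),
            })
            residents = residents + (admitted,)
            continue
        swap = asm.eviction(residents, S)
        if swap is not None:
            u, v = swap
            trace.steps.append({
                "residents": grid[list(residents)].tolist(),
                "action": "substitute",
                "evicted": float(grid[u]),
                "replacement": float(grid[v]),
            })
            residents = tuple(i for i in residents if i != u) + (v,)
            continue
        external = [S[i] for i in range(len(grid)) if i not in residents]
        trace.max_external_growth = float(max(external)) if external else float("nan")
        trace.terminated = True
        trace.termination_reason = "no admissible invader or substitution"
        break
    else:
        trace.termination_reason = f"step cap {max_steps} reached (possible cycle)"

    trace.final_residents = sorted(float(grid[i]) for i in residents)
    return trace


def count_coexisting(trace: AssemblyTrace) -> int:
    """Number of strategies in the terminal resident set."""
    if not trace.terminated:
        raise ValueError(
            f"assembly did not terminate: {trace.termination_reason or 'in progress'}"
        )
    return len(trace.final_residents)
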