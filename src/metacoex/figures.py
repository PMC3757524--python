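"""Figure helpers: residual-resource profiles and invasibility contours."""

from __future__ import annotations

from typing import Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .model import SpeciesTraits, SupplyField, rstar_profile  # noqa: E402

__all__ = ["plot_rstar_profiles", "plot_pip"]


def plot_rstar_profiles(
    traits_list: Sequence[SpeciesTraits],
    field: SupplyField,
    supply_grid: np.ndarray | None = None,
    ax=None,
):
    """Residual resource R*m against local supply rate, one curve per
    species/retention; curves for one species pivot through R* = m/b at the
    mean supply rate."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for tr in traits_list:
        S, rm = rstar_profile(tr, field, supply_grid)
        label = tr.species_id or f"R*={tr.rstar:.2g}, p={tr.p:.2g}"
        ax.plot(S, rm, label=label)
    ax.axvline(field.mean_supply, color="0.7", lw=0.8, ls=":")
    ax.set_xlabel("patch supply rate $S_x$")
    ax.set_ylabel(r"residual resource $R^{*m}_{jx}$")
    ax.legend(fontsize=8)
    return ax


def plot_pip(grid: np.ndarray, lam: np.ndarray, ax=None):
    """Pairwise invasibility plot: black = negative invader growth rate,
    white = positive (resident strategy on x, invader on y)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.contourf(
        grid, grid, lam, levels=[-np.inf, 0.0, np.inf], colors=["black", "white"]
    )
    ax.set_xlabel("resident strategy $p_r$")
    ax.set_ylabel("invader strategy $p_i$")
    return ax
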