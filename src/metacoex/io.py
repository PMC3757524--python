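"""Tabular readers/writers and the seeded supply-field generator.

All tables are single-header CSV.  Trait tables have columns
``species_id, m, b, Q, p``; supply tables ``patch_id, S`` (patches numbered
from 1 in files); state snapshots are a long table ``species_id, patch_id,
n`` plus ``patch_id, R``.  Numbers are written with 17 significant digits
so that write-then-read round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import MetacommunityState, SpeciesTraits, SupplyField

__all__ = [
    "generate_supply",
    "read_traits",
    "write_traits",
    "read_supply",
    "write_supply",
    "read_state",
    "write_state",
    "write_partition_table",
]

_FLOAT_FMT = "%.17g"


def generate_supply(
    n_patches: int,
    mu: float = 1.0,
    sigma: float = 1.5,
    seed: int | None = None,
    convention: str = "log",
) -> SupplyField:
    """Seeded log-normal supply field S_x.

    ``convention="log"`` (default) reads (mu, sigma) as the mean and
    standard deviation of log S; ``"arithmetic"`` reads them as the
    arithmetic mean and standard deviation of S itself and converts.
    """
    if n_patches < 1:
        raise ValueError("need at least one patch")
    if sigma < 0:
        raise ValueError("dispersion parameter must be >= 0")
    if convention == "log":
        log_mu, log_sigma = mu, sigma
    elif convention == "arithmetic":
        if mu <= 0:
            raise ValueError("arithmetic mean must be > 0")
        log_sigma2 = np.log1p((sigma / mu) ** 2)
        log_mu = np.log(mu) - log_sigma2 / 2.0
        log_sigma = np.sqrt(log_sigma2)
    else:
        raise ValueError("convention must be 'log' or 'arithmetic'")
    rng = np.random.default_rng(seed)
    S = np.exp(rng.normal(log_mu, log_sigma, size=n_patches))
    return SupplyField(S=S)


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing column(s): {', '.join(missing)}")


def write_traits(traits: Sequence[SpeciesTraits], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "species_id": [t.species_id or f"sp{i + 1}" for i, t in enumerate(traits)],
            "m": [t.m for t in traits],
            "b": [t.b for t in traits],
            "Q": [t.Q for t in traits],
            "p": [t.p for t in traits],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traits(path: str | Path) -> list[SpeciesTraits]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["species_id", "m", "b", "Q", "p"], "trait")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SpeciesTraits(
                    m=float(row["m"]), b=float(row["b"]), Q=float(row["Q"]),
                    p=float(row["p"]), species_id=str(row["species_id"]),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"malformed trait row {i + 2} in {path}: {err}") from err
    return out


def write_supply(field: SupplyField, path: str | Path) -> None:
    df = pd.DataFrame(
        {"patch_id": np.arange(1, field.n_patches + 1), "S": field.S}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_supply(path: str | Path) -> SupplyField:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["patch_id", "S"], "supply")
    df = df.sort_values("patch_id")
    return SupplyField(S=df["S"].to_numpy(dtype=float))


def write_state(
    state: MetacommunityState,
    traits: Sequence[SpeciesTraits],
    density_path: str | Path,
    resource_path: str | Path,
) -> None:
    ids = [t.species_id or f"sp{i + 1}" for i, t in enumerate(traits)]
    rows = {
        "species_id": np.repeat(ids, state.n_patches),
        "patch_id": np.tile(np.arange(1, state.n_patches + 1), state.n_species),
        "n": state.n.ravel(),
    }
    pd.DataFrame(rows).to_csv(density_path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        {"patch_id": np.arange(1, state.n_patches + 1), "R": state.R}
    ).to_csv(resource_path, index=False, float_format=_FLOAT_FMT)


def read_state(
    density_path: str | Path, resource_path: str | Path
) -> tuple[MetacommunityState, list[str]]:
    dn = pd.read_csv(density_path, float_precision="round_trip")
    _check_columns(dn, ["species_id", "patch_id", "n"], "density")
    dr = pd.read_csv(resource_path, float_precision="round_trip")
    _check_columns(dr, ["patch_id", "R"], "resource")
    dr = dr.sort_values("patch_id")
    ids = list(dict.fromkeys(dn["species_id"]))
    N = dr.shape[0]
    n = np.empty((len(ids), N))
    for j, sid in enumerate(ids):
        sub = dn[dn["species_id"] == sid].sort_values("patch_id")
        if sub.shape[0] != N:
            raise ValueError(f"species {sid} has {sub.shape[0]} patches, expected {N}")
        n[j] = sub["n"].to_numpy(dtype=float)
    state = MetacommunityState(n=n, R=dr["R"].to_numpy(dtype=float))
    return state, ids


def write_partition_table(rows: Sequence[dict], path: str | Path) -> None:
    """One row per (invader, resident set): mechanism components, mode,
    and the eigenvalue cross-check."""
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_config(path: str | Path) -> dict:
    """Structured run/experiment config, YAML or JSON by extension."""
    import json

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"unrecognised config extension: {path.suffix}")
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return data
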