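"""Reading and writing p-value tables, matrices and simulation configs.

TSV with a header row is the canonical format; CSV is accepted by
delimiter sniffing.  Scientific-notation p-values parse fine.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .simulation import SimulationConfig, expand_grid
from .types import AdjustmentResult, PValueVector

logger = logging.getLogger(__name__)


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs tab vs comma; python engine required for sniffing
    return pd.read_csv(path, sep=None, engine="python")


def read_pvalues(
    path: str | Path,
    id_column: str | None = None,
    p_column: str | None = None,
    drop_na: bool = False,
) -> PValueVector:
    """Read a p-value table into a validated :class:`PValueVector`.

    By default the first column is taken as the identifier and the
    second as the p-value; either can be named explicitly.  Rows with a
    missing p-value raise unless ``drop_na`` is set, in which case they
    are dropped with a logged count.
    """
    df = _read_table(path)
    if df.shape[1] < 2 and (id_column is None or p_column is None):
        raise ValueError(f"{path}: need at least two columns (id, p-value)")
    id_col = id_column if id_column is not None else df.columns[0]
    p_col = p_column if p_column is not None else df.columns[1]
    for col in (id_col, p_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(df.columns)})")

    p = pd.to_numeric(df[p_col], errors="coerce")
    unparseable = p.isna() & df[p_col].notna()
    if unparseable.any():
        row = int(np.flatnonzero(unparseable)[0])
        raise ValueError(
            f"{path}: unparseable p-value at row {row + 2}: {df[p_col].iloc[row]!r}"
        )
    missing = p.isna()
    if missing.any():
        if not drop_na:
            row = int(np.flatnonzero(missing)[0])
            raise ValueError(
                f"{path}: missing p-value at row {row + 2}; pass drop_na to drop"
            )
        logger.warning("%s: dropped %d row(s) with missing p-values", path, missing.sum())
        df, p = df[~missing], p[~missing]

    bad = (p < 0) | (p > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: p-value out of [0, 1] at row {row + 2}: {p.iloc[row]}"
        )
    return PValueVector(df[id_col].astype(str).tolist(), p.to_numpy())


def write_adjustment(
    results: Sequence[AdjustmentResult],
    path: str | Path,
    raw: PValueVector | None = None,
) -> None:
    """Write one row per id: raw p plus (adjusted, rejected) per procedure.

    Column order is deterministic (procedures in the order given);
    values round-trip through :func:`read_pvalues`-style table reads to
    machine precision.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one adjustment result to write")
    ids = results[0].ids
    for res in results[1:]:
        if res.ids != ids:
            raise ValueError("all results must share the same identifiers")
    table: dict[str, object] = {"id": list(ids)}
    if raw is not None:
        if raw.ids != ids:
            raise ValueError("raw p-value ids do not match the results")
        table["pvalue"] = raw.p
    for res in results:
        name = res.procedure.value
        table[f"{name}_adjusted"] = res.adjusted
        table[f"{name}_rejected"] = res.rejected.astype(bool)
    # default float formatting is shortest round-trip repr
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)


def read_matrix(
    path: str | Path, features_in: str = "columns"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a numeric matrix with an index column; returns samples x features.

    ``features_in="rows"`` transposes a features-by-samples table.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if features_in not in ("columns", "rows"):
        raise ValueError("features_in must be 'columns' or 'rows'")
    if features_in == "rows":
        df = df.T
    return df.to_numpy(dtype=float), df.index.astype(str).tolist(), df.columns.astype(str).tolist()


def read_groups(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a two-column (sample, group) table; returns sample ids and labels."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (sample, group)")
    return df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].astype(str).tolist()


def read_sim_configs(path: str | Path, seed: int | None = None) -> list[SimulationConfig]:
    """Load simulation cells from a YAML/JSON config.

    Scalar keys mirror :class:`SimulationConfig`; ``n_per_group``,
    ``rho`` and ``pi1`` may be lists, expanded as a Cartesian grid.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    grid_axes = {
        key: raw.pop(key)
        for key in ("n_per_group", "rho", "pi1")
        if isinstance(raw.get(key), (list, tuple))
    }
    if seed is not None:
        raw["seed"] = seed
    base = SimulationConfig(**raw)
    return expand_grid(base, **grid_axes)
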