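"""CSV/TSV readers for the assay table formats the analyses consume."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .energy_core import RT_DEFAULT
from .factorial import FactorialDesign
from .kinetics import TimeCourse
from .structure import ResidueId

__all__ = [
    "read_factorial_csv",
    "read_timecourse_csv",
    "read_titration_csv",
    "read_suggestions_tsv",
]


def read_factorial_csv(
    path: str | Path,
    factor_cols: Sequence[str],
    rate_col: str = "rate",
    replicate_col: str | None = "replicate",
    rt: float = RT_DEFAULT,
    response_kind: str = "kcat",
) -> FactorialDesign:
    """Long-format factorial table: ±1 factor columns plus a rate column.

    Rates are converted to ΔG = −RT·ln k on read; a precomputed ΔG
    column can be supplied instead by naming it in ``rate_col`` with
    ``rt=None``.
    """
    df = pd.read_csv(path)
    missing = [c for c in list(factor_cols) + [rate_col] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    values = df[rate_col].to_numpy(dtype=float)
    if rt is None:
        responses = values
    else:
        if np.any(values <= 0):
            bad = df.index[values <= 0].tolist()
            raise ValueError(f"non-positive rates at rows {bad} of {path}")
        responses = -rt * np.log(values)
    reps = None
    if replicate_col and replicate_col in df.columns:
        reps = df[replicate_col].to_numpy(dtype=int)
    return FactorialDesign(
        list(factor_cols),
        df[list(factor_cols)].to_numpy(dtype=int),
        responses,
        reps,
        response_kind=response_kind,
    )


def read_timecourse_csv(
    path: str | Path,
    enzyme_total: float,
    active_fraction: float = 1.0,
    time_col: str = "time",
    signal_col: str = "signal",
) -> TimeCourse:
    """Two-column product time course (seconds, product units)."""
    df = pd.read_csv(path)
    return TimeCourse(
        df[time_col].to_numpy(dtype=float),
        df[signal_col].to_numpy(dtype=float),
        enzyme_total=enzyme_total,
        active_fraction=active_fraction,
    )


def read_titration_csv(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """EDTA titration table: edta_total, activity, optional enzyme_conc."""
    df = pd.read_csv(path)
    for col in ("edta_total", "activity"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    enzyme = (
        df["enzyme_conc"].to_numpy(dtype=float)
        if "enzyme_conc" in df.columns
        else None
    )
    return (
        df["edta_total"].to_numpy(dtype=float),
        df["activity"].to_numpy(dtype=float),
        enzyme,
    )


def _parse_residue_id(token: str, default_chain: str = "A") -> ResidueId:
    token = str(token).strip()
    if ":" in token:
        chain, num = token.split(":", 1)
        return (chain, int(num))
    return (default_chain, int(token))


def read_suggestions_tsv(
    path: str | Path, default_chain: str = "A"
) -> list[tuple[ResidueId, str]]:
    """Two-column suggestion list: residue id ("A:33" or "33") and substitution."""
    out: list[tuple[ResidueId, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed suggestion line: {line!r}")
        out.append((_parse_residue_id(parts[0], default_chain), parts[1]))
    return out
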