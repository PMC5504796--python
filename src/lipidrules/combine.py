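"""Cross-software annotation alignment: append annotation columns from one
feature table onto another when features agree in m/z (ppm window, relative
to the base feature) and retention time (minutes).

Best-match semantics: among the other table's rows inside both windows the
smallest absolute ppm error wins, ties by smallest |ΔRT|, then first by row
order.  One other-row may serve several base rows; the base table's rows
and existing cells are never modified, columns are only appended.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem import ppm_error
from .data_io import FeatureTable

__all__ = ["AlignmentParams", "align_and_append"]


@dataclass(frozen=True)
class AlignmentParams:
    ppm_tol: float = 10.0
    rt_tol_min: float = 0.2

    def __post_init__(self):
        if self.ppm_tol <= 0 or self.rt_tol_min <= 0:
            raise ValueError("tolerances must be > 0")


def align_and_append(
    base: FeatureTable,
    other: FeatureTable,
    params: AlignmentParams = AlignmentParams(),
    prefix: str = "other_",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Return a copy of the base table with the other table's annotation
    columns appended for the best-matching feature (empty cells where no
    feature matches).

    ``columns`` selects which of the other table's columns to carry over;
    by default every column except its m/z and RT columns.
    """
    if columns is None:
        columns = [
            c for c in other.df.columns if c not in (other.mz_column, other.rt_column)
        ]
    other_mz = other.df[other.mz_column].astype(float).to_numpy()
    other_rt = other.df[other.rt_column].astype(float).to_numpy()

    out = base.df.copy()
    match_rows: list[int | None] = []
    for _, row in base.df.iterrows():
        bmz = float(row[base.mz_column])
        brt = float(row[base.rt_column])
        best: tuple[float, float, int] | None = None  # (|ppm|, |dRT|, idx)
        for idx in range(len(other_mz)):
            dppm = abs(ppm_error(other_mz[idx], bmz))
            if dppm > params.ppm_tol:
                continue
            drt = abs(other_rt[idx] - brt)
            if drt > params.rt_tol_min:
                continue
            key = (dppm, drt, idx)
            if best is None or key < best:
                best = key
        match_rows.append(best[2] if best else None)

    for col in columns:
        values = [
            other.df.iloc[idx][col] if idx is not None else ""
            for idx in match_rows
        ]
        out[f"{prefix}{col}"] = values
    return out
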