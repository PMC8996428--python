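"""RNA-seq TPM summaries and qRT-PCR relative quantification.

TPM matrices are genes x tissues DataFrames. Homoeologous copies are averaged
into group-level rows; a value below 1 TPM counts as unexpressed (>= 1 is
expressed); heatmap values are log2(TPM + 1).

qPCR tables are long-form records (gene, condition, timepoint, replicate,
ct_target, ct_reference) quantified by the 2^-ddCt method against a
designated control timepoint within each (gene, condition): dCt is the mean
over replicates of Ct_target - Ct_reference, ddCt subtracts the control dCt,
and the relative quantity is 2^-ddCt.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "average_homoeologs",
    "expression_flags",
    "heatmap_values",
    "ddct",
    "fold_category",
]


def average_homoeologs(
    matrix: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Arithmetic mean of member rows per group, column-wise."""
    rows = {}
    for group_id, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {group_id!r} has no members")
        missing = [m for m in members if m not in matrix.index]
        if missing:
            raise KeyError(
                f"group {group_id!r}: members missing from matrix: {missing}"
            )
        rows[group_id] = matrix.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T[matrix.columns]


def expression_flags(
    matrix: pd.DataFrame,
    threshold: float = 1.0,
    column_classes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame | None]:
    """Expressed/unexpressed calls per cell, per row, and per organ class.

    A value >= threshold is expressed (values below 1 TPM are conventionally
    treated as noise). Returns (boolean matrix, per-row any-column flag,
    per-row x organ-class roll-up or None without column metadata).
    """
    flags = matrix >= threshold
    anywhere = flags.any(axis=1)
    by_class = None
    if column_classes is not None:
        classes = pd.Series(
            {c: column_classes[c] for c in matrix.columns}
        )
        by_class = flags.T.groupby(classes).any().T
    return flags, anywhere, by_class


def heatmap_values(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1) transform."""
    return np.log2(matrix + 1.0)


def ddct(
    table: pd.DataFrame,
    control_timepoint: str = "0h",
) -> pd.DataFrame:
    """2^-ddCt relative quantities per (gene, condition, timepoint).

    Expects columns gene, condition, timepoint, replicate, ct_target,
    ct_reference. The control sample is the ``control_timepoint`` row set of
    the same gene and condition; a missing control raises, naming the gene.
    """
    required = {"gene", "condition", "timepoint", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns: {sorted(missing)}")
    work = table.copy()
    work["dct"] = work["ct_target"] - work["ct_reference"]
    mean_dct = (
        work.groupby(["gene", "condition", "timepoint"], sort=False)["dct"]
        .mean()
        .reset_index()
    )
    out_rows = []
    for (gene, condition), sub in mean_dct.groupby(
        ["gene", "condition"], sort=False
    ):
        control = sub[sub["timepoint"] == control_timepoint]
        if control.empty:
            raise ValueError(
                f"gene {gene!r}, condition {condition!r}: no control "
                f"timepoint {control_timepoint!r}"
            )
        base = float(control["dct"].iloc[0])
        for row in sub.itertuples(index=False):
            dd = row.dct - base
            out_rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "timepoint": row.timepoint,
                    "delta_ct": row.dct,
                    "ddct": dd,
                    "rq": 2.0 ** (-dd),
                    "log2_rq": -dd,
                }
            )
    return pd.DataFrame(out_rows)


def fold_category(rq: float, up: float = 15.0) -> str:
    """Coarse fold-change bucket used in stress-response reporting."""
    if rq > up:
        return f">{ up:g}-fold up"
    if rq > 2.0:
        return "up"
    if rq < 0.5:
        return "down"
    return "unchanged"
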