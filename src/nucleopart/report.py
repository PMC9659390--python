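"""Joined report tables across imaging and sequence evidence.

Evidence from N- and C-terminal tagging of the same gene is kept as
separate rows (tagging can disrupt a terminal targeting signal, so the two
termini are independent observations); a protein-level rollup takes
evidence from either terminus.
"""

from __future__ import annotations

from typing import Iterable, Optional, Set

import pandas as pd

from .partition import ClassificationThresholds, LineSummary, classify_localisation


def summaries_to_frame(summaries: Iterable[LineSummary],
                       thresholds: Optional[ClassificationThresholds] = None
                       ) -> pd.DataFrame:
    """LineSummary records as a table, with localisation classes attached."""
    thresholds = thresholds or ClassificationThresholds()
    rows = []
    for s in summaries:
        classes = classify_localisation(s, thresholds)
        rows.append({
            "id": s.line_id,
            "terminus": s.terminus,
            "n_cells": s.n_cells,
            "mean_total_signal": s.mean_total_signal,
            "mean_ratio_nc": s.mean_ratio_nc,
            "mean_ratio_nn": s.mean_ratio_nn,
            "low_confidence": s.low_confidence,
            "classes": ";".join(sorted(classes)),
            "t_nc": thresholds.t_nc,
            "t_nn": thresholds.t_nn,
        })
    return pd.DataFrame(rows)


def build_report(lines: pd.DataFrame,
                 seq_table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Outer-join per-line imaging evidence with per-protein sequence features.

    ``lines`` must carry one row per (id, terminus); duplicates are an
    error. ``seq_table`` is keyed on id alone and is broadcast to both
    termini; ids present in only one table appear with missing values.
    """
    if lines.duplicated(subset=["id", "terminus"]).any():
        dups = lines[lines.duplicated(subset=["id", "terminus"], keep=False)]
        raise ValueError(
            f"duplicate id x terminus rows: {sorted(set(dups['id']))}"
        )
    if seq_table is None or seq_table.empty:
        return lines.copy()
    if seq_table["id"].duplicated().any():
        raise ValueError("duplicate ids in sequence table")
    return lines.merge(seq_table, on="id", how="outer")


def rollup_protein(report: pd.DataFrame) -> pd.DataFrame:
    """Protein-level class rollup: a class applies if either terminus shows it."""
    def union_classes(series) -> str:
        classes: Set[str] = set()
        for v in series.dropna():
            classes.update(v.split(";"))
        return ";".join(sorted(classes))

    grouped = report.groupby("id", dropna=False)
    out = grouped.agg(
        n_termini=("terminus", "nunique"),
        classes=("classes", union_classes),
    ).reset_index()
    return out
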