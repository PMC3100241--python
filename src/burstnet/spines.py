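"""Dendritic-spine maturity and PSD-95 colocalization analysis.

Spines are scored 1-8 by shape; classes 1-5 count as immature and 6-8 as
mature. Proportions are computed per cell (the cell, not the spine, is the
unit of analysis for group means, SEMs and ANOVA). PSD-95 colocalization
proportions use only spines with a non-missing flag; conditions are
compared descriptively for PSD-95 (no test), matching how such data are
usually reported when only a qualitative shift is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netstats import one_way_anova

__all__ = [
    "CellSpineSummary",
    "classify_maturity",
    "cell_proportions",
    "summarize_cells",
    "group_spine_comparison",
    "MATURE_CLASSES",
]

MATURE_CLASSES = frozenset({6, 7, 8})


@dataclass
class CellSpineSummary:
    """Per-cell spine-shape composition."""

    cell_id: object
    n_spines: int
    class_proportions: np.ndarray
    prop_mature: float
    prop_psd95: float  # NaN when no spine has a PSD-95 flag

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != 8 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be 8 values summing to 1")
        self.class_proportions = p


def classify_maturity(shape_class: int) -> str:
    """Shape classes 1-5 are immature, 6-8 mature."""
    if shape_class != int(shape_class) or not 1 <= int(shape_class) <= 8:
        raise ValueError(f"shape_class must be an integer in 1..8, got {shape_class!r}")
    return "mature" if int(shape_class) in MATURE_CLASSES else "immature"


def cell_proportions(records: pd.DataFrame) -> CellSpineSummary:
    """Shape-class, maturity and PSD-95 proportions for one cell's spines."""
    if len(records) == 0:
        raise ValueError("cell has no spines")
    cell_ids = records["cell_id"].unique()
    if len(cell_ids) != 1:
        raise ValueError("records span more than one cell")
    classes = records["shape_class"].to_numpy()
    for c in np.unique(classes):
        classify_maturity(c)  # validates the domain
    counts = np.bincount(classes.astype(int), minlength=9)[1:9]
    props = counts / counts.sum()
    prop_mature = float(props[5:8].sum())
    if "psd95" in records:
        flags = records["psd95"]
        known = flags.notna()
        prop_psd95 = (
            float(flags[known].astype(bool).mean()) if known.any() else float("nan")
        )
    else:
        prop_psd95 = float("nan")
    return CellSpineSummary(
        cell_id=cell_ids[0],
        n_spines=int(len(records)),
        class_proportions=props,
        prop_mature=prop_mature,
        prop_psd95=prop_psd95,
    )


def summarize_cells(df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summary rows (condition, n_spines, per-class props,
    prop_mature, prop_psd95) for a spine-record table."""
    rows = []
    for (cond, cell), sub in df.groupby(["condition", "cell_id"], sort=True):
        s = cell_proportions(sub)
        row = {
            "condition": cond,
            "cell_id": cell,
            "n_spines": s.n_spines,
            "prop_mature": s.prop_mature,
            "prop_psd95": s.prop_psd95,
        }
        for k in range(8):
            row[f"prop_class_{k + 1}"] = s.class_proportions[k]
        rows.append(row)
    return pd.DataFrame(rows)


def group_spine_comparison(df: pd.DataFrame) -> dict:
    """Condition-level spine summary and ANOVA on per-cell mature proportion.

    For each condition: number of cells, mean ± SEM of each class
    proportion and of the mature proportion (over cells), and the mean
    PSD-95 proportion over cells that have flags. The ANOVA compares
    per-cell mature proportions across conditions; PSD-95 is reported as a
    mean difference only.
    """
    cells = summarize_cells(df)
    conditions = sorted(cells["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    report: dict = {"conditions": {}}
    groups, labels = [], []
    for cond in conditions:
        sub = cells[cells["condition"] == cond]
        if len(sub) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 cells")
        mature = sub["prop_mature"].to_numpy(dtype=float)
        psd = sub["prop_psd95"].to_numpy(dtype=float)
        psd = psd[~np.isnan(psd)]
        entry = {
            "n_cells": int(len(sub)),
            "mean_prop_mature": float(mature.mean()),
            "sem_prop_mature": float(np.std(mature, ddof=1) / np.sqrt(len(mature))),
            "mean_prop_psd95": float(psd.mean()) if psd.size else None,
            "n_cells_psd95": int(psd.size),
            "class_means": {},
            "class_sems": {},
        }
        for k in range(8):
            col = sub[f"prop_class_{k + 1}"].to_numpy(dtype=float)
            entry["class_means"][k + 1] = float(col.mean())
            entry["class_sems"][k + 1] = float(
                np.std(col, ddof=1) / np.sqrt(len(col))
            )
        report["conditions"][cond] = entry
        groups.append(mature)
        labels.append(cond)
    report["anova_prop_mature"] = one_way_anova(
        groups, metric="prop_mature", labels=labels
    ).to_dict()
    return report
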