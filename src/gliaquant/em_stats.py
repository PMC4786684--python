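"""Per-process electron-microscopy event statistics.

Events observed in single ultrathin sections (synaptic-cleft contacts,
element contacts, phagocytic inclusions) are normalized by the area of the
microglial process in which they occur, giving events/µm²; large processes
can contact more elements, so raw counts are not comparable.  Densities are
averaged within each animal (tens of processes per animal) and animals are
the unit of replication for group summaries.  A single pass of Grubbs'
outlier test may be applied to the density values: tiny traced processes
inflate the ratio.

Input tables are pandas DataFrames with columns ``animal``, ``group``,
``process``, ``area_um2`` and one column per event category.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ID_COLUMNS",
    "normalize_events",
    "grubbs_critical_value",
    "grubbs_remove_once",
    "summarize_groups",
]

ID_COLUMNS = ["animal", "group", "process", "area_um2"]


def _category_columns(table: pd.DataFrame) -> list[str]:
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
    cats = [c for c in table.columns if c not in ID_COLUMNS]
    if not cats:
        raise ValueError("table has no event-category columns")
    return cats


def normalize_events(table: pd.DataFrame) -> pd.DataFrame:
    """Per-process event densities (events/µm²) for every category.

    Rows with non-positive area are rejected with a logged warning.  Returns
    the table with each category column replaced by count/area.
    """
    cats = _category_columns(table)
    bad = table["area_um2"] <= 0
    if bad.any():
        logger.warning("rejecting %d rows with non-positive process area", int(bad.sum()))
        table = table.loc[~bad]
    densities = table.copy()
    for cat in cats:
        if (table[cat] < 0).any():
            raise ValueError(f"negative counts in category {cat!r}")
        densities[cat] = table[cat] / table["area_um2"]
    return densities


def animal_means(densities: pd.DataFrame) -> pd.DataFrame:
    """Mean density per animal per category (processes averaged within animal)."""
    cats = _category_columns(densities)
    return densities.groupby(["group", "animal"], as_index=False)[cats].mean()


def grubbs_critical_value(n: int, alpha: float, two_sided: bool = True) -> float:
    """Critical value of Grubbs' single-outlier statistic.

    G_crit = ((n−1)/√n) · √(t² / (n−2+t²)) with t the upper α/(2n) (two-sided)
    or α/n (one-sided) quantile of Student's t with n−2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    p = alpha / (2 * n) if two_sided else alpha / n
    t = stats.t.ppf(1 - p, df=n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_remove_once(
    values: np.ndarray | list[float],
    alpha: float = 0.05,
    two_sided: bool = True,
) -> tuple[np.ndarray, float | None]:
    """One (non-iterated) pass of Grubbs' outlier test.

    Computes G = max|xᵢ − mean|/sd (sample sd, ddof=1) and removes the single
    most extreme value iff G exceeds the critical value at ``alpha``.  With a
    tie on |deviation| the first-occurring extreme is removed.  A zero sd
    (all values equal) removes nothing.

    Returns ``(retained values, removed value or None)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return x, None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    if g > grubbs_critical_value(x.size, alpha, two_sided):
        return np.delete(x, idx), float(x[idx])
    return x, None


def summarize_groups(
    table: pd.DataFrame,
    alpha: float | None = 0.05,
    grubbs_two_sided: bool = True,
) -> pd.DataFrame:
    """Group mean ± s.e.m. of event densities, animals as the unit of n.

    The pipeline is: per-process densities → optional single Grubbs pass on
    each category's density values (``alpha=None`` disables) → per-animal
    means → per-group mean and s.e.m. across animals.  Returns a DataFrame
    with columns ``group``, ``category``, ``mean``, ``sem``, ``n_animals``.
    """
    densities = normalize_events(table)
    cats = _category_columns(densities)
    if alpha is not None:
        for cat in cats:
            vals = densities[cat].to_numpy()
            if vals.size >= 3:
                _, removed = grubbs_remove_once(vals, alpha, grubbs_two_sided)
                if removed is not None:
                    # masks only the flagged category for that process; the
                    # process's other categories stay in the analysis
                    drop = densities.index[densities[cat] == removed][:1]
                    logger.info("Grubbs: removed %s=%g (one process)", cat, removed)
                    densities.loc[drop, cat] = np.nan
    per_animal = animal_means(densities)
    rows = []
    for group, sub in per_animal.groupby("group"):
        for cat in cats:
            vals = sub[cat].to_numpy(dtype=float)
            sem = 0.0 if vals.size < 2 else float(vals.std(ddof=1) / np.sqrt(vals.size))
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "mean": float(vals.mean()),
                    "sem": sem,
                    "n_animals": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
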