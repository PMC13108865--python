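"""Cohort aggregation and group comparisons of wave-interval statistics.

Interval length and interval variability are compared between groups with
Welch two-sample t-tests (unequal variances) and the step-down Holm-Sidak
correction across the requested comparison pairs.
"""

from __future__ import annotations

import logging


import numpy as np
import pandas as pd
from scipy import stats as sps

from .kymograph import WaveEventGeometry
from .trace import IntervalSummary

logger = logging.getLogger(__name__)


def aggregate_cohort(
    summaries: dict[str, IntervalSummary],
    geometries: dict[str, list[WaveEventGeometry]] | None = None,
    group_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-animal interval summaries, wave geometry counts, and group
    labels into one cohort table.

    Animals with undefined CV (fewer than three waves) keep their row with
    ``cv = NaN`` rather than being dropped.

    Raises
    ------
    ValueError
        On duplicate animal ids.
    KeyError
        When ``group_map`` lacks an animal id.
    """
    ids = list(summaries)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal_id in summaries")
    geometries = geometries or {}
    rows = []
    for animal_id in ids:
        s = summaries[animal_id]
        geo = [g for g in geometries.get(animal_id, []) if not g.undetermined]
        n_ect = sum(g.ectopic for g in geo)
        frac_prop = float(np.mean([g.propagated for g in geo])) if geo else float("nan")
        if group_map is not None and animal_id not in group_map:
            raise KeyError(f"group_map has no entry for animal {animal_id!r}")
        rows.append(
            {
                "animal_id": animal_id,
                "group": group_map[animal_id] if group_map else "",
                "n_waves": s.n_waves,
                "mean_interval_s": s.mean_interval_s,
                "sd_interval_s": s.sd_interval_s,
                "cv": s.cv,
                "oscillation_absent": s.oscillation_absent,
                "recording_duration_s": s.recording_duration_s,
                "n_ectopic_events": n_ect,
                "fraction_propagated": frac_prop,
            }
        )
    return pd.DataFrame(rows)


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Sidak adjustment.

    Sort ascending; the p-value of rank k (1-based) among m tests becomes
    ``1 - (1 - p)^(m - k + 1)``; enforce monotone non-decrease down the
    sorted list, cap at 1, and restore the original order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def welch_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, Welch-Satterthwaite df, p)."""
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-pair Welch t-tests on a cohort metric with Holm-Sidak correction.

    Animals with an undefined metric (NaN) are excluded per test and
    counted in the report.  Pairs where either group has fewer than two
    defined values are skipped with a warning and do not enter the
    correction family.
    """
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for g1, g2 in pairs:
        x = table.loc[table["group"] == g1, metric].to_numpy(dtype=np.float64)
        y = table.loc[table["group"] == g2, metric].to_numpy(dtype=np.float64)
        n_excluded = int(np.isnan(x).sum() + np.isnan(y).sum())
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            logger.warning(
                "skipping pair (%s, %s): fewer than 2 defined %s values", g1, g2, metric
            )
            continue
        t, df, p = welch_ttest(x, y)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "n1": len(x),
                "n2": len(y),
                "n_excluded": n_excluded,
                "t": t,
                "df": df,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "group1", "group2", "n1", "n2", "n_excluded", "t", "df", "p_raw",
        ],
    )
    out["p_adj"] = holm_sidak_adjust(out["p_raw"].to_numpy()) if len(out) else []
    return out
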