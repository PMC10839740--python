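"""Deviation (z) scores and extreme-deviation group summaries.

A scan's deviation score for one ROI is

    z = (y - pred_mean) / pred_sd

with the predictive mean and SD taken from a fitted (reference or adapted)
normative model.  Because the prediction is batch-specific, z-scores are in
principle free of site and scanner effects and can be compared across
scanners and waves.  Extreme deviations (|z| > 2 by default) are counted
per ROI and group; contrasts between groups (e.g. preterm- vs term-born
children) are reported as percentage-point differences with binomial SEs.
No multiple-testing correction is applied to per-ROI contrasts — these are
descriptive percentages, not hypothesis tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .hbr import NormativeModel

__all__ = [
    "compute_zscores",
    "extreme_deviation_summary",
    "group_contrast",
]

META_COLS = ["row_id", "subject_id", "site", "scanner", "wave", "sex",
             "age", "group"]


def compute_zscores(model: NormativeModel, cohort: pd.DataFrame,
                    predictive: str | None = None) -> pd.DataFrame:
    """Score every cohort row against the model, one z per ROI.

    Returns a deviation table with the scan metadata, per-ROI ``z_<roi>``
    and the predictive ``mu_<roi>`` / ``sd_<roi>`` retained for audit.
    Raises ``UnknownBatchError`` if any row's batch is not in the model.
    """
    keys = model.resolve_batch_keys(cohort)
    out = cohort[[c for c in META_COLS if c in cohort.columns]].copy()
    ages = cohort["age"].to_numpy(dtype=float)
    for roi in model.rois:
        y = cohort[f"roi_{roi}"].to_numpy(dtype=float)
        mean, sd = model.predict_arrays(roi, keys.tolist(), ages,
                                        predictive=predictive)
        out[f"z_{roi}"] = (y - mean) / sd
        out[f"mu_{roi}"] = mean
        out[f"sd_{roi}"] = sd
    return out.reset_index(drop=True)


def extreme_deviation_summary(dev: pd.DataFrame, threshold: float = 2.0,
                              group_col: str = "group") -> pd.DataFrame:
    """Percentage of scans with z beyond +/- ``threshold``, per ROI x group."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    rois = [c[2:] for c in dev.columns if c.startswith("z_")]
    groups = (dev[group_col].dropna().unique().tolist()
              if group_col in dev.columns else ["all"])
    rows = []
    for group in sorted(map(str, groups)):
        sub = dev if group == "all" else dev[dev[group_col] == group]
        n = len(sub)
        for roi in rois:
            if n == 0:
                rows.append({"roi": roi, "group": group, "n": 0,
                             "pct_above": np.nan, "pct_below": np.nan,
                             "threshold": threshold})
                continue
            z = sub[f"z_{roi}"].to_numpy()
            rows.append({
                "roi": roi, "group": group, "n": n,
                "pct_above": 100.0 * np.mean(z > threshold),
                "pct_below": 100.0 * np.mean(z < -threshold),
                "threshold": threshold,
            })
    out = pd.DataFrame(rows)
    empty = out["n"] == 0
    if empty.any():
        warnings.warn(
            f"groups with no scans: "
            f"{sorted(out.loc[empty, 'group'].unique())}", RuntimeWarning,
            stacklevel=2)
    return out


def group_contrast(summary: pd.DataFrame, group_a: str,
                   group_b: str) -> pd.DataFrame:
    """Per-ROI, per-tail percentage differences ``group_a - group_b``.

    Positive differences mean more extreme deviations in ``group_a``.
    SEs are binomial on each group's percentage, combined in quadrature.
    """
    for g in (group_a, group_b):
        if g not in set(summary["group"]):
            raise KeyError(f"group {g!r} absent from summary")
    a = summary[summary["group"] == group_a].set_index("roi")
    b = summary[summary["group"] == group_b].set_index("roi")
    rows = []
    for roi in a.index:
        for tail, col in (("above", "pct_above"), ("below", "pct_below")):
            pa, pb = a.loc[roi, col], b.loc[roi, col]
            na, nb = a.loc[roi, "n"], b.loc[roi, "n"]
            se = np.sqrt(
                (pa * (100 - pa) / na if na else np.nan)
                + (pb * (100 - pb) / nb if nb else np.nan))
            rows.append({"roi": roi, "tail": tail,
                         f"{group_a}_pct": pa, f"{group_b}_pct": pb,
                         "diff": pa - pb, "se": se})
    return pd.DataFrame(rows)
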