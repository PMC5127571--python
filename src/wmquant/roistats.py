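"""ROI aggregation and paired between-region comparisons.

Each parameter map is summarised per region of interest (mean/SD over
in-mask, non-missing voxels, with left/right hemisphere sub-labels
averaged into one value per subject first), and regions are compared by
paired t-tests across subjects.  p-values are deliberately left
uncorrected for multiple comparisons -- the analysis is descriptive.
Significance stars: * p<0.05, ** p<0.01, *** p<0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["aggregate_roi", "paired_t", "summary_table", "REGION_PAIRS"]

#: Between-region comparison columns of the summary table.
REGION_PAIRS = (("frontal_wm", "cst_cs"), ("cst_cs", "cst_plic"))

#: Sentinel |t| reported when the paired differences have zero variance
#: but a non-zero mean (the test statistic diverges).
T_SENTINEL = 1e12


def aggregate_roi(
    param_map: np.ndarray,
    label_mask: np.ndarray,
    label: int | tuple[int, ...],
) -> tuple[float, float, int]:
    """(mean, SD, voxel count) of a map over one ROI label.

    ``label`` may be a tuple of sub-labels (e.g. left/right hemisphere);
    their per-label means are averaged with equal weight, the voxel count
    is the total, and the SD is computed over all pooled voxels.  Missing
    (NaN) voxels are excluded.  An absent label raises ``ValueError``.
    """
    param_map = np.asarray(param_map, float)
    label_mask = np.asarray(label_mask)
    if param_map.shape != label_mask.shape:
        raise ValueError(
            f"map shape {param_map.shape} != label mask shape {label_mask.shape}"
        )
    labels = label if isinstance(label, (tuple, list)) else (label,)
    sub_means, pooled = [], []
    for lab in labels:
        sel = label_mask == lab
        if not sel.any():
            raise ValueError(f"label {lab} not present in mask")
        vals = param_map[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"label {lab} contains only missing values")
        sub_means.append(vals.mean())
        pooled.append(vals)
    pooled = np.concatenate(pooled)
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return float(np.mean(sub_means)), sd, int(pooled.size)


@dataclass(frozen=True)
class PairedTResult:
    t_score: float
    p_value: float
    df: int
    degenerate: bool = False  # zero-variance differences with non-zero mean


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> PairedTResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = a - b.

    n >= 2 pairs required.  Zero-variance differences with a non-zero mean
    produce the capped sentinel t with p = 0 and the degenerate flag set;
    identical inputs give t = 0, p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = a.shape[0]
    if n < 2:
        raise ValueError("at least 2 pairs are required")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedTResult(0.0, 1.0, df)
        return PairedTResult(float(np.sign(d.mean()) * T_SENTINEL), 0.0, df, True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedTResult(t, p, df)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summary_table(
    subject_means: pd.DataFrame,
    region_pairs: tuple[tuple[str, str], ...] = REGION_PAIRS,
) -> pd.DataFrame:
    """Per-region group summary plus paired between-region t-scores.

    ``subject_means`` is long format with columns (subject, parameter,
    region, value): one region mean per subject, the unit of analysis.
    The output has one row per parameter with mean/SD/n per region and a
    t-score/p/stars column per region pair; a parameter missing a region
    of a pair leaves that comparison blank.
    """
    required = {"subject", "parameter", "region", "value"}
    if not required.issubset(subject_means.columns):
        raise ValueError(f"input table needs columns {sorted(required)}")
    if subject_means["subject"].nunique() < 2:
        raise ValueError("at least 2 subjects are required for group statistics")

    rows = []
    for param, sub in subject_means.groupby("parameter", sort=False):
        row: dict[str, object] = {"parameter": param}
        piv = sub.pivot_table(
            index="subject", columns="region", values="value", aggfunc="mean"
        )
        for region in piv.columns:
            vals = piv[region].dropna()
            row[f"{region}_mean"] = float(vals.mean())
            row[f"{region}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{region}_n"] = int(len(vals))
        for ra, rb in region_pairs:
            col = f"t_{ra}_vs_{rb}"
            if ra not in piv.columns or rb not in piv.columns:
                row[col], row[col + "_p"], row[col + "_sig"] = "", "", ""
                continue
            paired = piv[[ra, rb]].dropna()
            if len(paired) < 2:
                row[col], row[col + "_p"], row[col + "_sig"] = "", "", ""
                continue
            res = paired_t(paired[ra].to_numpy(), paired[rb].to_numpy())
            row[col] = res.t_score
            row[col + "_p"] = res.p_value
            row[col + "_sig"] = _stars(res.p_value)
        rows.append(row)
    return pd.DataFrame(rows)
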