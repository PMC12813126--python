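"""Statistical relevance screening of the 12 loop features.

Feature distributions are checked for normality (Shapiro-Wilk); since they
typically fail it, between-group differences (MI vs HC) are tested with the
two-sided Mann-Whitney U test and features are ranked by ascending p-value.
Screening is descriptive only: no feature is ever dropped and outlier
observations are flagged but retained, since extreme morphologies are real
clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FEATURE_NAMES

__all__ = ["ScreenResult", "shapiro_wilk_p", "mann_whitney",
           "screen_features", "boxplot_summary"]

#: Largest n_a * n_b product for which the exact U distribution is enumerated.
EXACT_LIMIT = 400


@dataclass
class ScreenResult:
    """Screening outcome for one feature."""

    feature_name: str
    sw_p: float        # pooled-sample Shapiro-Wilk p (headline column)
    sw_p_mi: float
    sw_p_hc: float
    mw_u: float
    mw_p: float
    rank: int = 0      # 1-based, ascending mw_p


def shapiro_wilk_p(values) -> float:
    """Shapiro-Wilk normality p-value; requires 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(values)}")
    return float(stats.shapiro(values).pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group_a, p).

    The exact null distribution is enumerated when ``n_a * n_b <= 400`` and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie and continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= EXACT_LIMIT and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def screen_features(feature_table: pd.DataFrame, labels=None) -> list[ScreenResult]:
    """Screen every feature column; results ordered by ascending M-W p.

    ``feature_table`` is either the canonical table (with ``record_id`` and
    ``label`` columns) or a bare feature frame plus an explicit ``labels``
    sequence. Ordering ties are broken by feature name; all 12 features are
    always reported.
    """
    if labels is None:
        if "label" not in feature_table.columns:
            raise ValueError("labels must be given or present as a column")
        labels = feature_table["label"]
    labels = np.asarray(labels)
    classes = set(labels)
    if not {"MI", "HC"} <= classes:
        raise ValueError(f"both MI and HC must be present, got {sorted(classes)}")

    results = []
    for name in FEATURE_NAMES:
        col = feature_table[name].to_numpy(dtype=float)
        mi, hc = col[labels == "MI"], col[labels == "HC"]
        u, p = mann_whitney(mi, hc)
        results.append(ScreenResult(
            feature_name=name,
            sw_p=shapiro_wilk_p(col),
            sw_p_mi=shapiro_wilk_p(mi),
            sw_p_hc=shapiro_wilk_p(hc),
            mw_u=u,
            mw_p=p,
        ))
    results.sort(key=lambda r: (r.mw_p, r.feature_name))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Render screening results as a table (one row per feature, by rank)."""
    return pd.DataFrame([{
        "rank": r.rank,
        "feature": r.feature_name,
        "sw_p": r.sw_p,
        "sw_p_mi": r.sw_p_mi,
        "sw_p_hc": r.sw_p_hc,
        "mw_u": r.mw_u,
        "mw_p": r.mw_p,
    } for r in results])


def boxplot_summary(values) -> dict:
    """Five-number summary with Tukey-fence outliers (1.5 IQR).

    Quartiles use linear interpolation (the "type 7" rule). Outliers are
    listed, never removed from any downstream data.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 1:
        raise ValueError("boxplot_summary needs at least one value")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    inliers = values[(values >= lo) & (values <= hi)]
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "whisker_lo": float(inliers.min()),
        "whisker_hi": float(inliers.max()),
        "outliers": outliers.tolist(),
    }
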