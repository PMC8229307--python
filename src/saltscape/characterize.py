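"""Contrast high-high vs low-low cluster members and build radar tables.

Continuous variables are compared with Welch's unequal-variance t-test,
binary ones with Fisher's exact test on the 2x2 class-by-level table; both
two-sided. Multi-level categoricals are expanded into one binary indicator
per level. For plotting, each group summary is z-standardized against the
full cohort (mean and population SD of the variable, or of the level
indicator for categoricals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .autocorr import LisaResult

__all__ = [
    "ClusterComparison",
    "compare_clusters",
    "radar_table",
    "plot_radar",
]

DEFAULT_CONTINUOUS = [
    "age", "energy", "zone_income",
    "supermarket", "grocery", "convenience",
    "na_intake", "k_intake", "na_k_ratio",
]
DEFAULT_CATEGORICAL = [
    "sex", "civil_status", "occupation", "education", "nationality",
]


@dataclass
class ClusterComparison:
    table: pd.DataFrame  # variable, kind, hh, ll, cohort_mean, cohort_sd,
    #                      test, statistic, p_value, hh_std, ll_std, note
    n_hh: int
    n_ll: int
    skipped: list = field(default_factory=list)


def _expand_binary(df: pd.DataFrame, variables) -> dict:
    """Map variable -> (kind, series) with categoricals expanded per level."""
    out = {}
    for v in variables:
        if v not in df.columns:
            continue
        s = df[v]
        if s.dtype.kind in "fiu":
            out[v] = ("continuous", s.astype(float))
        else:
            for lvl in sorted(s.dropna().unique()):
                out[f"{v}_{lvl}"] = ("binary", (s == lvl).astype(float))
    return out


def compare_clusters(
    participants: pd.DataFrame,
    lisa: LisaResult,
    variables=None,
) -> ClusterComparison:
    """HH-vs-LL contrast of socio-demographic and food-environment traits.

    ``participants`` rows must align with the LISA result. Raises if either
    class is empty; zero-variance continuous variables are skipped with a
    recorded reason.
    """
    df = participants.reset_index(drop=True)
    hh_idx = lisa.members("HH")
    ll_idx = lisa.members("LL")
    if len(hh_idx) == 0 or len(ll_idx) == 0:
        raise ValueError(
            f"empty cluster class (HH={len(hh_idx)}, LL={len(ll_idx)})"
        )
    if variables is None:
        variables = [
            v for v in DEFAULT_CONTINUOUS + DEFAULT_CATEGORICAL
            if v in df.columns
        ]

    expanded = _expand_binary(df, variables)
    rows, skipped = [], []
    for name, (kind, s) in expanded.items():
        hh = s.iloc[hh_idx].dropna()
        ll = s.iloc[ll_idx].dropna()
        full = s.dropna()
        mu, sd = full.mean(), full.std(ddof=0)
        if kind == "continuous":
            if hh.var(ddof=0) == 0 and ll.var(ddof=0) == 0:
                skipped.append((name, "zero variance in both groups"))
                continue
            stat, p = stats.ttest_ind(hh, ll, equal_var=False)
            hh_sum, ll_sum = hh.mean(), ll.mean()
            test = "welch_t"
        else:
            tab = np.array(
                [
                    [hh.sum(), len(hh) - hh.sum()],
                    [ll.sum(), len(ll) - ll.sum()],
                ]
            ).astype(int)
            stat, p = stats.fisher_exact(tab, alternative="two-sided")
            hh_sum, ll_sum = hh.mean(), ll.mean()  # proportions
            test = "fisher_exact"
        rows.append(
            {
                "variable": name,
                "kind": kind,
                "hh": hh_sum,
                "ll": ll_sum,
                "cohort_mean": mu,
                "cohort_sd": sd,
                "test": test,
                "statistic": float(stat),
                "p_value": float(p),
                "hh_std": (hh_sum - mu) / sd if sd > 0 else 0.0,
                "ll_std": (ll_sum - mu) / sd if sd > 0 else 0.0,
            }
        )
    return ClusterComparison(
        table=pd.DataFrame(rows),
        n_hh=len(hh_idx),
        n_ll=len(ll_idx),
        skipped=skipped,
    )


def radar_table(comparison: ClusterComparison) -> pd.DataFrame:
    """Radar-plot-ready table: one row per variable, standardized group
    summaries, significance stars at p < 0.05."""
    t = comparison.table
    return pd.DataFrame(
        {
            "variable": t["variable"],
            "hh_std": t["hh_std"],
            "ll_std": t["ll_std"],
            "p_value": t["p_value"],
            "significant": np.where(t["p_value"] < 0.05, "*", ""),
        }
    )


def plot_radar(comparison: ClusterComparison, path) -> None:
    """Convenience radar figure; the CSV table is the values-first contract."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = radar_table(comparison)
    labels = [
        f"{v}{s}" for v, s in zip(t["variable"], t["significant"])
    ]
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(8, 8))
    for col, label in (("hh_std", "high-high"), ("ll_std", "low-low")):
        vals = t[col].to_numpy()
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=label)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.legend(loc="upper right")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
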