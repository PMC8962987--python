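"""Rank-based statistical comparison of labeling strategies.

Per-subject means per strategy feed a Kruskal-Wallis test across strategies;
significant measures are followed up with pairwise Wilcoxon signed-rank tests
(the design is within-subject) under Bonferroni correction, with Rosenthal's
effect size r = |Z| / sqrt(N).  Time-based measures use only successfully
finished trials.  A simple screen flags values more than twice their group
mean as outliers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TIME_MEASURES",
    "MEASURES",
    "MethodComparison",
    "subject_means",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
    "effect_size_r",
    "screen_outliers",
    "compare_methods",
]

#: measures computed only over successfully finished trials
TIME_MEASURES = ("completion_time", "gross_motion_time", "fine_motion_time")

MEASURES = TIME_MEASURES + ("path_efficiency", "avg_speed", "max_speed",
                            "tt_avg_distance", "tt_avg_speed")


@dataclass
class MethodComparison:
    measure: str
    subject_means: pd.DataFrame        # subjects x methods
    kw_h: float = np.nan
    kw_p: float = np.nan
    pairwise: pd.DataFrame | None = None
    outliers: pd.DataFrame | None = None


def subject_means(trials: pd.DataFrame,
                  measures=MEASURES) -> pd.DataFrame:
    """Mean per (subject, strategy) and measure; failures excluded from the
    time measures.  Returns a tidy frame (subject, strategy, measure, value);
    cells without any valid trial are absent.
    """
    if trials.empty:
        raise ValueError("empty trials table")
    out = []
    for measure in measures:
        if measure not in trials.columns:
            continue
        df = trials
        if measure in TIME_MEASURES and "success" in trials.columns:
            df = trials[trials["success"].astype(bool)]
        grp = (df.dropna(subset=[measure])
                 .groupby(["subject", "strategy"])[measure].mean())
        for (subj, strat), val in grp.items():
            out.append({"subject": subj, "strategy": strat,
                        "measure": measure, "value": val})
    return pd.DataFrame(out)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups.

    All-identical data degenerates to (0, 1) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need >= 3 total observations")
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank p and approximate Z for one paired comparison.

    Zero differences are dropped before ranking; an all-zero difference
    vector yields (p=1, Z=0).
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        raise ValueError("need >= 2 complete pairs")
    if np.all(d == 0):
        return 1.0, 0.0
    res = sps.wilcoxon(d, zero_method="wilcox", method="approx",
                       correction=False)
    return float(res.pvalue), float(res.zstatistic)


def pairwise_wilcoxon_bonferroni(wide: pd.DataFrame,
                                 methods=None) -> pd.DataFrame:
    """All pairwise signed-rank tests between method columns, paired by
    subject (rows), with Bonferroni-corrected p and effect size r.

    ``wide`` is a subjects x methods table of per-subject means.
    """
    methods = list(wide.columns) if methods is None else list(methods)
    pairs = list(itertools.combinations(methods, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        sub = wide[[a, b]].dropna()
        p_raw, z = _signed_rank(sub[a].to_numpy(), sub[b].to_numpy())
        n_obs = 2 * len(sub)
        rows.append({
            "method_a": a, "method_b": b, "n_pairs": len(sub),
            "z": z, "p_raw": p_raw,
            "p_corrected": min(1.0, p_raw * n_comp),
            "effect_size_r": effect_size_r(z, n_obs),
        })
    return pd.DataFrame(rows)


def effect_size_r(z: float, n: int) -> float:
    """Rosenthal's effect size r = |Z| / sqrt(N) for N total observations."""
    if n < 1:
        raise ValueError("N must be >= 1")
    return float(abs(z) / np.sqrt(n))


def screen_outliers(values) -> np.ndarray:
    """Flag values more than twice the (inclusive) mean of their group."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    return v > 2.0 * np.nanmean(v)


def compare_methods(trials: pd.DataFrame, measure: str,
                    drop_outliers: bool = True) -> MethodComparison:
    """Full comparison of one performance measure across strategies."""
    means = subject_means(trials, measures=(measure,))
    if means.empty:
        raise ValueError(f"no data for measure {measure!r}")
    wide = means.pivot(index="subject", columns="strategy", values="value")

    flags = []
    for method in wide.columns:
        col = wide[method].dropna()
        if len(col) >= 2:
            mask = screen_outliers(col.to_numpy())
            for subj, bad in zip(col.index, mask):
                if bad:
                    flags.append({"strategy": method, "subject": subj,
                                  "value": col.loc[subj]})
                    if drop_outliers:
                        wide.loc[subj, method] = np.nan
    outliers = pd.DataFrame(flags)

    groups = [wide[m].dropna().to_numpy() for m in wide.columns]
    groups = [g for g in groups if len(g) > 0]
    h, p = kruskal_wallis(groups) if len(groups) >= 2 else (np.nan, np.nan)
    pairwise = pairwise_wilcoxon_bonferroni(wide)
    return MethodComparison(measure=measure, subject_means=wide,
                            kw_h=h, kw_p=p, pairwise=pairwise,
                            outliers=outliers)
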