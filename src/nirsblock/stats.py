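"""Channel-wise group inference over phase summaries.

Activation per (condition, phase) is tested channel-by-channel with a
one-sample, one-sided t-test of the subject phase means against zero
(alternative: mean > 0, i.e. an HbO increase), corrected across the
16-channel family with the Benjamini-Hochberg step-up procedure at
q = 0.05.  Differences between the four conditions are assessed per
channel with a one-way repeated-measures ANOVA followed by paired t-tests
for the six condition pairs, Bonferroni-corrected within channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "StatsConfig",
    "bh_fdr",
    "activation_test",
    "condition_comparison",
    "group_summary",
]


@dataclass(frozen=True)
class StatsConfig:
    fdr_q: float = 0.05
    alpha: float = 0.05
    activation_alternative: str = "greater"
    pairwise_correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr_q and alpha must lie in (0, 1)")
        if self.activation_alternative != "greater":
            raise ValueError("only the 'greater' alternative is supported")
        if self.pairwise_correction != "bonferroni":
            raise ValueError("only Bonferroni pairwise correction is supported")


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and reject flags.

    Adjusted p_(i) = min_{j >= i} m * p_(j) / j (capped at 1).  Rejection
    uses the equivalent step-up form directly -- reject the k* smallest
    p-values where k* is the largest k with p_(k) <= k q / m -- which
    avoids float round-off at exact threshold ties in the division-based
    adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    ranked = p[order] * m / ranks
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted

    passed = np.where(p[order] <= ranks * q / m)[0]
    reject = np.zeros(m, dtype=bool)
    if passed.size:
        reject[order[: passed[-1] + 1]] = True
    return adjusted, reject


def _one_sided_t(values: np.ndarray) -> tuple[float, float, float, float, int]:
    """(mean, sd, t, one-sided p) of values vs 0; sd is sample SD."""
    v = values[~np.isnan(values)]
    n = v.size
    mean = float(v.mean()) if n else np.nan
    if n > 1 and np.ptp(v) == 0:
        return mean, 0.0, np.nan, np.nan, n
    sd = float(v.std(ddof=1)) if n > 1 else np.nan
    if n < 2 or sd == 0:
        return mean, sd, np.nan, np.nan, n
    t = mean / (sd / np.sqrt(n))
    p = float(sp_stats.t.sf(t, df=n - 1))
    return mean, sd, float(t), p, n


def activation_test(
    summary: pd.DataFrame,
    condition: str,
    phase: str,
    config: StatsConfig = StatsConfig(),
) -> pd.DataFrame:
    """One-sided activation test per channel, BH-FDR over the channel family.

    ``summary`` is the long-format phase table (columns subject, condition,
    channel_id, phase, value).  Channels whose subject values are all
    missing get a missing row; zero-variance channels are error-flagged
    rather than assigned an infinite t.  The BH family is the set of
    channels with a valid p within this (condition, phase).
    """
    sub = summary[(summary["condition"] == condition) & (summary["phase"] == phase)]
    if sub.empty:
        raise ValueError(f"no rows for condition={condition!r}, phase={phase!r}")
    rows = []
    for cid, grp in sub.groupby("channel_id"):
        mean, sd, t, p, n = _one_sided_t(grp["value"].to_numpy())
        note = ""
        if n == 0:
            note = "all-missing"
        elif n < 2:
            note = "n<2"
        elif sd == 0:
            note = "zero-variance"
        rows.append(
            {
                "channel_id": cid,
                "condition": condition,
                "phase": phase,
                "n": n,
                "mean": mean,
                "sd": sd,
                "t": t,
                "p_raw": p,
                "note": note,
            }
        )
    out = pd.DataFrame(rows).sort_values("channel_id").reset_index(drop=True)
    valid = out["p_raw"].notna().to_numpy()
    p_adj = np.full(len(out), np.nan)
    signif = np.zeros(len(out), dtype=bool)
    if valid.any():
        adj, rej = bh_fdr(out.loc[valid, "p_raw"].to_numpy(), config.fdr_q)
        p_adj[valid] = adj
        signif[valid] = rej
    out["p_adj"] = p_adj
    out["significant"] = signif
    return out


def _pivot_complete(summary: pd.DataFrame, phase: str, channel_id: int) -> pd.DataFrame:
    sub = summary[(summary["phase"] == phase) & (summary["channel_id"] == channel_id)]
    wide = sub.pivot(index="subject", columns="condition", values="value")
    return wide.dropna(axis=0, how="any")


def condition_comparison(
    summary: pd.DataFrame,
    phase: str,
    config: StatsConfig = StatsConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel omnibus RM-ANOVA plus Bonferroni-corrected paired tests.

    Subjects must have complete data across the conditions for a channel to
    enter (listwise deletion within channel).  Returns (omnibus, pairwise)
    tables; pairwise p-values are Bonferroni-multiplied by the number of
    condition pairs within the channel.
    """
    from statsmodels.stats.anova import AnovaRM

    conditions = sorted(summary["condition"].unique())
    pairs = list(combinations(conditions, 2))
    omni_rows, pair_rows = [], []
    for cid in sorted(summary["channel_id"].unique()):
        wide = _pivot_complete(summary, phase, cid)
        n = len(wide)
        if n < 3:
            omni_rows.append(
                {"channel_id": cid, "phase": phase, "n": n, "F": np.nan, "p": np.nan, "note": "n<3"}
            )
            continue
        if np.ptp(wide.to_numpy() - wide.to_numpy().mean(axis=1, keepdims=True)) == 0:
            # no within-subject condition effect at all: F is 0 by definition
            f_val, p_val = 0.0, 1.0
        else:
            long = wide.reset_index().melt(id_vars="subject", var_name="condition", value_name="value")
            res = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
            f_val = float(res.anova_table["F Value"].iloc[0])
            p_val = float(res.anova_table["Pr > F"].iloc[0])
        omni_rows.append({"channel_id": cid, "phase": phase, "n": n, "F": f_val, "p": p_val, "note": ""})

        for a, b in pairs:
            diff = wide[a].to_numpy() - wide[b].to_numpy()
            if np.allclose(diff.std(ddof=1), 0.0):
                t = 0.0 if np.allclose(diff.mean(), 0.0) else np.nan
                p = 1.0 if t == 0.0 else np.nan
            else:
                t, p = sp_stats.ttest_rel(wide[a], wide[b])
                t, p = float(t), float(p)
            p_adj = min(p * len(pairs), 1.0) if not np.isnan(p) else np.nan
            pair_rows.append(
                {
                    "channel_id": cid,
                    "condition_a": a,
                    "condition_b": b,
                    "phase": phase,
                    "n": n,
                    "mean_diff": float(np.nanmean(diff)),
                    "t": t,
                    "p_raw": p,
                    "p_adj": p_adj,
                    "significant": bool(p_adj < config.alpha) if not np.isnan(p_adj) else False,
                }
            )
    return pd.DataFrame(omni_rows), pd.DataFrame(pair_rows)


def group_summary(
    summary: pd.DataFrame,
    activation: pd.DataFrame | None = None,
    phase: str = "early",
) -> pd.DataFrame:
    """Across-subject mean +/- SD per channel x condition (sample SD).

    Mirrors the conventional group table: one row per channel, one column
    pair per condition, with activation-significance flags merged in when
    an activation-test table is supplied.
    """
    sub = summary[summary["phase"] == phase]
    rows = []
    conditions = sorted(sub["condition"].unique())
    for cid in sorted(sub["channel_id"].unique()):
        row: dict = {"channel_id": cid}
        for cond in conditions:
            vals = sub[(sub["channel_id"] == cid) & (sub["condition"] == cond)]["value"].dropna()
            row[f"{cond}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{cond}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            row[f"{cond}_n"] = int(len(vals))
            if activation is not None:
                hit = activation[
                    (activation["channel_id"] == cid)
                    & (activation["condition"] == cond)
                    & (activation["phase"] == phase)
                ]
                row[f"{cond}_significant"] = bool(hit["significant"].iloc[0]) if len(hit) else False
        rows.append(row)
    return pd.DataFrame(rows)
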