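"""Nonparametric differential abundance with multiple-testing control.

Per feature (OTU or phylotype): a Kruskal-Wallis omnibus test across
exposure groups, Storey q-values across all features tested together,
post-hoc pairwise Mann-Whitney U tests with Holm correction for features
passing the significance gate (q < 0.2 and p < 0.05), pseudocount fold
changes, and a susceptibility rubric that labels each feature as
susceptible (persistent or resilient), resistant (bloom or stable) or
unclassified based on the direction and timing of its response.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import OtuTable

__all__ = [
    "kruskal_wallis",
    "mann_whitney",
    "holm_adjust",
    "storey_qvalues",
    "fold_change",
    "test_features",
    "classify_response",
    "GroupComparison",
    "compare_group_values",
]

CALLS = (
    "susceptible_persistent",
    "susceptible_resilient",
    "resistant_bloom",
    "resistant_stable",
    "unclassified",
)


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    A degenerate input where every observation is identical returns
    (H=0, p=1) instead of failing on the tie correction.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample) and p-value.

    scipy chooses the exact null when both samples are small and untied,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def storey_qvalues(pvals: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoothed pi0 estimation.

    pi0 (the null proportion) is estimated on a lambda grid 0.05..0.95 with
    a cubic smoother evaluated at the largest lambda, as in the standard
    q-value procedure. For fewer than 100 tests the smoother is unstable,
    so pi0 falls back to 1 and the q-values reduce to Benjamini-Hochberg.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
            coeffs = np.polyfit(lam, pi0_lam, 3)
            pi0 = float(np.polyval(coeffs, lam.max()))
            pi0 = min(pi0, 1.0)
            if pi0 <= 0:
                pi0 = 1.0 / m  # pathological: essentially everything non-null
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")

    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(ranked, 0.0, 1.0)
    return q


def fold_change(
    table: OtuTable,
    feature: str,
    experimental_group: str,
    normalizing_group: str,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-sample fold change of a feature vs a normalizing group's mean.

    The pseudocount is added to every observation first, so all-zero
    features yield a fold change of exactly 1 and means of zero cannot
    produce spurious ratios.
    """
    counts = table.counts[feature].astype(float) + pseudocount
    groups = table.groups
    exp = counts[groups == experimental_group]
    norm = counts[groups == normalizing_group]
    if exp.empty or norm.empty:
        raise ValueError("both groups must contain samples")
    denom = norm.mean()
    records = pd.DataFrame(
        {
            "feature": feature,
            "sample_id": exp.index,
            "experimental_group": experimental_group,
            "normalizing_group": normalizing_group,
            "fold_change": (exp / denom).to_numpy(),
        }
    )
    return records.reset_index(drop=True)


def _direction(exp_vals: np.ndarray, ref_vals: np.ndarray) -> str:
    """'increase'/'decrease'/'none', judged on medians with a mean tiebreak."""
    d = np.median(exp_vals) - np.median(ref_vals)
    if d == 0:
        d = exp_vals.mean() - ref_vals.mean()
    if d > 0:
        return "increase"
    if d < 0:
        return "decrease"
    return "none"


def test_features(
    table: OtuTable,
    reference_group: str = "unexposed",
    p_gate: float = 0.05,
    q_gate: float = 0.2,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Run the full differential-abundance battery over every feature.

    Returns one row per feature with the omnibus H/p/q, Holm-adjusted
    pairwise Mann-Whitney p-values and directions for every group pair,
    median fold changes for the contrasts against ``reference_group``, the
    overall mean abundance and the susceptibility call.
    """
    groups = table.groups
    labels = list(pd.unique(groups))
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not in metadata")
    pairs = list(combinations(labels, 2))
    counts = table.counts

    rows = []
    for feature in table.otu_ids:
        vals = counts[feature].to_numpy(dtype=float)
        h, p = kruskal_wallis(vals, groups.to_numpy())
        row: dict = {
            "feature": feature,
            "H": h,
            "p": p,
            "mean_abundance": float(vals.mean()),
        }
        by_group = {g: vals[(groups == g).to_numpy()] for g in labels}
        raw_ps = []
        for a, b in pairs:
            _, mw_p = mann_whitney(by_group[a], by_group[b])
            raw_ps.append(mw_p)
        holm_ps = holm_adjust(raw_ps)
        for (a, b), hp in zip(pairs, holm_ps):
            key = _pair_key(a, b, reference_group)
            row[f"mw_holm_p[{key}]"] = float(hp)
            if reference_group in (a, b):
                exp = b if a == reference_group else a
                row[f"direction[{key}]"] = _direction(by_group[exp], by_group[reference_group])
            else:
                row[f"direction[{key}]"] = _direction(by_group[a], by_group[b])
        rows.append(row)

    results = pd.DataFrame(rows).set_index("feature")
    results["q"] = storey_qvalues(results["p"].to_numpy())
    results["gate_passed"] = (results["q"] < q_gate) & (results["p"] < p_gate)

    # median fold change per vs-reference contrast, only where gate passed
    for g in labels:
        if g == reference_group:
            continue
        col = f"median_fc[{g}_vs_{reference_group}]"
        fcs = []
        for feature in results.index:
            if results.loc[feature, "gate_passed"]:
                rec = fold_change(table, feature, g, reference_group, pseudocount)
                fcs.append(float(rec["fold_change"].median()))
            else:
                fcs.append(np.nan)
        results[col] = fcs

    results["call"] = classify_response(
        results, reference_group=reference_group, exposed_groups=[g for g in labels if g != reference_group]
    )
    return results


def _pair_key(a: str, b: str, reference: str) -> str:
    if b == reference:
        return f"{a}_vs_{b}"
    if a == reference:
        return f"{b}_vs_{a}"
    return f"{a}_vs_{b}"


def classify_response(
    results: pd.DataFrame,
    reference_group: str = "unexposed",
    exposed_groups: Sequence[str] = ("four_day", "seven_day"),
    p_gate: float = 0.05,
    alpha_pairwise: float = 0.05,
    stable_min_mean: float = 100.0,
) -> pd.Series:
    """Label each feature with a triclosan-susceptibility archetype.

    - susceptible_persistent: significant decrease vs the reference in both
      the early and late exposure contrasts;
    - susceptible_resilient: significant decrease only in the late contrast;
    - resistant_bloom: significant increase vs the reference in either
      exposure contrast;
    - resistant_stable: omnibus p > 0.05 and mean abundance above
      ``stable_min_mean`` counts;
    - unclassified otherwise.

    Pairwise significance is only consulted for features passing the
    omnibus gate (``gate_passed`` column), matching the post-hoc design.
    """
    if len(exposed_groups) != 2:
        raise ValueError("the rubric expects exactly two exposure groups (early, late)")
    early, late = exposed_groups

    def sig_dir(row: pd.Series, group: str) -> str | None:
        key = f"{group}_vs_{reference_group}"
        if row[f"mw_holm_p[{key}]"] <= alpha_pairwise:
            return row[f"direction[{key}]"]
        return None

    calls = []
    for _, row in results.iterrows():
        call = "unclassified"
        if row["gate_passed"]:
            d_early = sig_dir(row, early)
            d_late = sig_dir(row, late)
            if d_early == "decrease" and d_late == "decrease":
                call = "susceptible_persistent"
            elif d_late == "decrease" and d_early is None:
                call = "susceptible_resilient"
            elif d_early == "increase" or d_late == "increase":
                call = "resistant_bloom"
        elif row["p"] > p_gate and row["mean_abundance"] > stable_min_mean:
            call = "resistant_stable"
        calls.append(call)
    return pd.Series(calls, index=results.index, name="call")


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus Holm-corrected pairwise Mann-Whitney."""

    H: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, U, p_raw, p_holm


def compare_group_values(values: Sequence[float], groups: Sequence[str]) -> GroupComparison:
    """Compare one numeric variable (e.g. Shannon entropy) across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    h, p = kruskal_wallis(values, groups)
    labels = list(pd.unique(groups))
    rows = []
    for a, b in combinations(labels, 2):
        u, mw_p = mann_whitney(values[groups == a], values[groups == b])
        rows.append({"group_a": a, "group_b": b, "U": u, "p_raw": mw_p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    return GroupComparison(H=h, p=p, pairwise=pairwise)
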