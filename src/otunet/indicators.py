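"""Dufrene-Legendre indicator value (IndVal) analysis.

For OTU i and sample class j, specificity A_ij is the class-j mean
abundance as a fraction of the summed class means, fidelity B_ij is the
fraction of class-j samples where the OTU occurs, and IV_ij = A_ij * B_ij.
An OTU's indicator class is the argmax over classes; significance comes
from permuting class labels over samples and comparing the permuted max-IV
to the observed one. The exposure analysis pools the four- and seven-day
groups into one "exposed" class against "unexposed" by default.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import storey_qvalues
from .tables_io import OtuTable

__all__ = [
    "EXPOSED_POOLING",
    "pool_classes",
    "indval",
    "indval_significance",
    "select_indicators",
    "indicator_analysis",
]

#: Default pooling of exposure groups into indicator classes.
EXPOSED_POOLING: Mapping[str, str] = {
    "unexposed": "unexposed",
    "four_day": "exposed",
    "seven_day": "exposed",
}


def pool_classes(
    groups: pd.Series, pooling: Mapping[str, str] | None = EXPOSED_POOLING
) -> pd.Series:
    """Map group labels to indicator classes (identity if pooling is None)."""
    if pooling is None:
        return groups
    unmapped = set(groups.unique()) - set(pooling)
    if unmapped:
        raise ValueError(f"groups without a class mapping: {sorted(unmapped)}")
    return groups.map(pooling)


def _class_matrices(classes: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = list(pd.unique(np.asarray(classes)))
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    onehot = np.array([[c == lab for c in classes] for lab in labels], dtype=float)
    sizes = onehot.sum(axis=1)
    if (sizes == 0).any():
        raise ValueError("every class must be non-empty")
    return onehot, sizes, labels


def _indval_components(
    counts: np.ndarray, onehot: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(A, B, IV), each classes x OTUs."""
    means = (onehot @ counts) / sizes[:, None]
    mean_sums = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(mean_sums > 0, means / np.where(mean_sums > 0, mean_sums, 1.0), 0.0)
    b = (onehot @ (counts > 0)) / sizes[:, None]
    return a, b, a * b


def indval(table: OtuTable, classes: pd.Series | Sequence[str]) -> pd.DataFrame:
    """Indicator values for every OTU x class.

    Returns one row per OTU with the argmax class and its IV, A and B,
    the per-class IVs, and the indicator class's relative abundance and
    occurrence frequency (used to scale dot plots). An OTU absent
    everywhere gets IV = 0 in every class.
    """
    if isinstance(classes, pd.Series):
        classes = classes.loc[table.sample_ids].to_numpy()
    onehot, sizes, labels = _class_matrices(list(classes))
    counts = table.counts.to_numpy(dtype=float)
    a, b, iv = _indval_components(counts, onehot, sizes)

    best = iv.argmax(axis=0)
    otus = table.otu_ids
    rel = table.relative_abundance().to_numpy()
    class_rel = (onehot @ rel) / sizes[:, None]  # mean relative abundance per class

    rows = []
    for i, otu in enumerate(otus):
        j = best[i]
        row = {
            "otu_id": otu,
            "class": labels[j],
            "IV": iv[j, i],
            "A": a[j, i],
            "B": b[j, i],
            "class_relative_abundance": class_rel[j, i],
            "class_frequency": b[j, i],
        }
        for jj, lab in enumerate(labels):
            row[f"IV[{lab}]"] = iv[jj, i]
        rows.append(row)
    return pd.DataFrame(rows).set_index("otu_id")


def indval_significance(
    table: OtuTable,
    classes: pd.Series | Sequence[str],
    nperm: int = 999,
    seed: int | None = None,
) -> pd.Series:
    """Permutation p-values for each OTU's max-class IV.

    p = (1 + #{permuted max-IV >= observed}) / (nperm + 1), permuting
    class labels over samples.
    """
    if nperm < 999:
        raise ValueError("use at least 999 permutations")
    if isinstance(classes, pd.Series):
        classes = classes.loc[table.sample_ids].to_numpy()
    classes = np.asarray(classes)
    onehot, sizes, _ = _class_matrices(list(classes))
    counts = table.counts.to_numpy(dtype=float)
    presence = (counts > 0).astype(float)

    _, _, iv = _indval_components(counts, onehot, sizes)
    obs = iv.max(axis=0)

    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    exceed = np.zeros(counts.shape[1], dtype=np.int64)
    for _ in range(nperm):
        perm = rng.permutation(n)
        oh = onehot[:, perm]
        means = (oh @ counts) / sizes[:, None]
        mean_sums = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(mean_sums > 0, means / np.where(mean_sums > 0, mean_sums, 1.0), 0.0)
        b = (oh @ presence) / sizes[:, None]
        exceed += ((a * b).max(axis=0) >= obs - 1e-12)
    p = (1 + exceed) / (1 + nperm)
    return pd.Series(p, index=table.otu_ids, name="p")


def select_indicators(
    results: pd.DataFrame,
    iv_min: float = 0.4,
    p_max: float = 0.05,
    q_max: float = 0.2,
) -> pd.DataFrame:
    """Drop poor indicators: keep IV >= 0.4, p <= 0.05 and q <= 0.2."""
    for col in ("IV", "p", "q"):
        if col not in results.columns:
            raise ValueError(f"results must carry a {col!r} column")
    keep = (results["IV"] >= iv_min) & (results["p"] <= p_max) & (results["q"] <= q_max)
    return results[keep].copy()


def indicator_analysis(
    table: OtuTable,
    pooling: Mapping[str, str] | None = EXPOSED_POOLING,
    nperm: int = 999,
    seed: int | None = None,
    iv_min: float = 0.4,
    p_max: float = 0.05,
    q_max: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full indicator workflow: IndVal, permutation p, q, selection.

    Returns (all results, selected indicators).
    """
    classes = pool_classes(table.groups, pooling)
    results = indval(table, classes)
    results["p"] = indval_significance(table, classes, nperm=nperm, seed=seed)
    results["q"] = storey_qvalues(results["p"].to_numpy())
    return results, select_indicators(results, iv_min=iv_min, p_max=p_max, q_max=q_max)
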