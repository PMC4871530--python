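"""Rarefaction and the low-abundance / low-prevalence OTU filter.

The filter mirrors common practice for rarefied 16S tables: drop OTUs whose
maximum per-sample relative abundance never reaches 0.1% of the community,
and OTUs detected in fewer than ~10% of samples. Both cuts are applied as a
single AND filter, and a removal log records why each OTU fell out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import OtuTable

__all__ = ["FilterSpec", "rarefy_counts", "filter_otus"]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for :func:`filter_otus`.

    max_rel_abund_threshold
        Keep an OTU only if its relative abundance reaches this fraction in
        at least one sample (default 0.001, i.e. 0.1%).
    min_prevalence
        Keep an OTU only if it is non-zero in at least
        ``ceil(min_prevalence * n_samples)`` samples (default 0.10).
    min_prevalence_count
        Optional explicit sample count overriding the ceil rule.
    """

    max_rel_abund_threshold: float = 0.001
    min_prevalence: float = 0.10
    min_prevalence_count: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.max_rel_abund_threshold < 1:
            raise ValueError("max_rel_abund_threshold must be in (0, 1)")
        if not 0 < self.min_prevalence < 1:
            raise ValueError("min_prevalence must be in (0, 1)")

    def prevalence_count(self, n_samples: int) -> int:
        if self.min_prevalence_count is not None:
            return self.min_prevalence_count
        return math.ceil(self.min_prevalence * n_samples)


def rarefy_counts(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample every sample to ``depth`` counts, uniformly without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.
    Each retained sample's counts follow the multivariate hypergeometric
    distribution, i.e. an exact uniform subsample of its reads.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    rng = np.random.default_rng(seed)

    totals = table.sample_totals()
    shallow = totals.index[totals < depth]
    if len(shallow) > 0:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: "
            f"{list(shallow)}",
            stacklevel=2,
        )
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    if not keep:
        raise ValueError(f"no sample has at least {depth} counts")

    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts.to_numpy())
    for i, row in enumerate(sub.counts.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=sub.counts.index, columns=sub.counts.columns)
    return OtuTable(counts, sub.sample_meta)


def filter_otus(
    table: OtuTable, spec: FilterSpec = FilterSpec()
) -> tuple[OtuTable, pd.DataFrame]:
    """Apply the abundance AND prevalence filter.

    Returns the filtered table and a removal log
    (otu_id, reason, max_rel_abund, prevalence). Raises if every OTU would
    be removed, which usually means the thresholds are inappropriate for
    the table at hand.
    """
    if table.n_otus == 0 or table.n_samples == 0:
        raise ValueError("cannot filter an empty table")

    rel = table.relative_abundance()
    max_rel = rel.max(axis=0)
    prevalence = (table.counts > 0).sum(axis=0)
    min_prev = spec.prevalence_count(table.n_samples)

    abund_ok = max_rel >= spec.max_rel_abund_threshold
    prev_ok = prevalence >= min_prev
    keep = abund_ok & prev_ok

    removed = []
    for otu in table.otu_ids:
        if keep[otu]:
            continue
        reason = "abundance" if not abund_ok[otu] else "prevalence"
        removed.append(
            {
                "otu_id": otu,
                "reason": reason,
                "max_rel_abund": float(max_rel[otu]),
                "prevalence": int(prevalence[otu]),
            }
        )
    log = pd.DataFrame(removed, columns=["otu_id", "reason", "max_rel_abund", "prevalence"])

    kept_ids = [o for o in table.otu_ids if keep[o]]
    if not kept_ids:
        raise ValueError(
            "all OTUs removed by the abundance/prevalence filter; "
            "review FilterSpec thresholds"
        )
    return table.select_otus(kept_ids), log
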