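"""ASV-level filters and rank-level aggregation.

The screening procedure applies its filters at the ASV level first —
a minimum-total-read filter (default 5 reads, summed over all samples in
the analysis unit) and a minimum-occurrence filter (default: present in
more than one sample) — and only then rolls counts up to a taxonomic rank,
by default the order. Features missing a label at the chosen rank pool
into a reserved ``unassigned`` bucket that is namespaced so it can never
collide with a real taxonomy label.

All aggregation is integer arithmetic until the final division, so read
totals are conserved exactly.
"""

from __future__ import annotations

import pandas as pd

from contamscreen.io_formats import (
    RANKS,
    FeatureTable,
    TaxonomyTable,
    ValidationError,
)

#: Reserved order-position label for reads whose feature has no label at the
#: aggregation rank. The double-underscore namespacing guarantees it cannot
#: collide with a Silva taxonomy label.
UNASSIGNED = "__unassigned__"


def filter_min_total_reads(table: FeatureTable, min_reads: int = 5) -> FeatureTable:
    """Keep features whose total reads across all samples is >= ``min_reads``.

    The boundary is inclusive (a feature totalling exactly ``min_reads``
    survives); the sample set is unchanged.
    """
    if min_reads < 0:
        raise ValueError(f"min_reads must be >= 0, got {min_reads}")
    totals = table.feature_totals()
    keep = totals.index[totals >= min_reads]
    return FeatureTable(table.counts.loc[keep].copy())


def feature_occurrence(table: FeatureTable) -> pd.DataFrame:
    """Per-feature read totals and occurrence (number of samples with >= 1 read).

    Returns a DataFrame indexed by feature id with columns ``total_reads``
    and ``occurrence``, sorted by descending occurrence then descending
    total reads then feature id (a Table 3-style ranking).
    """
    totals = table.feature_totals()
    occurrence = (table.counts > 0).sum(axis=1)
    df = pd.DataFrame({"total_reads": totals, "occurrence": occurrence})
    df.index.name = "feature_id"
    return df.sort_values(
        by=["occurrence", "total_reads", "feature_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )


def filter_min_occurrence(table: FeatureTable, min_occurrence: int = 2) -> FeatureTable:
    """Keep features present (>= 1 read) in at least ``min_occurrence`` samples."""
    if min_occurrence < 0:
        raise ValueError(f"min_occurrence must be >= 0, got {min_occurrence}")
    occurrence = (table.counts > 0).sum(axis=1)
    keep = occurrence.index[occurrence >= min_occurrence]
    return FeatureTable(table.counts.loc[keep].copy())


def to_relative_abundance(table: pd.DataFrame | FeatureTable,
                          allow_zero_read_samples: bool = False) -> pd.DataFrame:
    """Convert counts to per-sample fractions (each column sums to 1).

    Zero-read samples cannot be normalised; they raise unless
    ``allow_zero_read_samples`` is set, in which case their column is left
    as all-zero fractions.
    """
    counts = table.counts if isinstance(table, FeatureTable) else table
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero) and not allow_zero_read_samples:
        raise ValidationError(
            f"zero-read sample(s) {list(zero)}: cannot compute relative "
            "abundance (pass allow_zero_read_samples=True to keep them as "
            "all-zero columns)"
        )
    safe_totals = totals.replace(0, 1)
    return counts.div(safe_totals, axis=1)


def aggregate_to_rank(table: FeatureTable, taxonomy: TaxonomyTable,
                      rank: str = "order") -> pd.DataFrame:
    """Roll feature counts up to ``rank``; unlabeled features pool into UNASSIGNED.

    Returns an integer DataFrame (labels x samples) whose column sums equal
    the input column sums exactly. Rows are sorted with real labels first
    (lexicographic) and UNASSIGNED last.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise ValidationError(
            f"features absent from taxonomy: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    labels = pd.Series(
        [taxonomy[f].get(rank) or UNASSIGNED for f in table.feature_ids],
        index=table.counts.index,
    )
    agg = table.counts.groupby(labels, sort=False).sum()
    real = sorted(l for l in agg.index if l != UNASSIGNED)
    order = real + ([UNASSIGNED] if UNASSIGNED in agg.index else [])
    return agg.loc[order]
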