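"""Build, serialize and load the two-part contaminant order database.

The database holds two order lists: *laboratory* contaminants, pooled from
control groups I (drilling-associated swabs, lubricants, paints) and II
(extraction/PCR blanks, laboratory air), and *seawater* contaminants from
control group III (seawater and drilling fluids). Each list is the top-k
most abundant orders in its pool (default k=30), restricted to orders whose
pooled relative abundance exceeds ``min_pooled_fraction`` (default 1%).
Orders appearing in both lists are flagged *ubiquitous*; the intersection is
recomputed and verified every time a database is loaded.

The ranking statistic is the pooled read fraction — reads of the order
summed over the pool's samples divided by the pool's total reads — which
weights deep samples more than shallow ones. A mean-of-per-sample-fractions
alternative is available via ``ScreeningConfig.ranking_statistic`` for users
who prefer every control sample to count equally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from contamscreen.abundance import UNASSIGNED, to_relative_abundance
from contamscreen.io_formats import RANKS, SampleManifest, ValidationError

SCHEMA_VERSION = 1

_RANKING_STATISTICS = ("pooled", "mean_of_fractions")


class DatabaseIntegrityError(ValueError):
    """A serialized database is internally inconsistent."""


@dataclass(frozen=True)
class ScreeningConfig:
    """Tunable constants of the database-building and screening procedure.

    Defaults mirror the published procedure: order-level aggregation, the
    30 most abundant orders per control pool, a 1% pooled-abundance floor,
    the >=5-total-read and >1-sample ASV filters, and a 1% per-sample
    order-abundance threshold below which reads are never called
    contamination.
    """

    rank: str = "order"
    top_k: int = 30
    min_pooled_fraction: float = 0.01
    min_reads: int = 5
    min_occurrence: int = 2
    per_sample_threshold: float = 0.01
    ranking_statistic: str = "pooled"

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        for name in ("top_k", "min_reads", "min_occurrence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("min_pooled_fraction", "per_sample_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.ranking_statistic not in _RANKING_STATISTICS:
            raise ValueError(
                f"ranking_statistic must be one of {_RANKING_STATISTICS}"
            )


@dataclass(frozen=True)
class OrderRecord:
    """One database member: an order with its pooled abundance evidence.

    ``pooled_fraction`` and friends are ``None`` for reference databases
    transcribed from a printed order list, where the underlying counts are
    not available.
    """

    label: str
    pooled_fraction: float | None = None
    n_samples: int | None = None
    rank_position: int | None = None


@dataclass
class ContaminantDatabase:
    """Two order lists plus the recomputed ubiquitous intersection."""

    laboratory: list[OrderRecord]
    seawater: list[OrderRecord]
    rank: str = "order"
    config: ScreeningConfig | None = None
    provenance: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    @property
    def laboratory_labels(self) -> frozenset[str]:
        return frozenset(r.label for r in self.laboratory)

    @property
    def seawater_labels(self) -> frozenset[str]:
        return frozenset(r.label for r in self.seawater)

    @property
    def ubiquitous(self) -> list[str]:
        """Orders in both lists — recomputed, never trusted from disk."""
        return sorted(self.laboratory_labels & self.seawater_labels)

    @property
    def all_labels(self) -> frozenset[str]:
        return self.laboratory_labels | self.seawater_labels


# ---------------------------------------------------------------------------
# Ranking and selection
# ---------------------------------------------------------------------------

def pooled_order_fractions(agg_table: pd.DataFrame,
                           sample_subset: Sequence[str],
                           statistic: str = "pooled") -> list[OrderRecord]:
    """Rank orders in a control pool by abundance.

    ``agg_table`` is a rank-aggregated count table (labels x samples).
    Zero-read samples are excluded from the pool; the ``unassigned`` bucket
    is excluded from the ranking. Sorted by descending fraction, ties broken
    lexicographically by label; rank positions start at 1.
    """
    if statistic not in _RANKING_STATISTICS:
        raise ValueError(f"statistic must be one of {_RANKING_STATISTICS}")
    subset = list(sample_subset)
    missing = [s for s in subset if s not in agg_table.columns]
    if missing:
        raise KeyError(f"samples not in aggregated table: {missing}")
    pool = agg_table[subset]
    totals = pool.sum(axis=0)
    pool = pool.loc[:, totals > 0]
    if pool.shape[1] == 0:
        raise ValidationError(
            "control pool is empty after excluding zero-read samples"
        )
    if statistic == "pooled":
        order_reads = pool.sum(axis=1)
        fractions = order_reads / order_reads.sum()
    else:
        fractions = to_relative_abundance(pool).mean(axis=1)
    n_present = (pool > 0).sum(axis=1)
    records = [
        (label, float(fractions[label]), int(n_present[label]))
        for label in pool.index
        if label != UNASSIGNED and pool.loc[label].sum() > 0
    ]
    records.sort(key=lambda rec: (-rec[1], rec[0]))
    return [
        OrderRecord(label=label, pooled_fraction=frac, n_samples=n,
                    rank_position=i + 1)
        for i, (label, frac, n) in enumerate(records)
    ]


def select_top_orders(ranked: Sequence[OrderRecord], top_k: int = 30,
                      min_pooled_fraction: float = 0.01) -> list[OrderRecord]:
    """Take the top-k records, keeping boundary ties, then apply the fraction floor.

    Records tied (equal fraction) with the record at position ``top_k`` are
    retained before the floor is applied, so the selection never depends on
    how a tie happened to be ordered.
    """
    if top_k <= 0:
        return []
    selected = list(ranked[:top_k])
    if len(ranked) > top_k and selected:
        boundary = selected[-1].pooled_fraction
        for rec in ranked[top_k:]:
            if rec.pooled_fraction == boundary:
                selected.append(rec)
            else:
                break
    return [r for r in selected
            if r.pooled_fraction is not None
            and r.pooled_fraction >= min_pooled_fraction]


def build_database(agg_table: pd.DataFrame, manifest: SampleManifest,
                   config: ScreeningConfig | None = None,
                   provenance: dict | None = None) -> ContaminantDatabase:
    """Build the database from a rank-aggregated count table.

    The laboratory list pools control groups I and II; the seawater list
    uses group III. Each group must contribute at least one non-zero-read
    sample.
    """
    config = config or ScreeningConfig()
    in_table = set(agg_table.columns)
    lab_samples = [s for s in manifest.samples_with_role("control_I", "control_II")
                   if s in in_table]
    sea_samples = [s for s in manifest.samples_with_role("control_III")
                   if s in in_table]
    for group, samples in (("I+II (laboratory)", lab_samples),
                           ("III (seawater)", sea_samples)):
        if not samples:
            raise ValidationError(
                f"no control samples for group {group}; cannot build database"
            )
    lab_ranked = pooled_order_fractions(agg_table, lab_samples,
                                        config.ranking_statistic)
    sea_ranked = pooled_order_fractions(agg_table, sea_samples,
                                        config.ranking_statistic)
    lab = select_top_orders(lab_ranked, config.top_k, config.min_pooled_fraction)
    sea = select_top_orders(sea_ranked, config.top_k, config.min_pooled_fraction)
    prov = dict(provenance or {})
    prov.setdefault("n_laboratory_samples", len(lab_samples))
    prov.setdefault("n_seawater_samples", len(sea_samples))
    # per-group sub-lists for reporting; selection itself always pools I+II
    prov.setdefault("per_group_samples", {
        "control_I": manifest.samples_with_role("control_I"),
        "control_II": manifest.samples_with_role("control_II"),
        "control_III": manifest.samples_with_role("control_III"),
    })
    return ContaminantDatabase(laboratory=lab, seawater=sea, rank=config.rank,
                               config=config, provenance=prov)


def build_database_from_counts(table, taxonomy, manifest,
                               config: ScreeningConfig | None = None) -> ContaminantDatabase:
    """Full pipeline: ASV filters, rank rollup, then :func:`build_database`."""
    from contamscreen.abundance import (
        aggregate_to_rank, filter_min_occurrence, filter_min_total_reads,
    )
    config = config or ScreeningConfig()
    filtered = filter_min_total_reads(table, config.min_reads)
    filtered = filter_min_occurrence(filtered, config.min_occurrence)
    agg = aggregate_to_rank(filtered, taxonomy, config.rank)
    digest = hashlib.sha256(
        table.counts.to_csv(sep="\t").encode()
    ).hexdigest()
    return build_database(agg, manifest, config,
                          provenance={"input_table_sha256": digest})


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _record_to_dict(rec: OrderRecord) -> dict:
    return {"label": rec.label, "pooled_fraction": rec.pooled_fraction,
            "n_samples": rec.n_samples, "rank_position": rec.rank_position}


def database_to_json(db: ContaminantDatabase) -> str:
    payload = {
        "schema_version": db.schema_version,
        "rank": db.rank,
        "config": asdict(db.config) if db.config else None,
        "laboratory": [_record_to_dict(r) for r in db.laboratory],
        "seawater": [_record_to_dict(r) for r in db.seawater],
        "ubiquitous": db.ubiquitous,
        "provenance": db.provenance,
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def write_database(db: ContaminantDatabase, path: str | Path) -> None:
    Path(path).write_text(database_to_json(db))


def database_from_json(text: str, source: str = "<string>") -> ContaminantDatabase:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DatabaseIntegrityError(f"{source}: not valid JSON: {exc}") from None
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DatabaseIntegrityError(
            f"{source}: unsupported schema version {version!r} "
            f"(supported: {SCHEMA_VERSION})"
        )
    def _records(key: str) -> list[OrderRecord]:
        return [OrderRecord(label=d["label"],
                            pooled_fraction=d.get("pooled_fraction"),
                            n_samples=d.get("n_samples"),
                            rank_position=d.get("rank_position"))
                for d in payload.get(key, [])]
    config = None
    if payload.get("config"):
        config = ScreeningConfig(**payload["config"])
    db = ContaminantDatabase(
        laboratory=_records("laboratory"),
        seawater=_records("seawater"),
        rank=payload.get("rank", "order"),
        config=config,
        provenance=payload.get("provenance", {}),
        schema_version=version,
    )
    stored = sorted(payload.get("ubiquitous", []))
    if stored != db.ubiquitous:
        raise DatabaseIntegrityError(
            f"{source}: stored ubiquitous list {stored} does not equal the "
            f"recomputed intersection {db.ubiquitous}"
        )
    return db


def read_database(path: str | Path) -> ContaminantDatabase:
    path = Path(path)
    return database_from_json(path.read_text(), source=str(path))


_REFERENCE_RESOURCE = "reference_contaminant_orders.json"


def load_reference_database() -> ContaminantDatabase:
    """Load the packaged reference database of published contaminant orders.

    The laboratory and seawater order lists were transcribed from the
    published compilation of the most abundant orders in scientific ocean
    drilling contamination controls, for screening query datasets when no
    control samples of one's own are available.
    """
    text = (resources.files("contamscreen") / "data" / _REFERENCE_RESOURCE).read_text()
    return database_from_json(text, source=_REFERENCE_RESOURCE)
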