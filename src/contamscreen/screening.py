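"""Classify query samples' order-level reads against a contaminant database.

Each (sample, order) pair receives exactly one of five labels:

* ``unassigned`` — the reads' features carry no label at the screening rank;
* ``below_threshold`` — the order is under the per-sample abundance
  threshold (default 1%), and is never counted as contamination;
* ``potential_contaminant`` — the order is in the laboratory list;
* ``seawater_influenced`` — the order is in the seawater list (and not the
  laboratory list: ubiquitous orders resolve to ``potential_contaminant``,
  since most observed contamination is laboratory-derived — both membership
  flags are kept in the per-order detail so users can re-bin);
* ``endemic`` — not found in either control list.

The *database coverage* of a sample is the fraction of its reads whose
order is in the union of the two lists, ignoring the per-sample threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from contamscreen.abundance import (
    UNASSIGNED,
    aggregate_to_rank,
    filter_min_occurrence,
    filter_min_total_reads,
)
from contamscreen.contamdb import ContaminantDatabase, ScreeningConfig
from contamscreen.io_formats import (
    FeatureTable,
    SampleManifest,
    TaxonomyTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

LABELS = ("potential_contaminant", "seawater_influenced", "endemic",
          "below_threshold", "unassigned")

#: Labels counted as contamination in threshold summaries.
CONTAMINATION_LABELS = ("potential_contaminant", "seawater_influenced")


def label_order(order: str, sample_fraction: float,
                db: ContaminantDatabase,
                config: ScreeningConfig | None = None) -> str:
    """Label one order's reads within one sample.

    Precedence: unassigned > below-threshold > laboratory > seawater >
    endemic. ``sample_fraction`` is the order's share of the sample's reads.
    """
    config = config or ScreeningConfig()
    if not 0.0 <= sample_fraction <= 1.0 + 1e-12:
        raise ValueError(f"sample_fraction must be in [0, 1], got {sample_fraction}")
    if order == UNASSIGNED:
        return "unassigned"
    if sample_fraction < config.per_sample_threshold:
        return "below_threshold"
    if order in db.laboratory_labels:
        return "potential_contaminant"
    if order in db.seawater_labels:
        return "seawater_influenced"
    return "endemic"


def database_coverage(sample_profile: pd.Series, db: ContaminantDatabase) -> float:
    """Fraction of a sample's reads in database orders, thresholds ignored.

    ``sample_profile`` maps order label -> read fraction for one sample
    (the ``unassigned`` bucket included).
    """
    total = float(sample_profile.sum())
    if total == 0:
        return 0.0
    member = sample_profile.index.isin(db.all_labels)
    return float(sample_profile[member].sum()) / total


@dataclass
class SampleScreeningResult:
    """Per-sample label fractions, per-order detail, and database coverage."""

    sample_id: str
    fractions: dict[str, float]
    detail: pd.DataFrame  # columns: order, fraction, label, in_laboratory, in_seawater
    coverage: float
    total_reads: int

    @property
    def contamination_fraction(self) -> float:
        return sum(self.fractions[l] for l in CONTAMINATION_LABELS)


@dataclass
class ScreeningReport:
    results: list[SampleScreeningResult]
    config: ScreeningConfig
    db_provenance: dict = field(default_factory=dict)
    skipped_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.results]

    def to_wide_frame(self) -> pd.DataFrame:
        """One row per sample: the five label fractions, coverage, total reads."""
        rows = []
        for r in self.results:
            row = {"sample_id": r.sample_id}
            row.update({l: r.fractions[l] for l in LABELS})
            row["contamination_fraction"] = r.contamination_fraction
            row["database_coverage"] = r.coverage
            row["total_reads"] = r.total_reads
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (sample, order, fraction, label) for stacked-bar plots."""
        frames = []
        for r in self.results:
            df = r.detail.copy()
            df.insert(0, "sample_id", r.sample_id)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["sample_id", "order", "fraction",
                                         "label", "in_laboratory", "in_seawater"])
        return pd.concat(frames, ignore_index=True)


def screen_samples(table: FeatureTable, taxonomy: TaxonomyTable,
                   manifest: SampleManifest, db: ContaminantDatabase,
                   config: ScreeningConfig | None = None) -> ScreeningReport:
    """Screen every query sample in the bundle against the database.

    The abundance pipeline is applied first — the minimum-total-read and
    minimum-occurrence ASV filters computed over all samples in the input
    table (the analysis unit), then rollup to the screening rank — and each
    query sample's order fractions are labelled. Zero-read query samples
    (before or after filtering) are skipped with a warning.
    """
    config = config or ScreeningConfig()
    if db.rank != config.rank:
        raise ValidationError(
            f"database rank {db.rank!r} does not match config rank {config.rank!r}"
        )
    query_ids = [s for s in manifest.samples_with_role("query")
                 if s in table.counts.columns]
    if not query_ids:
        raise ValidationError("no query samples found in table")

    filtered = filter_min_total_reads(table, config.min_reads)
    filtered = filter_min_occurrence(filtered, config.min_occurrence)
    agg = aggregate_to_rank(filtered, taxonomy, config.rank)

    results: list[SampleScreeningResult] = []
    skipped: list[str] = []
    for sample in query_ids:
        column = agg[sample]
        total = int(column.sum())
        if total == 0:
            logger.warning("query sample %s has zero reads after filtering; skipped",
                           sample)
            skipped.append(sample)
            continue
        fractions_by_order = column / total
        label_fracs = {l: 0.0 for l in LABELS}
        rows = []
        for order, frac in fractions_by_order.items():
            if frac == 0:
                continue
            label = label_order(order, float(frac), db, config)
            label_fracs[label] += float(frac)
            rows.append({
                "order": order,
                "fraction": float(frac),
                "label": label,
                "in_laboratory": order in db.laboratory_labels,
                "in_seawater": order in db.seawater_labels,
            })
        detail = pd.DataFrame(rows, columns=["order", "fraction", "label",
                                             "in_laboratory", "in_seawater"])
        detail = detail.sort_values("fraction", ascending=False,
                                    kind="mergesort").reset_index(drop=True)
        coverage = database_coverage(fractions_by_order, db)
        results.append(SampleScreeningResult(
            sample_id=sample, fractions=label_fracs, detail=detail,
            coverage=coverage, total_reads=total,
        ))
    return ScreeningReport(results=results, config=config,
                           db_provenance=dict(db.provenance),
                           skipped_samples=skipped)


def summarize_contamination(report: ScreeningReport,
                            cutoffs: Iterable[float] = (0.2, 0.5),
                            include_seawater: bool = True) -> pd.DataFrame:
    """Count samples above / at-or-below each contamination cutoff.

    The contamination fraction is potential_contaminant +
    seawater_influenced by default; set ``include_seawater=False`` to treat
    seawater-list orders as potentially endemic fluid-borne organisms.
    """
    cutoffs = sorted(cutoffs)
    for c in cutoffs:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {c}")
    labels = CONTAMINATION_LABELS if include_seawater else ("potential_contaminant",)
    loads = [sum(r.fractions[l] for l in labels) for r in report.results]
    n = len(loads)
    rows = []
    for c in cutoffs:
        n_above = sum(1 for x in loads if x > c)
        rows.append({
            "cutoff": c,
            "n_samples": n,
            "n_above": n_above,
            "fraction_above": (n_above / n) if n else 0.0,
            "n_at_or_below": n - n_above,
            "fraction_at_or_below": ((n - n_above) / n) if n else 0.0,
        })
    return pd.DataFrame(rows)


def write_report(report: ScreeningReport, outdir,
                 cutoffs: Sequence[float] = (0.2, 0.5)) -> dict[str, str]:
    """Write the wide, long and summary TSVs; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wide": outdir / "screening_per_sample.tsv",
        "long": outdir / "screening_per_order.tsv",
        "summary": outdir / "screening_summary.tsv",
    }
    report.to_wide_frame().to_csv(paths["wide"], sep="\t", lineterminator="\n")
    report.to_long_frame().to_csv(paths["long"], sep="\t", index=False,
                                  lineterminator="\n")
    summarize_contamination(report, cutoffs).to_csv(
        paths["summary"], sep="\t", index=False, lineterminator="\n")
    return {k: str(v) for k, v in paths.items()}
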