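"""Readers, writers and validation for the three input tables and their dialects.

On-disk conventions
-------------------
* Feature table: TSV, first column ``feature_id``, remaining columns sample
  ids, integer cells. Features-as-rows is the default orientation; the
  transposed dialect must be requested explicitly, never guessed.
* Taxonomy: either a two-column TSV ``feature_id<TAB>lineage`` where the
  lineage is a Silva-style prefixed string
  (``d__Bacteria;p__...;o__Burkholderiales;f__;g__``), or a seven-column
  rank table (``feature_id`` + the six ranks).
* Manifest: TSV ``sample_id<TAB>role<TAB>source`` where role is one of
  ``control_I`` (drilling-associated), ``control_II`` (laboratory),
  ``control_III`` (seawater / drilling fluid) or ``query``.

Missing taxonomy ranks are held as a single canonical sentinel
(:data:`MISSING`, i.e. ``None``) — never as an empty string — and written
back out as empty fields (prefixed dialect) or ``na`` (rank columns).
Labels are kept verbatim and matched case-sensitively: ``Subgroup 2`` and
``subgroup 2`` are different orders, and silently normalising them would be
invisible data editing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Canonical sentinel for a missing rank label.
MISSING = None

#: Strings treated as missing when reading rank-column taxonomy files.
_NA_STRINGS = frozenset({"", "na", "NA", "n/a", "N/A"})

_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")

ROLES = ("control_I", "control_II", "control_III", "query")

FEATURE_TABLE_DIALECTS = ("tsv_features_by_samples", "tsv_samples_by_features")
TAXONOMY_DIALECTS = ("silva_prefixed_string", "rank_columns")


class FormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a table invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lineage:
    """Ranked lineage from domain to genus; missing ranks are ``None``."""

    domain: str | None = MISSING
    phylum: str | None = MISSING
    class_: str | None = MISSING
    order: str | None = MISSING
    family: str | None = MISSING
    genus: str | None = MISSING

    def __post_init__(self) -> None:
        for rank in RANKS:
            value = self.get(rank)
            if value == "":
                raise ValidationError(
                    f"rank {rank!r} is an empty string; use the missing "
                    "sentinel (None) instead"
                )

    def get(self, rank: str) -> str | None:
        if rank == "class":
            return self.class_
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, rank)

    def as_tuple(self) -> tuple[str | None, ...]:
        return tuple(self.get(r) for r in RANKS)

    @classmethod
    def from_values(cls, values: Iterable[str | None]) -> "Lineage":
        vals = list(values)
        if len(vals) > len(RANKS):
            raise ValidationError(
                f"lineage has {len(vals)} ranks; at most {len(RANKS)} allowed"
            )
        vals += [MISSING] * (len(RANKS) - len(vals))
        return cls(domain=vals[0], phylum=vals[1], class_=vals[2],
                   order=vals[3], family=vals[4], genus=vals[5])


@dataclass
class FeatureTable:
    """Non-negative integer count matrix, ASV features (rows) x samples (cols)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.size and not all(pd.api.types.is_integer_dtype(t) for t in df.dtypes):
            raise ValidationError("counts must be integers (no coercion applied)")
        if df.size and (df.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = df.astype("int64") if df.size else df

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def feature_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def zero_read_samples(self) -> list[str]:
        """Samples with zero total reads (e.g. empty blanks) — legal, flagged."""
        totals = self.sample_totals()
        return list(totals.index[totals == 0])

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return FeatureTable(self.counts[ids].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.counts.equals(other.counts)


class TaxonomyTable:
    """Mapping from feature id to :class:`Lineage`."""

    def __init__(self, lineages: Mapping[str, Lineage]):
        self._lineages = dict(lineages)

    def __getitem__(self, feature_id: str) -> Lineage:
        return self._lineages[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def __iter__(self):
        return iter(self._lineages)

    def items(self):
        return self._lineages.items()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTable):
            return NotImplemented
        return self._lineages == other._lineages

    def labels_at(self, rank: str) -> dict[str, str | None]:
        """Feature id -> label at ``rank`` (``None`` when missing)."""
        return {fid: lin.get(rank) for fid, lin in self._lineages.items()}


@dataclass
class SampleManifest:
    """Sample roles and free-text source labels."""

    entries: pd.DataFrame  # columns: role, source; index: sample_id

    def __post_init__(self) -> None:
        df = self.entries
        if df.empty:
            raise ValidationError("manifest contains no samples")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in manifest: {dups}")
        bad = sorted(set(df["role"]) - set(ROLES))
        if bad:
            raise ValidationError(
                f"unknown roles {bad}; legal values are {list(ROLES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries.index)

    def role_of(self, sample_id: str) -> str:
        return self.entries.loc[sample_id, "role"]

    def samples_with_role(self, *roles: str) -> list[str]:
        for r in roles:
            if r not in ROLES:
                raise KeyError(f"unknown role {r!r}")
        mask = self.entries["role"].isin(roles)
        return list(self.entries.index[mask])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleManifest):
            return NotImplemented
        return self.entries.equals(other.entries)


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path,
                       dialect: str = "tsv_features_by_samples") -> FeatureTable:
    """Read a TSV count table.

    Non-integer or negative cells are errors, never coerced; the transposed
    orientation must be requested via ``dialect`` explicitly.
    """
    if dialect not in FEATURE_TABLE_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {FEATURE_TABLE_DIALECTS}"
        )
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: line 1: empty header")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            parsed[col] = df[col].map(_parse_count)
        except ValueError as exc:
            raise ValidationError(f"{path}: column {col!r}: {exc}") from None
    if dialect == "tsv_samples_by_features":
        parsed = parsed.T
    return FeatureTable(parsed)


def _parse_count(cell: str) -> int:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        raise ValueError("missing cell")
    text = str(cell).strip()
    try:
        value = int(text)
    except ValueError:
        raise ValueError(f"non-integer count {text!r}") from None
    if value < 0:
        raise ValueError(f"negative count {value}")
    return value


def write_feature_table(table: FeatureTable, path: str | Path,
                        dialect: str = "tsv_features_by_samples") -> None:
    if dialect not in FEATURE_TABLE_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {FEATURE_TABLE_DIALECTS}"
        )
    df = table.counts
    if dialect == "tsv_samples_by_features":
        df = df.T
    out = df.copy()
    out.index.name = "feature_id" if dialect == "tsv_features_by_samples" else "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Taxonomy I/O
# ---------------------------------------------------------------------------

def parse_silva_lineage(text: str) -> Lineage:
    """Parse a prefixed lineage string like ``d__Bacteria;...;o__Burkholderiales``.

    Rank prefixes (``d__`` .. ``g__``) are stripped when present; empty
    fields become the missing sentinel. More than six fields is an error.
    """
    fields = text.split(";")
    if len(fields) > len(RANKS):
        raise ValidationError(
            f"lineage {text!r} has {len(fields)} ranks; at most {len(RANKS)}"
        )
    values: list[str | None] = []
    for i, raw in enumerate(fields):
        label = raw.strip()
        prefix = _RANK_PREFIXES[i]
        if label.startswith(prefix):
            label = label[len(prefix):]
        values.append(label if label else MISSING)
    return Lineage.from_values(values)


def format_silva_lineage(lineage: Lineage) -> str:
    parts = []
    for prefix, value in zip(_RANK_PREFIXES, lineage.as_tuple()):
        parts.append(prefix + (value if value is not None else ""))
    return ";".join(parts)


def read_taxonomy(path: str | Path,
                  dialect: str = "silva_prefixed_string") -> TaxonomyTable:
    if dialect not in TAXONOMY_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {TAXONOMY_DIALECTS}"
        )
    path = Path(path)
    lineages: dict[str, Lineage] = {}
    if dialect == "silva_prefixed_string":
        with path.open() as fh:
            header = fh.readline().rstrip("\n")
            if not header:
                raise FormatError(f"{path}: line 1: empty header")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 2 tab-separated "
                        f"columns, found {len(parts)}"
                    )
                fid, lineage_text = parts
                if fid in lineages:
                    raise ValidationError(f"feature id repeated: {fid!r}")
                try:
                    lineages[fid] = parse_silva_lineage(lineage_text)
                except ValidationError as exc:
                    raise ValidationError(f"feature {fid!r}: {exc}") from None
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        expected = ["feature_id", *RANKS]
        if list(df.columns) != expected:
            raise FormatError(
                f"{path}: line 1: expected columns {expected}, found "
                f"{list(df.columns)}"
            )
        for _, row in df.iterrows():
            fid = row["feature_id"]
            if fid in lineages:
                raise ValidationError(f"feature id repeated: {fid!r}")
            values = [
                (MISSING if row[r] in _NA_STRINGS else row[r]) for r in RANKS
            ]
            lineages[fid] = Lineage.from_values(values)
    return TaxonomyTable(lineages)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path,
                   dialect: str = "silva_prefixed_string") -> None:
    if dialect not in TAXONOMY_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {TAXONOMY_DIALECTS}"
        )
    buf = io.StringIO()
    if dialect == "silva_prefixed_string":
        buf.write("feature_id\tlineage\n")
        for fid, lin in taxonomy.items():
            buf.write(f"{fid}\t{format_silva_lineage(lin)}\n")
    else:
        buf.write("feature_id\t" + "\t".join(RANKS) + "\n")
        for fid, lin in taxonomy.items():
            cells = [v if v is not None else "na" for v in lin.as_tuple()]
            buf.write(fid + "\t" + "\t".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> SampleManifest:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"{path}: manifest is empty (no samples)")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["sample_id", "role", "source"]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: line 1: expected columns {expected}, found {list(df.columns)}"
        )
    if df.empty:
        raise ValidationError(f"{path}: manifest is empty (no samples)")
    df = df.set_index("sample_id")
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    out = manifest.entries.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Findings from cross-checking a table/taxonomy/manifest bundle.

    Zero-read samples are warnings (empty blanks are expected in this kind
    of survey); missing taxonomy entries and manifest/table mismatches are
    errors.
    """

    zero_read_samples: list[str] = field(default_factory=list)
    features_without_taxonomy: list[str] = field(default_factory=list)
    samples_missing_from_manifest: list[str] = field(default_factory=list)
    samples_missing_from_table: list[str] = field(default_factory=list)

    @property
    def warnings(self) -> list[str]:
        return [f"zero-read sample: {s}" for s in self.zero_read_samples]

    @property
    def errors(self) -> list[str]:
        msgs = [f"feature without taxonomy: {f}"
                for f in self.features_without_taxonomy]
        msgs += [f"sample missing from manifest: {s}"
                 for s in self.samples_missing_from_manifest]
        msgs += [f"manifest sample missing from table: {s}"
                 for s in self.samples_missing_from_table]
        return msgs

    @property
    def ok(self) -> bool:
        return not self.errors

    def is_empty(self) -> bool:
        return not self.errors and not self.warnings


def validate_bundle(table: FeatureTable, taxonomy: TaxonomyTable,
                    manifest: SampleManifest) -> ValidationReport:
    report = ValidationReport()
    report.zero_read_samples = table.zero_read_samples()
    report.features_without_taxonomy = [
        f for f in table.feature_ids if f not in taxonomy
    ]
    manifest_ids = set(manifest.sample_ids)
    table_ids = set(table.sample_ids)
    report.samples_missing_from_manifest = sorted(table_ids - manifest_ids)
    report.samples_missing_from_table = sorted(manifest_ids - table_ids)
    return report
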