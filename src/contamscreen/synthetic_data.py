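"""Synthetic ASV bundles with ground truth for testing the screening pipeline.

The generator emulates the statistical structure of contamination-control
surveys from scientific ocean drilling:

* *laboratory* controls (groups I and II) dominated by a small pool of
  contaminant orders, with one or more *dominance-flagged* orders (think
  Burkholderiales) whose reads concentrate in few ASVs — a large share of
  reads but a small share of unique ASVs;
* *seawater* controls (group III) with an even community;
* extraction/PCR blanks that may yield zero reads at all;
* *query* samples that are mixtures of endemic, laboratory-contaminant and
  seawater reads with a known planted contaminant load.

Per sample, order proportions are drawn from a Dirichlet centred on the
pool's base weights, pools are mixed by the planted fractions, orders are
expanded to ASVs through geometric within-order weights (steeper for
dominance-flagged orders), and counts are drawn multinomially at the
sample's depth. Every sample has its own named RNG stream derived from
(seed, role, index), so adding a sample never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from contamscreen.io_formats import (
    FeatureTable,
    Lineage,
    SampleManifest,
    TaxonomyTable,
)

POOL_NAMES = ("laboratory", "seawater", "endemic")

_ROLE_CODES = {"control_I": 1, "control_II": 2, "control_III": 3,
               "query": 4, "zero_blank": 5}


@dataclass(frozen=True)
class CommunitySpec:
    """Named order pools with base weights and within-order ASV structure.

    ``skew`` is the geometric decay ratio of ASV weights within an order
    (1 = uniform); dominance-flagged orders use the steeper
    ``dominant_skew`` so their reads concentrate in their first few ASVs.
    """

    pools: Mapping[str, Mapping[str, float]]
    asvs_per_order: int = 8
    skew: float = 0.7
    dominant_skew: float = 0.25
    dominant_orders: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.pools) - set(POOL_NAMES)
        if unknown:
            raise ValueError(f"unknown pool names {sorted(unknown)}; "
                             f"expected subset of {POOL_NAMES}")
        for pool, weights in self.pools.items():
            if not weights:
                raise ValueError(f"pool {pool!r} has no orders")
            vals = list(weights.values())
            if any(w < 0 for w in vals):
                raise ValueError(f"pool {pool!r} has negative weights")
            if sum(vals) <= 0:
                raise ValueError(f"pool {pool!r} has no positive weight")
        for name in ("skew", "dominant_skew"):
            r = getattr(self, name)
            if not 0.0 < r <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {r}")
        if self.asvs_per_order < 1:
            raise ValueError("asvs_per_order must be >= 1")

    def pool_orders(self, pool: str) -> list[str]:
        return sorted(self.pools[pool])


@dataclass(frozen=True)
class SimulationConfig:
    """Sample counts, sequencing depths and planted mixture fractions.

    ``contaminant_load`` (the laboratory-read fraction pi) and
    ``seawater_fraction`` apply to every query sample when scalar, or may
    be sequences of length ``n_query``. Depths are drawn log-uniform over
    ``depth_range``; set ``query_depth`` for a fixed query depth.
    """

    n_control_I: int = 6
    n_control_II: int = 6
    n_control_III: int = 6
    n_query: int = 6
    n_zero_blanks: int = 3
    depth_range: tuple[int, int] = (1_000, 400_000)
    query_depth: int | None = None
    dirichlet_concentration: float = 100.0
    contaminant_load: float | Sequence[float] = 0.4
    seawater_fraction: float | Sequence[float] = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control_I", "n_control_II", "n_control_III",
                     "n_query", "n_zero_blanks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid depth_range {self.depth_range}")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        for pi, sw in zip(self.query_loads(), self.query_seawater_fractions()):
            if pi < 0 or sw < 0 or pi + sw > 1.0 + 1e-12:
                raise ValueError(
                    f"infeasible mixture: laboratory {pi} + seawater {sw} > 1"
                )

    def _per_query(self, value) -> list[float]:
        if np.isscalar(value):
            return [float(value)] * self.n_query
        values = [float(v) for v in value]
        if len(values) != self.n_query:
            raise ValueError(
                f"expected {self.n_query} per-query values, got {len(values)}"
            )
        return values

    def query_loads(self) -> list[float]:
        return self._per_query(self.contaminant_load)

    def query_seawater_fractions(self) -> list[float]:
        return self._per_query(self.seawater_fraction)


@dataclass
class SimulationTruth:
    """Ground truth: planted fractions, planted order sets, ASV provenance."""

    sample_fractions: pd.DataFrame  # index sample_id; role + three true fractions
    laboratory_orders: list[str]
    seawater_orders: list[str]
    endemic_orders: list[str]
    asv_order: dict[str, str] = field(default_factory=dict)
    asv_source: dict[str, str] = field(default_factory=dict)
    depths: pd.Series = field(default_factory=lambda: pd.Series(dtype="int64"))

    def query_ids(self) -> list[str]:
        mask = self.sample_fractions["role"] == "query"
        return list(self.sample_fractions.index[mask])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _asv_roster(spec: CommunitySpec):
    """Deterministic pool-specific ASV roster and taxonomy.

    Each pool gets its own ASVs for its orders, so the same order appearing
    in two pools (e.g. a contaminant also found in seawater) is represented
    by distinct sequences, as in real surveys.
    """
    asv_ids: list[str] = []
    asv_order: dict[str, str] = {}
    asv_source: dict[str, str] = {}
    weights: dict[str, list[tuple[str, float]]] = {}  # (pool, order) key
    counter = 0
    for pool in POOL_NAMES:
        if pool not in spec.pools:
            continue
        for order in spec.pool_orders(pool):
            ratio = (spec.dominant_skew if order in spec.dominant_orders
                     else spec.skew)
            m = spec.asvs_per_order
            w = np.array([ratio ** k for k in range(m)], dtype=float)
            w /= w.sum()
            entries = []
            for k in range(m):
                counter += 1
                asv = f"ASV{counter:05d}"
                asv_ids.append(asv)
                asv_order[asv] = order
                asv_source[asv] = pool
                entries.append((asv, float(w[k])))
            weights[f"{pool}\t{order}"] = entries
    return asv_ids, asv_order, asv_source, weights


def _draw_depth(rng: np.random.Generator, depth_range: tuple[int, int]) -> int:
    lo, hi = depth_range
    if lo == hi:
        return lo
    u = rng.uniform(np.log(lo), np.log(hi))
    return int(np.clip(round(np.exp(u)), lo, hi))


def _sample_probabilities(spec: CommunitySpec, rng: np.random.Generator,
                          pool_fractions: Mapping[str, float],
                          concentration: float,
                          asv_index: Mapping[str, int],
                          roster_weights) -> np.ndarray:
    p = np.zeros(len(asv_index))
    for pool, frac in pool_fractions.items():
        if frac <= 0:
            continue
        orders = spec.pool_orders(pool)
        base = np.array([spec.pools[pool][o] for o in orders], dtype=float)
        base = base / base.sum()
        props = rng.dirichlet(concentration * base)
        for order, prop in zip(orders, props):
            for asv, w in roster_weights[f"{pool}\t{order}"]:
                p[asv_index[asv]] += frac * prop * w
    total = p.sum()
    if total > 0:
        p /= total
    return p


def simulate_bundle(spec: CommunitySpec, config: SimulationConfig
                    ) -> tuple[FeatureTable, TaxonomyTable, SampleManifest,
                               SimulationTruth]:
    """Generate a feature table, taxonomy, manifest and ground truth."""
    required = {"laboratory", "seawater", "endemic"}
    have = set(spec.pools)
    need = set()
    if config.n_control_I or config.n_control_II:
        need.add("laboratory")
    if config.n_control_III:
        need.add("seawater")
    if config.n_query:
        need |= required
    missing = need - have
    if missing:
        raise ValueError(f"spec is missing pools {sorted(missing)}")

    asv_ids, asv_order, asv_source, roster_weights = _asv_roster(spec)
    asv_index = {a: i for i, a in enumerate(asv_ids)}
    conc = config.dirichlet_concentration

    columns: dict[str, np.ndarray] = {}
    manifest_rows = []
    truth_rows = []
    depths = {}

    def add_sample(sample_id, role, source, pool_fractions, depth_rng,
                   fixed_depth=None):
        rng = depth_rng
        depth = fixed_depth if fixed_depth is not None else _draw_depth(
            rng, config.depth_range)
        p = _sample_probabilities(spec, rng, pool_fractions, conc,
                                  asv_index, roster_weights)
        columns[sample_id] = rng.multinomial(depth, p)
        depths[sample_id] = depth
        manifest_rows.append((sample_id, role, source))
        truth_rows.append((sample_id, role,
                           pool_fractions.get("laboratory", 0.0),
                           pool_fractions.get("seawater", 0.0),
                           pool_fractions.get("endemic", 0.0)))

    for i in range(config.n_control_I):
        rng = np.random.default_rng([config.seed, _ROLE_CODES["control_I"], i])
        add_sample(f"drill_{i + 1:02d}", "control_I", "drill equipment swab",
                   {"laboratory": 1.0}, rng)
    for i in range(config.n_control_II):
        rng = np.random.default_rng([config.seed, _ROLE_CODES["control_II"], i])
        add_sample(f"blank_{i + 1:02d}", "control_II", "PCR blank",
                   {"laboratory": 1.0}, rng)
    for i in range(config.n_control_III):
        rng = np.random.default_rng([config.seed, _ROLE_CODES["control_III"], i])
        add_sample(f"seawater_{i + 1:02d}", "control_III", "seawater",
                   {"seawater": 1.0}, rng)
    loads = config.query_loads()
    sea_fracs = config.query_seawater_fractions()
    for i in range(config.n_query):
        rng = np.random.default_rng([config.seed, _ROLE_CODES["query"], i])
        pi, sw = loads[i], sea_fracs[i]
        add_sample(f"query_{i + 1:02d}", "query", "sediment core",
                   {"laboratory": pi, "seawater": sw,
                    "endemic": max(0.0, 1.0 - pi - sw)},
                   rng, fixed_depth=config.query_depth)
    for i in range(config.n_zero_blanks):
        sid = f"zeroblank_{i + 1:02d}"
        columns[sid] = np.zeros(len(asv_ids), dtype="int64")
        depths[sid] = 0
        manifest_rows.append((sid, "control_II", "DNA extraction blank"))
        truth_rows.append((sid, "control_II", 1.0, 0.0, 0.0))

    counts = pd.DataFrame(columns, index=pd.Index(asv_ids, name="feature_id"),
                          dtype="int64")
    table = FeatureTable(counts)
    taxonomy = TaxonomyTable({
        asv: Lineage(domain="Bacteria", order=asv_order[asv])
        for asv in asv_ids
    })
    manifest = SampleManifest(
        pd.DataFrame(manifest_rows, columns=["sample_id", "role", "source"])
        .set_index("sample_id")
    )
    fractions = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "role", "true_laboratory", "true_seawater",
                 "true_endemic"],
    ).set_index("sample_id")
    truth = SimulationTruth(
        sample_fractions=fractions,
        laboratory_orders=spec.pool_orders("laboratory")
        if "laboratory" in spec.pools else [],
        seawater_orders=spec.pool_orders("seawater")
        if "seawater" in spec.pools else [],
        endemic_orders=spec.pool_orders("endemic")
        if "endemic" in spec.pools else [],
        asv_order=asv_order,
        asv_source=asv_source,
        depths=pd.Series(depths, name="depth").astype("int64"),
    )
    return table, taxonomy, manifest, truth


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    per_sample: pd.DataFrame
    mean_abs_error_laboratory: float
    mean_abs_error_seawater: float
    laboratory_precision: float | None = None
    laboratory_recall: float | None = None
    seawater_precision: float | None = None
    seawater_recall: float | None = None


def evaluate_screening(truth: SimulationTruth, report,
                       db=None) -> EvaluationResult:
    """Compare screening estimates with the planted ground truth.

    Per-sample absolute errors between the estimated and planted laboratory
    and seawater fractions; if the built database is supplied, order-set
    precision/recall against the planted pools.
    """
    truth_ids = set(truth.query_ids())
    report_ids = set(report.sample_ids)
    stray = sorted(report_ids - truth_ids)
    if stray:
        raise ValueError(f"report samples not in truth: {stray}")
    unaccounted = sorted(truth_ids - report_ids - set(report.skipped_samples))
    if unaccounted:
        raise ValueError(f"truth query samples missing from report: {unaccounted}")
    rows = []
    for result in report.results:
        planted = truth.sample_fractions.loc[result.sample_id]
        est_lab = result.fractions["potential_contaminant"]
        est_sea = result.fractions["seawater_influenced"]
        rows.append({
            "sample_id": result.sample_id,
            "true_laboratory": float(planted["true_laboratory"]),
            "estimated_laboratory": est_lab,
            "abs_error_laboratory": abs(est_lab - float(planted["true_laboratory"])),
            "true_seawater": float(planted["true_seawater"]),
            "estimated_seawater": est_sea,
            "abs_error_seawater": abs(est_sea - float(planted["true_seawater"])),
        })
    per_sample = pd.DataFrame(rows).set_index("sample_id") if rows else \
        pd.DataFrame(columns=["true_laboratory", "estimated_laboratory",
                              "abs_error_laboratory", "true_seawater",
                              "estimated_seawater", "abs_error_seawater"])
    out = EvaluationResult(
        per_sample=per_sample,
        mean_abs_error_laboratory=float(per_sample["abs_error_laboratory"].mean())
        if len(per_sample) else 0.0,
        mean_abs_error_seawater=float(per_sample["abs_error_seawater"].mean())
        if len(per_sample) else 0.0,
    )
    if db is not None:
        def _pr(recovered: frozenset[str], planted_set: set[str]):
            if not recovered:
                return (1.0 if not planted_set else 0.0,
                        0.0 if planted_set else 1.0)
            tp = len(recovered & planted_set)
            precision = tp / len(recovered)
            recall = tp / len(planted_set) if planted_set else 1.0
            return precision, recall
        out.laboratory_precision, out.laboratory_recall = _pr(
            db.laboratory_labels, set(truth.laboratory_orders))
        out.seawater_precision, out.seawater_recall = _pr(
            db.seawater_labels, set(truth.seawater_orders))
    return out


# ---------------------------------------------------------------------------
# Canned community specs
# ---------------------------------------------------------------------------

def default_community_spec() -> CommunitySpec:
    """Pools named after the packaged reference order lists.

    The laboratory pool is dominance-skewed toward Burkholderiales (the
    overamplification pattern of low-biomass controls); the seawater pool
    is close to even; the endemic pool uses orders commonly reported from
    subseafloor sediments, none of which appear in the reference lists.
    """
    from contamscreen.contamdb import load_reference_database

    ref = load_reference_database()
    lab_orders = sorted(ref.laboratory_labels)
    sea_orders = sorted(ref.seawater_labels)
    lab_weights = {}
    rest = [o for o in lab_orders if o != "Burkholderiales"]
    for i, o in enumerate(rest):
        lab_weights[o] = 0.4 * (0.9 ** i)
    lab_weights["Burkholderiales"] = 0.6 * sum(lab_weights.values()) / 0.4
    sea_weights = {o: 1.0 * (0.97 ** i) for i, o in enumerate(sea_orders)}
    endemic = {
        "Anaerolineales": 0.25,
        "Desulfobacterales": 0.20,
        "Atribacterales": 0.15,
        "Methanosarcinales": 0.12,
        "Aminicenantales": 0.10,
        "Dehalococcoidales": 0.10,
        "Thermoplasmatales": 0.08,
    }
    return CommunitySpec(
        pools={"laboratory": lab_weights, "seawater": sea_weights,
               "endemic": endemic},
        asvs_per_order=8,
        skew=0.7,
        dominant_skew=0.25,
        dominant_orders=frozenset({"Burkholderiales"}),
    )


def compact_community_spec() -> CommunitySpec:
    """Small disjoint pools, every order comfortably above a 1% pooled floor.

    Suitable for exact planted-database recovery and load-recovery checks:
    the three pools share no order, so a read's label identifies its source
    pool unambiguously.
    """
    return CommunitySpec(
        pools={
            "laboratory": {
                "Burkholderiales": 0.45,
                "Pseudomonadales": 0.20,
                "Xanthomonadales": 0.15,
                "Sphingomonadales": 0.12,
                "Staphylococcales": 0.08,
            },
            "seawater": {
                "Nitrosopumilales": 0.30,
                "SAR11 clade": 0.25,
                "Synechococcales": 0.20,
                "Rhodospirillales": 0.15,
                "Actinomarinales": 0.10,
            },
            "endemic": {
                "Anaerolineales": 0.30,
                "Desulfobacterales": 0.20,
                "Atribacterales": 0.15,
                "Methanosarcinales": 0.15,
                "Aminicenantales": 0.10,
                "Dehalococcoidales": 0.10,
            },
        },
        asvs_per_order=6,
        skew=0.7,
        dominant_skew=0.25,
        dominant_orders=frozenset({"Burkholderiales"}),
    )


# ---------------------------------------------------------------------------
# Scenario files and truth I/O
# ---------------------------------------------------------------------------

def load_scenario(path: str | Path) -> tuple[CommunitySpec, SimulationConfig]:
    """Read a YAML scenario with ``community`` and ``simulation`` sections."""
    with Path(path).open() as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "community" not in payload:
        raise ValueError(f"{path}: scenario must contain a 'community' section")
    comm = dict(payload["community"])
    if "dominant_orders" in comm:
        comm["dominant_orders"] = frozenset(comm["dominant_orders"])
    spec = CommunitySpec(**comm)
    sim = dict(payload.get("simulation", {}))
    if "depth_range" in sim:
        sim["depth_range"] = tuple(sim["depth_range"])
    config = SimulationConfig(**sim)
    return spec, config


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    out = truth.sample_fractions.copy()
    out["depth"] = truth.depths.reindex(out.index)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_truth_fractions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    required = {"role", "true_laboratory", "true_seawater", "true_endemic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: truth file missing columns {sorted(missing)}")
    return df
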