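import numpy as np
import pandas as pd
import pytest

from contamscreen.io_formats import (
    FeatureTable,
    Lineage,
    SampleManifest,
    TaxonomyTable,
)


def make_table(data: dict[str, dict[str, int]]) -> FeatureTable:
    """Build a FeatureTable from {feature: {sample: count}} (missing -> 0)."""
    df = pd.DataFrame(data).T.fillna(0).astype("int64")
    df.index.name = "feature_id"
    return FeatureTable(df)


def make_taxonomy(orders: dict[str, str | None]) -> TaxonomyTable:
    return TaxonomyTable({
        fid: Lineage(domain="Bacteria", order=order)
        for fid, order in orders.items()
    })


def make_manifest(roles: dict[str, tuple[str, str]]) -> SampleManifest:
    df = pd.DataFrame(
        [(sid, role, source) for sid, (role, source) in roles.items()],
        columns=["sample_id", "role", "source"],
    ).set_index("sample_id")
    return SampleManifest(df)


@pytest.fixture
def tiny_bundle():
    """Hand-computable bundle: 6 ASVs, 3 controls, 2 queries, 1 empty blank.

    Orders: Burkholderiales (laboratory-style, 2 ASVs), Pseudomonadales,
    Nitrosopumilales (seawater-style), Anaerolineales (endemic), and one
    ASV with no order assignment.
    """
    table = make_table({
        "b1": {"drill1": 60, "blank1": 30, "sw1": 5, "q1": 40, "q2": 10},
        "b2": {"drill1": 20, "blank1": 10, "q1": 10},
        "p1": {"drill1": 20, "blank1": 10, "sw1": 5, "q2": 10},
        "n1": {"sw1": 80, "q1": 20, "q2": 10},
        "a1": {"q1": 25, "q2": 65},
        "u1": {"q1": 5, "q2": 5, "drill1": 5},
    })
    taxonomy = make_taxonomy({
        "b1": "Burkholderiales", "b2": "Burkholderiales",
        "p1": "Pseudomonadales", "n1": "Nitrosopumilales",
        "a1": "Anaerolineales", "u1": None,
    })
    manifest = make_manifest({
        "drill1": ("control_I", "drill swab"),
        "blank1": ("control_II", "PCR blank"),
        "sw1": ("control_III", "seawater"),
        "q1": ("query", "sediment core"),
        "q2": ("query", "sediment core"),
        "zb1": ("control_II", "DNA extraction blank"),
    })
    # the empty blank: an all-zero column
    counts = table.counts.copy()
    counts["zb1"] = 0
    return FeatureTable(counts), taxonomy, manifest


def random_table(rng: np.random.Generator, n_features: int,
                 n_samples: int, max_count: int = 50) -> FeatureTable:
    counts = rng.integers(0, max_count + 1, size=(n_features, n_samples))
    # sprinkle zeros so occurrence varies
    mask = rng.random(counts.shape) < 0.4
    counts = np.where(mask, 0, counts)
    df = pd.DataFrame(
        counts,
        index=[f"f{i:03d}" for i in range(n_features)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    ).astype("int64")
    df.index.name = "feature_id"
    return FeatureTable(df)
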