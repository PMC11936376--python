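import numpy as np
import pandas as pd
import pytest

from contamscreen.abundance import UNASSIGNED
from contamscreen.contamdb import (
    ContaminantDatabase,
    OrderRecord,
    ScreeningConfig,
    load_reference_database,
)
from contamscreen.io_formats import FeatureTable, ValidationError
from contamscreen.screening import (
    LABELS,
    database_coverage,
    label_order,
    screen_samples,
    summarize_contamination,
)

from conftest import make_manifest, make_table, make_taxonomy
from oracles import bruteforce_label_fractions


def small_db():
    return ContaminantDatabase(
        laboratory=[OrderRecord("Burkholderiales"), OrderRecord("Pseudomonadales")],
        seawater=[OrderRecord("Nitrosopumilales"), OrderRecord("Pseudomonadales")],
    )


class TestLabelOrder:
    def test_reference_db_classifies_known_orders(self):
        db = load_reference_database()
        assert label_order("Burkholderiales", 0.40, db) == "potential_contaminant"
        assert label_order("Nitrosopumilales", 0.10, db) == "seawater_influenced"

    def test_below_threshold_wins_over_membership(self):
        db = small_db()
        config = ScreeningConfig(per_sample_threshold=0.01)
        assert label_order("Burkholderiales", 0.005, db, config) == "below_threshold"

    def test_unassigned_wins_over_everything(self):
        assert label_order(UNASSIGNED, 0.5, small_db()) == "unassigned"

    def test_order_in_both_sets_is_laboratory_precedence(self):
        assert label_order("Pseudomonadales", 0.2, small_db()) == \
            "potential_contaminant"

    def test_unknown_order_is_endemic(self):
        assert label_order("Anaerolineales", 0.2, small_db()) == "endemic"


class TestScreenSamples:
    def config(self, **kw):
        defaults = dict(min_reads=1, min_occurrence=1)
        defaults.update(kw)
        return ScreeningConfig(**defaults)

    def test_all_endemic_sample_has_zero_contamination(self):
        table = make_table({"a1": {"q1": 60, "q2": 60}, "a2": {"q1": 40, "q2": 40}})
        tax = make_taxonomy({"a1": "Anaerolineales", "a2": "Desulfobacterales"})
        manifest = make_manifest({"q1": ("query", "core"), "q2": ("query", "core")})
        report = screen_samples(table, tax, manifest, small_db(), self.config())
        for r in report.results:
            assert r.fractions["potential_contaminant"] == 0.0
            assert abs(sum(r.fractions.values()) - 1.0) < 1e-9

    def test_label_fractions_match_bruteforce_oracle(self, tiny_bundle):
        table, tax, manifest = tiny_bundle
        db = small_db()
        config = self.config()
        report = screen_samples(table, tax, manifest, db, config)
        for r in report.results:
            profile = {row["order"]: row["fraction"]
                       for _, row in r.detail.iterrows()}
            expected = bruteforce_label_fractions(
                profile, set(db.laboratory_labels), set(db.seawater_labels),
                config.per_sample_threshold, UNASSIGNED)
            for label in LABELS:
                assert r.fractions[label] == pytest.approx(expected[label])

    def test_zero_threshold_means_no_below_threshold_reads(self, tiny_bundle):
        table, tax, manifest = tiny_bundle
        report = screen_samples(table, tax, manifest, small_db(),
                                self.config(per_sample_threshold=0.0))
        assert all(r.fractions["below_threshold"] == 0.0 for r in report.results)

    def test_coverage_dominates_flagged_contamination(self, tiny_bundle):
        table, tax, manifest = tiny_bundle
        report = screen_samples(table, tax, manifest, small_db(), self.config())
        for r in report.results:
            flagged = (r.fractions["potential_contaminant"]
                       + r.fractions["seawater_influenced"])
            assert r.coverage >= flagged - 1e-12

    def test_zero_read_query_skipped_with_warning(self):
        table = make_table({"a1": {"q1": 10, "q2": 0}})
        tax = make_taxonomy({"a1": "Anaerolineales"})
        manifest = make_manifest({"q1": ("query", "core"), "q2": ("query", "core")})
        report = screen_samples(table, tax, manifest, small_db(), self.config())
        assert report.skipped_samples == ["q2"]
        assert report.sample_ids == ["q1"]

    def test_no_query_samples_is_error(self):
        table = make_table({"a1": {"c1": 10}})
        tax = make_taxonomy({"a1": "Anaerolineales"})
        manifest = make_manifest({"c1": ("control_I", "swab")})
        with pytest.raises(ValidationError, match="query"):
            screen_samples(table, tax, manifest, small_db(), self.config())

    def test_rank_mismatch_is_error(self):
        db = small_db()
        db.rank = "family"
        table = make_table({"a1": {"q1": 10}})
        tax = make_taxonomy({"a1": "Anaerolineales"})
        manifest = make_manifest({"q1": ("query", "core")})
        with pytest.raises(ValidationError, match="rank"):
            screen_samples(table, tax, manifest, db, self.config())

    def test_invariant_under_sample_and_feature_permutation(self, tiny_bundle):
        table, tax, manifest = tiny_bundle
        rng = np.random.default_rng(1)
        features = list(table.feature_ids)
        samples = list(table.sample_ids)
        rng.shuffle(features)
        rng.shuffle(samples)
        permuted = FeatureTable(table.counts.loc[features, samples])
        a = screen_samples(table, tax, manifest, small_db(), self.config())
        b = screen_samples(permuted, tax, manifest, small_db(), self.config())
        fa = {r.sample_id: r.fractions for r in a.results}
        fb = {r.sample_id: r.fractions for r in b.results}
        assert set(fa) == set(fb)
        for sid in fa:
            for label in LABELS:
                assert fa[sid][label] == pytest.approx(fb[sid][label])


class TestCoverage:
    def test_all_and_none_in_database(self):
        db = small_db()
        all_in = pd.Series({"Burkholderiales": 0.7, "Nitrosopumilales": 0.3})
        none_in = pd.Series({"Anaerolineales": 1.0})
        assert database_coverage(all_in, db) == 1.0
        assert database_coverage(none_in, db) == 0.0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(12)
        db = small_db()
        orders = ["Burkholderiales", "Nitrosopumilales", "Anaerolineales",
                  "Desulfobacterales", UNASSIGNED]
        fracs = rng.dirichlet(np.ones(len(orders)))
        profile = pd.Series(fracs, index=orders)
        expected = sum(f for o, f in profile.items() if o in db.all_labels)
        assert database_coverage(profile, db) == pytest.approx(expected)


class TestSummary:
    def _report_with_loads(self, loads):
        from contamscreen.screening import SampleScreeningResult, ScreeningReport
        results = []
        for i, x in enumerate(loads):
            fractions = {l: 0.0 for l in LABELS}
            fractions["potential_contaminant"] = x
            fractions["endemic"] = 1 - x
            results.append(SampleScreeningResult(
                sample_id=f"s{i}", fractions=fractions,
                detail=pd.DataFrame(), coverage=x, total_reads=1000))
        return ScreeningReport(results=results, config=ScreeningConfig())

    def test_counts_above_cutoff(self):
        report = self._report_with_loads([0.1, 0.3, 0.6])
        summary = summarize_contamination(report, cutoffs=[0.2])
        row = summary.iloc[0]
        assert row["n_above"] == 2
        assert row["n_at_or_below"] == 1
        assert row["fraction_above"] == pytest.approx(2 / 3)

    def test_empty_report_gives_zero_counts(self):
        report = self._report_with_loads([])
        summary = summarize_contamination(report, cutoffs=[0.2, 0.5])
        assert (summary["n_above"] == 0).all()
        assert (summary["n_samples"] == 0).all()

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(8)
        loads = rng.random(40).tolist()
        report = self._report_with_loads(loads)
        for cutoff in (0.2, 0.5, 0.9):
            summary = summarize_contamination(report, cutoffs=[cutoff])
            assert summary.iloc[0]["n_above"] == sum(1 for x in loads if x > cutoff)

    def test_exclude_seawater_switch(self):
        from contamscreen.screening import SampleScreeningResult, ScreeningReport
        fractions = {l: 0.0 for l in LABELS}
        fractions["seawater_influenced"] = 0.4
        fractions["endemic"] = 0.6
        report = ScreeningReport(
            results=[SampleScreeningResult("s0", fractions, pd.DataFrame(),
                                           0.4, 100)],
            config=ScreeningConfig())
        with_sea = summarize_contamination(report, cutoffs=[0.2])
        without = summarize_contamination(report, cutoffs=[0.2],
                                          include_seawater=False)
        assert with_sea.iloc[0]["n_above"] == 1
        assert without.iloc[0]["n_above"] == 0
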