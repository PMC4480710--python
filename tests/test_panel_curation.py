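"""Exclusion cascade, identity matching and TP53 functional classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdm2strat import panel_curation as pc
from mdm2strat.errors import ValidationError

CALL = st.sampled_from(["AA", "AB", "BB", "NC"])


def brute_force_match(a, b):
    matched = compared = 0
    for x, y in zip(a, b):
        if x in ("AA", "AB", "BB") and y in ("AA", "AB", "BB"):
            compared += 1
            matched += x == y
    return 100.0 * matched / compared if compared else float("nan")


class TestPercentGenotypeMatch:
    def test_identical_vectors(self):
        assert pc.percent_genotype_match(["AA", "AB", "BB"] * 4,
                                         ["AA", "AB", "BB"] * 4) == 100.0

    def test_fully_discordant(self):
        assert pc.percent_genotype_match(["AA"] * 6, ["BB"] * 6) == 0.0

    def test_hand_count_with_nocalls(self):
        a = ["AA"] * 10
        b = ["NC"] * 4 + ["AA"] * 5 + ["BB"]
        assert pc.percent_genotype_match(a, b) == pytest.approx(83.3333, abs=1e-3)

    def test_no_comparable_positions_undefined(self):
        assert np.isnan(pc.percent_genotype_match(["NC", "NC"], ["AA", "AA"]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pc.percent_genotype_match(["AA"], ["AA", "BB"])

    @given(st.lists(st.tuples(CALL, CALL), min_size=1, max_size=20))
    def test_matches_brute_force_and_symmetric(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        got = pc.percent_genotype_match(a, b)
        rev = pc.percent_genotype_match(b, a)
        want = brute_force_match(a, b)
        if np.isnan(want):
            assert np.isnan(got) and np.isnan(rev)
        else:
            assert got == pytest.approx(want) == pytest.approx(rev)


class TestResolveIdentity:
    def test_fixture_counts(self, default_fixture):
        fx = default_fixture
        live = fx.registry.loc[
            ~fx.registry["true_category"].isin(["poor_growth_or_cv", "no_dna"]),
            "line_id",
        ]
        res = pc.resolve_identity(
            fx.genotypes.loc[live], fx.reference_genotypes, 80.0
        )
        assert len(res.misidentified) == 5
        assert len(res.redundant) == 22

    def test_cluster_keeps_lexicographically_smallest(self):
        calls = ["AA", "AB", "BB", "AA", "AB"] * 20
        panel = pd.DataFrame(
            [calls, calls, ["BB"] * 100],
            index=["X2", "X1", "Y1"],
        )
        res = pc.resolve_identity(panel, panel.loc[[]], 80.0)
        assert res.synonymous_clusters == [["X1", "X2"]]
        assert res.redundant == {"X2"}
        assert res.misidentified == set()

    def test_no_pairs_above_threshold(self):
        rng = np.random.default_rng(0)
        panel = pd.DataFrame(
            rng.choice(["AA", "AB", "BB"], size=(4, 200), p=[0.36, 0.48, 0.16]),
            index=list("abcd"),
        )
        res = pc.resolve_identity(panel, panel, 80.0)
        assert not res.misidentified and not res.redundant

    def test_threshold_domain(self):
        panel = pd.DataFrame([["AA"]], index=["a"])
        with pytest.raises(ValidationError):
            pc.resolve_identity(panel, panel, 40.0)


class TestFlagViral:
    def test_detected_flag_excludes(self):
        rec = dict.fromkeys(pc.VIRAL_FLAG_COLUMNS, False) | {"hpv16": True}
        assert pc.flag_viral(rec) == (True, "hpv16")

    def test_all_negative_retained(self):
        rec = dict.fromkeys(pc.VIRAL_FLAG_COLUMNS, False)
        assert pc.flag_viral(rec) == (False, None)

    def test_fixture_has_8_viral_exclusions(self, curated_result):
        _, audit = curated_result
        assert audit.counts["viral"] == 8


class TestClassifyTp53:
    TABLE = pc.load_transactivation_table()

    def call(self, *args, **kw):
        return pc.MutationCall("TP53", *args, **kw)

    def test_functional_missense_is_wt(self):
        st = pc.classify_tp53([self.call("Q331R", "missense")], True, self.TABLE)
        assert st == pc.STATUS_WT

    def test_exon_deletion_is_mutant(self):
        st = pc.classify_tp53([self.call("E5_E8del", "deletion")], True, self.TABLE)
        assert st == pc.STATUS_MUTANT

    def test_heterozygous_inactivating(self):
        st = pc.classify_tp53(
            [self.call("R175H", "missense", zygosity="heterozygous")],
            True, self.TABLE,
        )
        assert st == pc.STATUS_HETEROZYGOUS

    def test_no_calls_is_wt(self):
        assert pc.classify_tp53([], True, self.TABLE) == pc.STATUS_WT

    def test_no_dna_is_unknown(self):
        assert pc.classify_tp53([], False, self.TABLE) == pc.STATUS_UNKNOWN

    def test_splice_disrupting_silent_forces_mutant(self):
        st = pc.classify_tp53([self.call("T125T", "silent")], True, self.TABLE)
        assert st == pc.STATUS_MUTANT

    def test_ordinary_silent_is_wt(self):
        st = pc.classify_tp53([self.call("L35L", "silent")], True, self.TABLE)
        assert st == pc.STATUS_WT

    def test_unknown_missense_defaults_non_functional(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mdm2strat.panel_curation"):
            st = pc.classify_tp53([self.call("A999V", "missense")], True, self.TABLE)
        assert st == pc.STATUS_MUTANT
        assert any("transactivation table" in r.message for r in caplog.records)

    def test_conflicting_calls_classify_mutant(self):
        st = pc.classify_tp53(
            [self.call("Q331R", "missense"), self.call("R196*", "nonsense")],
            True, self.TABLE,
        )
        assert st == pc.STATUS_MUTANT


class TestLowExpressionReannotation:
    def test_fixture_flags_exactly_the_planted_lines(self, default_fixture,
                                                     curated_result):
        curated, audit = curated_result
        planted = set(
            default_fixture.registry.loc[
                default_fixture.registry["true_category"] == "low_expression_wt",
                "line_id",
            ]
        )
        assert set(audit.reannotated) == planted
        flagged = curated[curated["reannotated"]]
        assert set(flagged["line_id"]) == planted
        assert (flagged["status"] == "MUTANT").all()

    def test_all_responsive_wt_flags_nothing(self):
        df = pd.DataFrame({
            "line_id": ["a", "b", "c"],
            "tp53_expression": [1.0, 5.0, 9.0],
            "censored": [False] * 3,
            "ic50_um": [0.1, 0.2, 0.3],
        })
        assert pc.flag_low_expression_wt(df) == []

    def test_zero_quantile_flags_nothing(self):
        df = pd.DataFrame({
            "line_id": ["a", "b"],
            "tp53_expression": [1.0, 5.0],
            "censored": [True, True],
            "ic50_um": [50.0, 50.0],
        })
        assert pc.flag_low_expression_wt(df, expr_quantile=0.0) == []


class TestCascade:
    def test_default_fixture_audit(self, curated_result):
        curated, audit = curated_result
        assert audit.survivors == 173
        assert [audit.counts[s] for s in pc.EXCLUSION_STAGES] == [26, 1, 5, 22, 8, 25]
        assert (curated["status"] == "WT").sum() == 58
        assert (curated["status"] == "MUTANT").sum() == 115

    def test_conservation(self, curated_result):
        _, audit = curated_result
        assert audit.survivors + sum(audit.counts.values()) == audit.n_input

    def test_idempotence(self, default_fixture, curated_result):
        curated, _ = curated_result
        fx = default_fixture
        again, audit2 = pc.apply_exclusion_cascade(
            curated.drop(columns=["status", "reannotated"]),
            fx.mutations, fx.genotypes, fx.reference_genotypes,
        )
        assert sum(audit2.counts.values()) == 0
        assert audit2.survivors == len(curated)
        merged = again.set_index("line_id")["status"]
        orig = curated.set_index("line_id")["status"]
        assert merged.sort_index().equals(orig.sort_index())

    def test_empty_registry(self):
        empty = pd.DataFrame(
            columns=["line_id", "tissue", "mean_count", "cv", "dna_available",
                     *pc.VIRAL_FLAG_COLUMNS, "tp53_expression", "ic50_um",
                     "censored", "auc"]
        )
        curated, audit = pc.apply_exclusion_cascade(empty, None)
        assert len(curated) == 0
        assert audit.survivors == 0 and sum(audit.counts.values()) == 0

    def test_membership_independent_of_stage_order(self):
        """A line failing several stages is excluded regardless of which stage
        claims it: the excluded set equals the union of per-stage failures."""
        rows = []
        rng = np.random.default_rng(2)
        for i in range(12):
            rows.append(dict(
                line_id=f"M{i:02d}", tissue="lung",
                mean_count=float(rng.uniform(500, 1500)),
                cv=0.5 if i % 3 == 0 else 0.05,  # some QC failures
                dna_available=i % 4 != 0,  # overlapping no-DNA failures
                **dict.fromkeys(pc.VIRAL_FLAG_COLUMNS, False),
                tp53_expression=8.0, ic50_um=1.0, censored=False, auc=0.4,
            ))
            if i % 2 == 0:
                rows[-1]["hpv18"] = True  # overlapping viral failures
        reg = pd.DataFrame(rows)
        curated, audit = pc.apply_exclusion_cascade(reg, None)
        expected_excluded = {
            r["line_id"] for r in rows
            if r["cv"] > 0.3 or not r["dna_available"] or r.get("hpv18", False)
        }
        assert set(reg["line_id"]) - set(curated["line_id"]) == expected_excluded
        # reason attribution follows cascade order: first failing stage wins
        ledger = audit.ledger.set_index("line_id")["stage"]
        for r in rows:
            if r["cv"] > 0.3:
                assert ledger[r["line_id"]] == "poor_growth_or_cv"
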