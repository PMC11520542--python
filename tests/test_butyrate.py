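import numpy as np
import pandas as pd
import pytest

from butyroscope import (
    ButyrateRuleSet,
    CommunityProfile,
    EnzymeContentTable,
    classify_butyrate_roles,
    compare_roles,
    role_abundances,
    simulate_community,
    simulate_enzyme_content,
)

PRODUCER = {"EC:2.8.3.-", "EC:2.8.3.9", "EC:2.8.3.8", "EC:2.7.2.7"}
CONSUMER_ALL = {"EC:2.8.3.8", "EC:1.3.8.1"}
CONSUMER_EITHER = {"EC:4.2.1.149", "EC:4.2.1.17"}
ALL_LABELS = sorted(PRODUCER | CONSUMER_ALL | CONSUMER_EITHER | {"EC:1.1.1.1"})


def table_from(assignments: dict) -> EnzymeContentTable:
    rows = [
        (taxon, ec, 1.0) for taxon, ecs in assignments.items() for ec in ecs
    ]
    # keep every taxon visible even with no enzymes
    for taxon, ecs in assignments.items():
        if not ecs:
            rows.append((taxon, "EC:9.9.9.9", 0.0))
    return EnzymeContentTable(
        pd.DataFrame(rows, columns=["taxon_id", "ec_label", "copy_value"])
    )


def oracle_roles(ecs: set) -> tuple:
    """Direct set-logic evaluation of the rule definitions."""
    producer = len(ecs & PRODUCER) > 0
    consumer = CONSUMER_ALL <= ecs and len(ecs & CONSUMER_EITHER) > 0
    return producer, consumer


class TestClassification:
    @pytest.mark.parametrize(
        "ecs,expected",
        [
            ({"EC:2.7.2.7"}, (True, False)),  # butyrate kinase alone: producer
            ({"EC:2.8.3.8", "EC:1.3.8.1", "EC:4.2.1.17"}, (True, True)),  # dual
            ({"EC:1.3.8.1", "EC:4.2.1.149"}, (False, False)),  # missing But
            (set(), (False, False)),
            ({"EC:2.8.3.-"}, (True, False)),  # partial label matched literally
            ({"EC:2.8.3.1"}, (False, False)),  # not expanded as a wildcard
        ],
    )
    def test_rule_examples(self, ecs, expected):
        cls = classify_butyrate_roles(table_from({"t": ecs}))
        if ecs:
            row = cls.flags.loc["t"]
            assert (row["is_producer"], row["is_consumer"]) == expected
        else:
            assert "t" not in cls.flags.index or not cls.flags.loc["t"].any()

    def test_prefix_match_mode(self):
        rules = ButyrateRuleSet(prefix_match=True)
        cls = classify_butyrate_roles(table_from({"t": {"EC:2.8.3.1"}}), rules)
        assert bool(cls.flags.loc["t", "is_producer"])

    def test_presence_threshold(self):
        table = EnzymeContentTable(
            pd.DataFrame(
                {
                    "taxon_id": ["t"],
                    "ec_label": ["EC:2.7.2.7"],
                    "copy_value": [0.0],
                }
            )
        )
        cls = classify_butyrate_roles(table)
        assert "t" not in cls.flags.index or not cls.flags.loc["t", "is_producer"]

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 6))
            assignments = {
                f"t{i}": set(
                    rng.choice(ALL_LABELS, size=rng.integers(0, 6), replace=False)
                )
                for i in range(n)
            }
            cls = classify_butyrate_roles(table_from(assignments))
            for taxon, ecs in assignments.items():
                want_p, want_c = oracle_roles(ecs)
                if taxon in cls.flags.index:
                    got_p = bool(cls.flags.loc[taxon, "is_producer"])
                    got_c = bool(cls.flags.loc[taxon, "is_consumer"])
                else:
                    got_p = got_c = False
                assert (got_p, got_c) == (want_p, want_c), (taxon, ecs)

    def test_adding_producer_enzyme_is_monotone(self, rng):
        for _ in range(100):
            ecs = set(rng.choice(ALL_LABELS, size=rng.integers(0, 5), replace=False))
            extra = str(rng.choice(sorted(PRODUCER)))
            before = classify_butyrate_roles(table_from({"t": ecs}))
            after = classify_butyrate_roles(table_from({"t": ecs | {extra}}))
            was = "t" in before.flags.index and bool(
                before.flags.loc["t", "is_producer"]
            )
            now = bool(after.flags.loc["t", "is_producer"])
            assert now >= was

    def test_recovers_synthetic_truth_without_dropout(self):
        profile, truth = simulate_community(seed=7)
        enzymes = simulate_enzyme_content(truth, dropout_rate=0.0, seed=7)
        cls = classify_butyrate_roles(enzymes)
        got_p = cls.flags["is_producer"].reindex(truth.taxa.index).fillna(False)
        got_c = cls.flags["is_consumer"].reindex(truth.taxa.index).fillna(False)
        assert (got_p == truth.taxa["is_producer"]).all()
        assert (got_c == truth.taxa["is_consumer"]).all()


def one_sample_profile(counts: dict) -> CommunityProfile:
    c = pd.DataFrame([counts], index=["s1"])
    tax = pd.DataFrame(
        {"Kingdom": "Bacteria"}, index=list(counts)
    )
    meta = pd.DataFrame({"group": ["A"]}, index=["s1"])
    return CommunityProfile(counts=c, taxonomy=tax, sample_meta=meta)


def classification_of(producers, consumers) -> "FunctionalClassification":
    from butyroscope import FunctionalClassification

    taxa = sorted(set(producers) | set(consumers))
    flags = pd.DataFrame(
        {
            "is_producer": [t in producers for t in taxa],
            "is_consumer": [t in consumers for t in taxa],
            "matched": [set() for _ in taxa],
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    return FunctionalClassification(flags)


class TestRoleAbundances:
    def test_basic_arithmetic(self):
        profile = one_sample_profile({"p": 50, "c": 25, "n": 25})
        cls = classification_of({"p"}, {"c"})
        res = role_abundances(profile, cls)
        row = res.table.loc["s1"]
        assert row["producer_abundance"] == pytest.approx(0.5)
        assert row["consumer_abundance"] == pytest.approx(0.25)
        assert row["ratio"] == pytest.approx(2.0)

    def test_no_consumers_gives_undefined_ratio(self):
        profile = one_sample_profile({"p": 50, "n": 50})
        res = role_abundances(profile, classification_of({"p"}, set()))
        assert np.isnan(res.table.loc["s1", "ratio"])
        assert len(res.defined_ratios()) == 0

    def test_dual_role_contributes_to_both_sums(self):
        profile = one_sample_profile({"d": 30, "n": 70})
        res = role_abundances(profile, classification_of({"d"}, {"d"}))
        row = res.table.loc["s1"]
        assert row["producer_abundance"] == pytest.approx(0.3)
        assert row["consumer_abundance"] == pytest.approx(0.3)
        assert row["ratio"] == pytest.approx(1.0)

    def test_subset_keeps_total_denominator(self):
        profile = one_sample_profile({"p1": 40, "p2": 40, "n": 20})
        cls = classification_of({"p1", "p2"}, set())
        res = role_abundances(profile, cls, subset_taxa=["p1"])
        assert res.table.loc["s1", "producer_abundance"] == pytest.approx(0.4)

    def test_uncovered_taxa_default_to_neither(self, tiny_profile):
        res = role_abundances(tiny_profile, classification_of({"t1"}, set()))
        assert (res.table["consumer_abundance"] == 0).all()

    def test_role_sum_bounds(self, rng):
        # producer + consumer abundance within [union, union + dual]
        profile, truth = simulate_community(seed=11)
        cls = truth.classification()
        res = role_abundances(profile, cls)
        union_taxa = truth.taxa.index[
            truth.taxa["is_producer"] | truth.taxa["is_consumer"]
        ]
        dual_taxa = truth.taxa.index[
            truth.taxa["is_producer"] & truth.taxa["is_consumer"]
        ]
        totals = profile.counts.sum(axis=1)
        union = profile.counts[union_taxa].sum(axis=1) / totals
        dual = profile.counts[dual_taxa].sum(axis=1) / totals
        both = res.table["producer_abundance"] + res.table["consumer_abundance"]
        assert ((both >= union - 1e-12) & (both <= union + dual + 1e-12)).all()


class TestCompareRoles:
    def _result(self, ratios):
        from butyroscope import RoleAbundanceResult

        table = pd.DataFrame(
            {
                "producer_abundance": ratios,
                "consumer_abundance": ratios,
                "ratio": ratios,
            },
            index=[f"s{i}" for i in range(len(ratios))],
        )
        return RoleAbundanceResult(table=table)

    def test_exact_enumeration_example(self):
        res = compare_roles(self._result([1, 2, 3]), self._result([4, 5, 6]))
        ratio_p = res.loc[res["quantity"] == "ratio", "p_value"].iloc[0]
        assert ratio_p == pytest.approx(0.1)
        assert (res.loc[res["quantity"] == "ratio", "method"] == "exact").all()

    def test_identical_groups_degenerate(self):
        res = compare_roles(self._result([1, 1, 1]), self._result([1, 1, 1]))
        assert (res["p_value"] == 1.0).all()
        assert res["degenerate"].all()

    def test_planted_depletion_detected(self):
        # single seed smoke check; the seed-sweep power test lives in the
        # acceptance suite
        profile, truth = simulate_community(seed=3)
        cls = truth.classification()
        groups = profile.sample_meta["group"]
        labels = list(dict.fromkeys(groups))
        res_all = role_abundances(profile, cls)
        from butyroscope import RoleAbundanceResult

        parts = [
            RoleAbundanceResult(res_all.table.loc[groups == g]) for g in labels
        ]
        res = compare_roles(parts[0], parts[1])
        ratio_p = res.loc[res["quantity"] == "ratio", "p_value"].iloc[0]
        assert ratio_p < 0.05
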