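import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from butyroscope import (
    CommunityProfile,
    PipelineConfig,
    agglomerate_taxa,
    bh_adjust,
    simulate_community,
    tss_log2_regression,
    wilcoxon_differential,
)


def bh_oracle(p):
    """Textbook step-up definition, implemented independently (O(m^2))."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        q = min(prev, p[i] * m / rank, 1.0)
        adjusted[i] = q
        prev = q
    return adjusted


def mw_enumeration_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    n1n2 = n1 * (len(pooled) - n1)
    dev_obs = abs(u_obs - n1n2 / 2)
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - n1n2 / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestBhAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_textbook_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            p = rng.uniform(size=20)
            np.testing.assert_allclose(
                bh_adjust(p),
                stats.false_discovery_control(p, method="bh"),
                atol=1e-12,
            )

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAgglomerate:
    def test_counts_summed_at_genus(self, tiny_profile):
        out = agglomerate_taxa(tiny_profile, "Genus")
        # t1 + t2 share genus G1: 10 + 5, 8 + 8, 0 + 12
        g1 = [c for c in out.taxon_ids if c.endswith("G1")][0]
        assert out.counts[g1].tolist() == [15, 16, 12]

    def test_unassigned_dropped_by_default(self, tiny_profile):
        out = agglomerate_taxa(tiny_profile, "Genus")
        assert out.n_taxa == 2  # t4 has no genus

    def test_unassigned_pooled_when_requested(self, tiny_profile):
        out = agglomerate_taxa(tiny_profile, "Genus", drop_unassigned=False)
        assert out.n_taxa == 3
        assert any("unassigned" in t for t in out.taxon_ids)

    def test_idempotent(self, tiny_profile):
        once = agglomerate_taxa(tiny_profile, "Genus")
        twice = agglomerate_taxa(once, "Genus")
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_total_reads_preserved_when_pooling(self, tiny_profile):
        out = agglomerate_taxa(tiny_profile, "Family", drop_unassigned=False)
        assert out.counts.sum().sum() == tiny_profile.counts.sum().sum()

    def test_invalid_rank(self, tiny_profile):
        with pytest.raises(ValueError):
            agglomerate_taxa(tiny_profile, "Strain")


def two_group_profile(counts_a, counts_b, taxa=None):
    counts_a, counts_b = np.atleast_2d(counts_a), np.atleast_2d(counts_b)
    rows = np.vstack([counts_a, counts_b])
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    samples = [f"a{i}" for i in range(len(counts_a))] + [
        f"b{i}" for i in range(len(counts_b))
    ]
    counts = pd.DataFrame(rows, index=samples, columns=taxa)
    tax = pd.DataFrame(
        {"Kingdom": "Bacteria", "Species": [f"sp_{t}" for t in taxa]},
        index=taxa,
    )
    groups = ["A"] * len(counts_a) + ["B"] * len(counts_b)
    meta = pd.DataFrame({"group": groups}, index=samples)
    return CommunityProfile(counts=counts, taxonomy=tax, sample_meta=meta), groups


class TestTssRegression:
    def test_identical_groups_null(self):
        row = [30, 30, 40]
        profile, groups = two_group_profile([row] * 3, [row] * 3)
        res = tss_log2_regression(profile, groups)
        assert (res.table["effect"] == 0).all()
        assert not res.table.get("significant", pd.Series(dtype=bool)).any()

    def test_noise_free_effect_is_log2_ratio(self):
        # proportions 0.1 (A) vs 0.4 (B) for t0 -> effect = log2(4) = 2
        profile, groups = two_group_profile(
            [[10, 90]] * 4, [[40, 60]] * 4
        )
        cfg = PipelineConfig(pseudocount=1e-9)
        res = tss_log2_regression(profile, groups, cfg)
        effect = res.table.set_index("taxon_id").loc["t0", "effect"]
        assert effect == pytest.approx(2.0, abs=1e-6)

    def test_low_prevalence_filtered(self):
        # t2 present in 1 of 25 samples: prevalence 0.04 < 0.05
        a = np.tile([50, 50, 0], (13, 1))
        b = np.tile([50, 50, 0], (12, 1))
        a[0, 2] = 5
        profile, groups = two_group_profile(a, b)
        res = tss_log2_regression(profile, groups)
        assert "t2" not in set(res.table["taxon_id"])
        assert {"t0", "t1"} <= set(res.table["taxon_id"])

    def test_p_matches_ols_t_test(self, rng):
        # coefficient t-test on a two-level indicator == pooled t-test;
        # cross-check against an explicit OLS fit via lstsq + t formula
        profile, groups = two_group_profile(
            rng.integers(10, 100, size=(6, 4)), rng.integers(10, 100, size=(5, 4))
        )
        cfg = PipelineConfig(pseudocount=1e-6)
        res = tss_log2_regression(profile, groups, cfg)
        props = profile.counts.div(profile.counts.sum(axis=1), axis=0)
        y_all = np.log2(props + 1e-6)
        x = np.column_stack([np.ones(11), [0] * 6 + [1] * 5])
        for rec in res.table.itertuples():
            y = y_all[rec.taxon_id].to_numpy()
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            sigma2 = resid @ resid / (len(y) - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), len(y) - 2)
            assert rec.effect == pytest.approx(beta[1], rel=1e-9)
            assert rec.p_raw == pytest.approx(p, rel=1e-9)


class TestWilcoxonDifferential:
    def test_total_count_500_pruned(self):
        # t1 totals exactly 500 -> pruned ("greater than 500" is strict)
        a = np.tile([1000, 125, 1000], (2, 1))
        b = np.tile([1000, 125, 1000], (2, 1))
        profile, groups = two_group_profile(a, b)
        res = wilcoxon_differential(profile, groups, ranks=("Species",))
        kept = set(res.table["taxon_id"].str.split(";").str[-1])
        assert not any("t1" in t for t in kept)

    def test_identical_groups_nothing_significant(self):
        row = [600, 700, 800]
        profile, groups = two_group_profile([row] * 3, [row] * 3)
        res = wilcoxon_differential(profile, groups, ranks=("Species",))
        assert not res.table["significant"].any()

    def test_exact_p_example(self):
        # per-taxon proportions {0.01,0.02,0.03} vs {0.04,0.05,0.06}
        # scaled to integer counts with constant totals
        a = [[100, 9900], [200, 9800], [300, 9700]]
        b = [[400, 9600], [500, 9500], [600, 9400]]
        profile, groups = two_group_profile(a, b)
        res = wilcoxon_differential(profile, groups, ranks=("Species",))
        t0 = res.table[res.table["taxon_id"].str.contains("t0")]
        assert t0["p_raw"].iloc[0] == pytest.approx(0.1)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(3, 8, size=2)
            x = rng.uniform(size=n1)
            y = rng.uniform(size=n2)
            from butyroscope._stats import rank_sum_test

            res = rank_sum_test(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(mw_enumeration_p(x, y), abs=1e-12)

    def test_planted_depletion_recovered_with_direction(self):
        profile, truth = simulate_community(seed=21)
        res = wilcoxon_differential(
            profile, profile.sample_meta["group"], ranks=("Species",)
        )
        planted = set(truth.taxa.index[truth.taxa["depleted"]])
        hits = res.table[
            res.table["taxon_id"].str.split(";sp_").str[-1].isin(planted)
            & (res.table["p_adj"] < 0.05)
        ]
        assert len(hits) >= 8
        assert (hits["direction"] == "depleted").all()

    def test_contrast_with_single_sample_skipped(self):
        a = [[600, 700]]
        b = [[600, 700], [650, 650], [700, 600]]
        profile, groups = two_group_profile(a, b)
        with pytest.warns(UserWarning):
            res = wilcoxon_differential(profile, groups, ranks=("Species",))
        assert len(res.table) == 0


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
@settings(max_examples=200, derandomize=True, deadline=None)
def test_bh_bounds_and_order_preservation(p):
    adj = bh_adjust(p)
    p = np.asarray(p)
    assert ((adj >= p - 1e-12) & (adj <= 1 + 1e-12)).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()
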