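"""Rank agglomeration and compositional differential-abundance tests.

Two complementary engines operate on total-sum-scaled (TSS) proportions:

* ``tss_log2_regression`` — per-taxon ordinary least squares of
  log2(proportion + pseudocount) on a two-level group indicator, after a
  minimum-prevalence filter; the fitted coefficient is the log2
  fold-change and its t statistic gives the p-value.
* ``wilcoxon_differential`` — the heat-tree matrix procedure: taxa are
  agglomerated at each requested rank, pruned at a total-count floor,
  converted to per-sample proportions, and every pair of groups is
  compared per taxon with a two-sided Wilcoxon rank-sum test; the effect
  is the difference of log2 median proportions.

Both report Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .config import PipelineConfig
from .io_core import RANKS, CommunityProfile


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorts ascending, scales p_(i) by m/i, enforces monotonicity from the
    largest down, caps at 1 and restores the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def default_pseudocount(proportions: pd.DataFrame) -> float:
    """Half the smallest nonzero proportion in the table."""
    vals = proportions.to_numpy()
    nz = vals[vals > 0]
    if nz.size == 0:
        return 0.5
    return float(nz.min() / 2.0)


def agglomerate_taxa(
    profile: CommunityProfile, rank: str, drop_unassigned: bool = True
) -> CommunityProfile:
    """Sum counts over taxa sharing the full lineage down to ``rank``.

    The agglomerated taxon id is the lineage joined with ``;``.  Taxa
    unassigned at ``rank`` are dropped by default, or pooled under an
    explicit ``unassigned`` lineage otherwise.  Idempotent.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    depth = RANKS.index(rank) + 1
    lineage_ranks = list(RANKS[:depth])
    tax = profile.taxonomy.copy()

    assigned = tax[rank].notna()
    if drop_unassigned:
        tax = tax[assigned]
    else:
        tax.loc[~assigned, lineage_ranks] = tax.loc[~assigned, lineage_ranks].fillna(
            "unassigned"
        )
    if not len(tax):
        raise ValueError(f"no taxa assigned at rank {rank!r}")

    lineage = tax[lineage_ranks].astype("string").fillna("unassigned")
    key = lineage.agg(";".join, axis=1)
    counts = profile.counts[tax.index].T.groupby(key, sort=True).sum().T
    new_tax = (
        lineage.assign(_key=key).drop_duplicates("_key").set_index("_key").sort_index()
    )
    for r in RANKS[depth:]:
        new_tax[r] = pd.NA
    new_tax.index.name = "taxon_id"
    return CommunityProfile(
        counts=counts, taxonomy=new_tax, sample_meta=profile.sample_meta
    )


@dataclass
class DifferentialResult:
    """Tidy per-taxon test records with a method tag."""

    table: pd.DataFrame  # taxon_id, rank, contrast, effect, p_raw, p_adj, direction...
    method: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] <= alpha]


def _two_groups(group_labels: pd.Series) -> tuple:
    levels = pd.unique(np.asarray(group_labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    return levels[0], levels[1]


def tss_log2_regression(
    profile: CommunityProfile,
    group_labels: Sequence,
    cfg: Optional[PipelineConfig] = None,
    rank: Optional[str] = None,
) -> DifferentialResult:
    """Per-taxon OLS of log2 TSS proportions on a two-group indicator.

    Taxa observed in fewer than ``cfg.min_prevalence`` of samples are
    removed before testing.  The effect is the fitted coefficient of the
    second group versus the first (log2 fold-change); its p-value comes
    from the coefficient's t statistic, equivalently the pooled-variance
    two-sample t-test.  BH adjustment is applied across taxa.
    """
    cfg = cfg or PipelineConfig()
    if rank is not None:
        profile = agglomerate_taxa(profile, rank)
    labels = pd.Series(list(group_labels), index=profile.sample_ids)
    ref, alt = _two_groups(labels)

    props = profile.proportions()
    prevalence = (profile.counts > 0).mean(axis=0)
    kept = prevalence.index[prevalence >= cfg.min_prevalence]
    props = props[kept]
    pc = cfg.pseudocount or default_pseudocount(props)
    log_props = np.log2(props + pc)

    mask_alt = (labels == alt).to_numpy()
    rows = []
    for taxon in kept:
        y = log_props[taxon].to_numpy()
        y_a, y_b = y[~mask_alt], y[mask_alt]
        effect = float(y_b.mean() - y_a.mean())
        if np.all(y == y[0]):
            p, degenerate = 1.0, True
        else:
            t = stats.ttest_ind(y_b, y_a, equal_var=True)
            p, degenerate = float(t.pvalue), False
            if not np.isfinite(p):  # zero pooled variance, nonzero effect
                p, degenerate = 0.0, False
        rows.append(
            {
                "taxon_id": taxon,
                "rank": rank or "input",
                "contrast": f"{alt} vs {ref}",
                "effect": effect,
                "p_raw": p,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        table["direction"] = np.where(table["effect"] >= 0, "enriched", "depleted")
        table["significant"] = table["p_adj"] <= cfg.alpha
    return DifferentialResult(table=table, method="tss_log2_regression")


def wilcoxon_differential(
    profile: CommunityProfile,
    group_labels: Sequence,
    cfg: Optional[PipelineConfig] = None,
    ranks: Sequence[str] = ("Species",),
) -> DifferentialResult:
    """Heat-tree-matrix Wilcoxon test over ranks and group contrasts.

    At each rank: agglomerate, prune taxa whose total count over all
    samples is not strictly greater than ``cfg.prune_total_min``,
    convert to per-sample proportions, and run a two-sided Wilcoxon
    rank-sum test per taxon for every pair of groups.  The effect is
    log2(median_A + pc) - log2(median_B + pc) of per-sample proportions.
    BH adjustment is applied within each contrast (all ranks pooled).
    """
    cfg = cfg or PipelineConfig()
    labels = pd.Series(list(group_labels), index=profile.sample_ids)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")

    rows = []
    for rank in ranks:
        sub = agglomerate_taxa(profile, rank) if rank in RANKS else profile
        totals = sub.counts.sum(axis=0)
        kept = totals.index[totals > cfg.prune_total_min]
        if not len(kept):
            continue
        pruned = sub.subset_taxa(kept)
        props = pruned.counts.div(pruned.counts.sum(axis=1), axis=0)
        pc = cfg.pseudocount or default_pseudocount(props)
        for i, ga in enumerate(levels):
            for gb in levels[i + 1 :]:
                in_a = (labels == ga).to_numpy()
                in_b = (labels == gb).to_numpy()
                if in_a.sum() < 2 or in_b.sum() < 2:
                    warnings.warn(
                        f"contrast {ga} vs {gb} skipped: fewer than 2 samples "
                        "in a group",
                        stacklevel=2,
                    )
                    continue
                for taxon in kept:
                    x = props.loc[in_a, taxon].to_numpy()
                    y = props.loc[in_b, taxon].to_numpy()
                    res = rank_sum_test(x, y)
                    effect = float(
                        np.log2(np.median(x) + pc) - np.log2(np.median(y) + pc)
                    )
                    rows.append(
                        {
                            "taxon_id": taxon,
                            "rank": rank,
                            "contrast": f"{ga} vs {gb}",
                            "effect": effect,
                            "p_raw": res.p_value,
                            "degenerate": res.degenerate,
                        }
                    )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = np.nan
        for contrast, idx in table.groupby("contrast").groups.items():
            table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p_raw"].to_numpy())
        # effect = log2(median first group) - log2(median second group), so a
        # positive effect means the taxon is depleted in the second (usually
        # treated) group of the contrast — matching the regression convention
        table["direction"] = np.where(table["effect"] > 0, "depleted", "enriched")
        table["significant"] = table["p_adj"] < cfg.alpha
    return DifferentialResult(table=table, method="wilcoxon_median_proportion")
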