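"""Butyrate producer/consumer classification and role-abundance statistics.

Gut bacteria are classified from their enzyme content into butyrate
*producers* and *consumers*.  A producer conserves at least one terminal
enzyme of a butyrate-producing pathway:

* 4Hbt, butyryl-CoA:4-hydroxybutyrate CoA transferase (``EC:2.8.3.-``)
* Ato, butyryl-CoA:acetoacetate CoA transferase (``EC:2.8.3.9``)
* But, butyryl-CoA:acetate CoA transferase (``EC:2.8.3.8``)
* Buk, butyrate kinase (``EC:2.7.2.7``)

A consumer conserves *each* of But (``EC:2.8.3.8``) and Acd, acyl-CoA
dehydrogenase (``EC:1.3.8.1``), plus at least one of Crt,
crotonobetainyl-CoA hydratase (``EC:4.2.1.149``) or Ech, enoyl-CoA
hydratase (``EC:4.2.1.17``).  Because But appears in both rules a taxon
can carry both roles (a dual producer/consumer); indeed every complete
consumer is also a producer under these definitions.

The per-sample summed relative abundance of producer-flagged and
consumer-flagged taxa, and their ratio, summarize a community's net
butyrate potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import RankTestResult, rank_sum_test
from .io_core import CommunityProfile, EnzymeContentTable, normalize_ec


@dataclass(frozen=True)
class ButyrateRuleSet:
    """EC-label rule sets defining producer and consumer roles.

    ``producer_any``: conserving any one label makes a producer.
    ``consumer_all``: every label required for a consumer...
    ``consumer_either``: ...plus at least one of these.
    ``presence_min``: copy value strictly above this counts as conserved.

    Partial labels such as ``EC:2.8.3.-`` are matched literally by
    default; ``prefix_match`` instead treats them as prefix wildcards
    (which would make every ``EC:2.8.3.x`` carrier a 4Hbt hit, so it is
    off by default).
    """

    producer_any: frozenset = field(
        default_factory=lambda: frozenset(
            {"EC:2.8.3.-", "EC:2.8.3.9", "EC:2.8.3.8", "EC:2.7.2.7"}
        )
    )
    consumer_all: frozenset = field(
        default_factory=lambda: frozenset({"EC:2.8.3.8", "EC:1.3.8.1"})
    )
    consumer_either: frozenset = field(
        default_factory=lambda: frozenset({"EC:4.2.1.149", "EC:4.2.1.17"})
    )
    presence_min: float = 0.0
    prefix_match: bool = False

    def __post_init__(self):
        for name in ("producer_any", "consumer_all", "consumer_either"):
            labels = getattr(self, name)
            if not labels:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, frozenset(normalize_ec(e) for e in labels))
        if self.presence_min < 0:
            raise ValueError("presence_min must be >= 0")

    @property
    def all_labels(self) -> frozenset:
        return self.producer_any | self.consumer_all | self.consumer_either


@dataclass
class FunctionalClassification:
    """Per-taxon producer/consumer flags with the enzymes that matched."""

    flags: pd.DataFrame  # index taxon_id; columns is_producer, is_consumer, matched

    def __post_init__(self):
        required = {"is_producer", "is_consumer", "matched"}
        if not required.issubset(self.flags.columns):
            raise ValueError(f"flags needs columns {sorted(required)}")

    @property
    def producers(self) -> pd.Index:
        return self.flags.index[self.flags["is_producer"]]

    @property
    def consumers(self) -> pd.Index:
        return self.flags.index[self.flags["is_consumer"]]

    @property
    def dual(self) -> pd.Index:
        both = self.flags["is_producer"] & self.flags["is_consumer"]
        return self.flags.index[both]

    def to_frame(self) -> pd.DataFrame:
        out = self.flags.copy()
        out["matched"] = out["matched"].map(lambda s: ";".join(sorted(s)))
        return out


def _matches(conserved: set, label: str, prefix_match: bool) -> bool:
    if label in conserved:
        return True
    if prefix_match and label.endswith(".-"):
        stem = label[: -1]  # keep trailing dot: "EC:2.8.3."
        return any(e.startswith(stem) for e in conserved)
    return False


def classify_butyrate_roles(
    enzymes: EnzymeContentTable, rules: Optional[ButyrateRuleSet] = None
) -> FunctionalClassification:
    """Apply the producer/consumer rules to each taxon's enzyme content.

    A taxon *conserves* an enzyme when its copy value exceeds
    ``rules.presence_min``.  ``is_producer`` requires any one of
    ``producer_any``; ``is_consumer`` requires all of ``consumer_all``
    and at least one of ``consumer_either``.  Deterministic.
    """
    rules = rules or ButyrateRuleSet()
    records = []
    data = enzymes.data
    conserved_by_taxon = (
        data[data["copy_value"] > rules.presence_min]
        .groupby("taxon_id")["ec_label"]
        .agg(set)
    )
    for taxon_id, conserved in conserved_by_taxon.items():
        hit_prod = {
            e for e in rules.producer_any if _matches(conserved, e, rules.prefix_match)
        }
        hit_all = {
            e for e in rules.consumer_all if _matches(conserved, e, rules.prefix_match)
        }
        hit_either = {
            e
            for e in rules.consumer_either
            if _matches(conserved, e, rules.prefix_match)
        }
        is_producer = bool(hit_prod)
        is_consumer = (len(hit_all) == len(rules.consumer_all)) and bool(hit_either)
        matched = set()
        if is_producer:
            matched |= hit_prod
        if is_consumer:
            matched |= hit_all | hit_either
        records.append((taxon_id, is_producer, is_consumer, matched))
    flags = pd.DataFrame(
        records, columns=["taxon_id", "is_producer", "is_consumer", "matched"]
    ).set_index("taxon_id")
    if not len(flags):
        flags = pd.DataFrame(
            columns=["is_producer", "is_consumer", "matched"],
            index=pd.Index([], name="taxon_id"),
        )
    return FunctionalClassification(flags)


@dataclass
class RoleAbundanceResult:
    """Per-sample producer/consumer relative abundances and their ratio.

    ``table`` columns: ``producer_abundance``, ``consumer_abundance``,
    ``ratio`` (NaN when the consumer sum is zero), indexed by sample id.
    ``subset`` tags which taxa entered the sums ("total" or a caller
    label such as "differential").
    """

    table: pd.DataFrame
    subset: str = "total"

    def defined_ratios(self) -> pd.Series:
        r = self.table["ratio"]
        return r[r.notna()]


def role_abundances(
    profile: CommunityProfile,
    classification: FunctionalClassification,
    subset_taxa: Optional[Sequence] = None,
    subset_label: Optional[str] = None,
) -> RoleAbundanceResult:
    """Summed relative abundance of producer- and consumer-flagged taxa.

    Per sample, producer (consumer) abundance is the summed count of
    flagged taxa within ``subset_taxa`` (default: all taxa) divided by
    the sample's total count over *all* taxa, keeping subset panels on a
    common denominator.  Dual-role taxa contribute to both sums.  The
    ratio producer/consumer is NaN where the consumer sum is zero; a
    zero-total sample yields NaN abundances with a warning.
    """
    taxa = profile.taxon_ids
    if subset_taxa is not None:
        subset = pd.Index(subset_taxa)
        unknown = subset.difference(taxa)
        if len(unknown):
            raise ValueError(f"subset taxa not in profile: {sorted(map(str, unknown))}")
    else:
        subset = taxa

    flags = classification.flags.reindex(taxa)
    is_prod = flags["is_producer"].astype("boolean").fillna(False).astype(bool)
    is_cons = flags["is_consumer"].astype("boolean").fillna(False).astype(bool)
    in_subset = taxa.isin(subset)

    counts = profile.counts
    totals = counts.sum(axis=1).astype(float)
    prod_sum = counts.loc[:, np.asarray(is_prod) & in_subset].sum(axis=1)
    cons_sum = counts.loc[:, np.asarray(is_cons) & in_subset].sum(axis=1)

    zero_total = totals == 0
    if zero_total.any():
        warnings.warn(
            f"samples with zero total count: {list(totals.index[zero_total])}",
            stacklevel=2,
        )
    totals = totals.where(~zero_total)
    prod_rel = prod_sum / totals
    cons_rel = cons_sum / totals
    ratio = prod_rel / cons_rel.where(cons_rel > 0)

    table = pd.DataFrame(
        {
            "producer_abundance": prod_rel,
            "consumer_abundance": cons_rel,
            "ratio": ratio,
        }
    )
    label = subset_label or ("total" if subset_taxa is None else "subset")
    return RoleAbundanceResult(table=table, subset=label)


def compare_roles(
    result_a: RoleAbundanceResult, result_b: RoleAbundanceResult
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of role abundances between two groups.

    Tests producer abundance, consumer abundance and the ratio
    (undefined ratios are excluded).  Returns one row per quantity with
    the U statistic, two-sided p, the method used and a degenerate flag.
    """
    rows = []
    for quantity in ("producer_abundance", "consumer_abundance", "ratio"):
        a = result_a.table[quantity].dropna().to_numpy()
        b = result_b.table[quantity].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"{quantity}: need at least 2 defined values per group "
                f"(got {a.size} and {b.size})"
            )
        res = rank_sum_test(a, b)
        rows.append(
            {
                "quantity": quantity,
                "n_a": a.size,
                "n_b": b.size,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
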