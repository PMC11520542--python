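"""Synthetic data generators with returned ground truth.

Every downstream stage of the pipeline can be exercised without real
sequencing data.  Communities are drawn from a Dirichlet-multinomial
model — the standard overdispersed model for 16S count data, whose
closed-form expected proportions double as test oracles — with a planted
multiplicative depletion of a producer clade in the treated group.
Enzyme annotations follow the producer/consumer rule sets with
controllable dropout; disease courses are bounded monotone random walks
on the 0-5 ordinal scale starting no earlier than day 10; butyrate
levels follow a linear fiber + producer:consumer-ratio model with
Gaussian noise.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .butyrate import ButyrateRuleSet, FunctionalClassification, role_abundances
from .config import PipelineConfig
from .io_core import RANKS, CommunityProfile, EnzymeContentTable
from .disease import DiseaseCourseTable

#: decoy EC labels never present in the butyrate rule sets
DECOY_ECS = ("EC:1.1.1.1", "EC:2.7.1.1", "EC:5.3.1.9", "EC:3.2.1.4", "EC:6.3.4.2")

_PHYLA_POOL = ("Bacteroidota", "Firmicutes", "Proteobacteria", "Actinobacteriota")


@dataclass(frozen=True)
class SyntheticCommunityConfig:
    """Study conditions for the simulated gut community.

    Defaults describe a mouse-gut-like community: 60 taxa, 10 samples
    per group, a dominant 10-taxon producer clade holding roughly a
    third of the reads (as Lachnospiraceae-type producers do in mouse
    feces), a Dirichlet total concentration of 150 (mild compositional
    overdispersion typical of co-housed inbred cohorts), and libraries
    of ~1e5 reads with negative-binomial depth variation.  Because the
    consumer rule requires But (EC:2.8.3.8), itself a producer enzyme,
    consumer taxa are producers too; ``fraction_dual`` adds taxa that
    additionally carry a second producer enzyme.
    """

    n_taxa: int = 60
    n_samples_per_group: int = 10
    group_labels: tuple = ("B6", "B6+Lr")
    base_concentration: Optional[Sequence[float]] = None
    total_concentration: float = 150.0
    producer_weight: float = 3.0
    depletion_effect: float = 0.25
    library_size_mean: float = 100_000.0
    library_size_dispersion: float = 20.0
    fraction_producers: float = 0.17
    fraction_consumers: float = 0.10
    fraction_dual: float = 0.05
    include_contaminants: bool = False
    timepoint: str = "D30"
    diet: str = "chow"

    def __post_init__(self):
        fr = self.fraction_producers + self.fraction_consumers + self.fraction_dual
        if fr > 1:
            raise ValueError("role fractions must sum to at most 1")
        if self.depletion_effect <= 0:
            raise ValueError("depletion_effect must be positive")
        if self.base_concentration is not None:
            conc = np.asarray(self.base_concentration, dtype=float)
            if len(conc) != self.n_taxa:
                raise ValueError("base_concentration length must equal n_taxa")
            if (conc <= 0).any():
                raise ValueError("base_concentration entries must be positive")
        if self.total_concentration <= 0 or self.producer_weight <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def n_producers(self) -> int:
        return int(round(self.fraction_producers * self.n_taxa))

    @property
    def n_consumers(self) -> int:
        return int(round(self.fraction_consumers * self.n_taxa))

    @property
    def n_dual(self) -> int:
        return int(round(self.fraction_dual * self.n_taxa))


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside synthetic data.

    ``taxa``: per-taxon role flags (consistent with the classification
    rules), the planted depletion flag and the multiplicative group
    effect; ``severity_shift``: the true mean clinical-score shift of
    the treated group; ``metabolite_coefs``: coefficients of the
    butyrate model once metabolites are simulated.
    """

    taxa: pd.DataFrame
    severity_shift: Optional[float] = None
    metabolite_coefs: Optional[dict] = None

    def classification(self) -> FunctionalClassification:
        """True role flags packaged as a classification result."""
        flags = self.taxa[["is_producer", "is_consumer"]].copy()
        flags["matched"] = [set() for _ in range(len(flags))]
        return FunctionalClassification(flags)


def _role_vector(cfg: SyntheticCommunityConfig) -> pd.Series:
    roles = ["none"] * cfg.n_taxa
    i = 0
    for role, count in (
        ("producer", cfg.n_producers),
        ("consumer", cfg.n_consumers),
        ("dual", cfg.n_dual),
    ):
        for _ in range(count):
            roles[i] = role
            i += 1
    return pd.Series(roles)


def _taxonomy_for(taxon_ids, roles: pd.Series, rng) -> pd.DataFrame:
    """Seven-rank labels; planted clades share Family/Genus."""
    tax = pd.DataFrame(index=taxon_ids, columns=list(RANKS), dtype=object)
    tax["Kingdom"] = "Bacteria"
    tax["Species"] = [f"sp_{t}" for t in taxon_ids]
    for i, (tid, role) in enumerate(zip(taxon_ids, roles)):
        if role == "producer":
            fam, gen, phy = "Lachnospiraceae", "Lachnospiraceae_NK4A136", "Firmicutes"
        elif role == "consumer":
            fam, gen, phy = "Lachnospiraceae", "Lachnospiraceae_UCG-010", "Firmicutes"
        elif role == "dual":
            fam, gen, phy = "Clostridiaceae", "ASF519_group", "Firmicutes"
        else:
            phy = _PHYLA_POOL[i % len(_PHYLA_POOL)]
            fam = f"Family_{phy[:4]}_{i % 7}"
            gen = f"Genus_{i % 11}" if i % 5 else None  # some unassigned genera
        tax.loc[tid, ["Phylum", "Class", "Order", "Family", "Genus"]] = [
            phy, f"Class_{phy[:4]}", f"Order_{fam[:6]}", fam, gen,
        ]
    return tax


def simulate_community(
    cfg: Optional[SyntheticCommunityConfig] = None, seed: int = 0
):
    """Draw a grouped Dirichlet-multinomial community with planted truth.

    Per sample the composition is Dirichlet(alpha_group) where
    alpha_treated multiplies the planted producer clade's concentrations
    by ``depletion_effect``; counts are multinomial with a
    negative-binomial library size.  Returns ``(profile, truth)``;
    deterministic under a fixed seed.
    """
    cfg = cfg or SyntheticCommunityConfig()
    rng = np.random.default_rng(seed)

    taxon_ids = [f"t{i:04d}" for i in range(1, cfg.n_taxa + 1)]
    roles = _role_vector(cfg)
    roles.index = taxon_ids

    if cfg.base_concentration is not None:
        alpha = np.asarray(cfg.base_concentration, dtype=float)
    else:
        w = np.ones(cfg.n_taxa)
        w[np.asarray(roles == "producer")] = cfg.producer_weight
        alpha = w / w.sum() * cfg.total_concentration
    depleted = np.asarray(roles == "producer")
    effect = np.where(depleted, cfg.depletion_effect, 1.0)

    counts, meta_rows = [], []
    for gi, group in enumerate(cfg.group_labels):
        alpha_g = alpha * (effect if gi > 0 else 1.0)
        for j in range(cfg.n_samples_per_group):
            comp = rng.dirichlet(alpha_g)
            disp = cfg.library_size_dispersion
            depth = rng.negative_binomial(
                disp, disp / (disp + cfg.library_size_mean)
            )
            depth = max(int(depth), 1000)
            counts.append(rng.multinomial(depth, comp))
            sid = f"{group}_{j + 1:02d}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "timepoint": cfg.timepoint,
                    "diet": cfg.diet,
                    "animal_id": f"A_{group}_{j + 1:02d}",
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    count_df = pd.DataFrame(counts, index=meta.index, columns=taxon_ids)
    taxonomy = _taxonomy_for(taxon_ids, roles, rng)

    if cfg.include_contaminants:
        extra = pd.DataFrame(
            {
                "x_arch": rng.poisson(30, size=len(count_df)),
                "x_cyano": rng.poisson(30, size=len(count_df)),
            },
            index=count_df.index,
        )
        count_df = pd.concat([count_df, extra], axis=1)
        taxonomy.loc["x_arch"] = ["Archaea", "Euryarchaeota"] + [None] * 5
        taxonomy.loc["x_cyano"] = ["Bacteria", "Cyanobacteria"] + [None] * 5

    profile = CommunityProfile(counts=count_df, taxonomy=taxonomy, sample_meta=meta)

    is_prod = roles.isin(["producer", "consumer", "dual"])  # consumer rule nests But
    is_cons = roles.isin(["consumer", "dual"])
    alpha_s = pd.Series(alpha, index=taxon_ids)
    truth_taxa = pd.DataFrame(
        {
            "role": roles,
            "is_producer": is_prod,
            "is_consumer": is_cons,
            "depleted": pd.Series(depleted, index=taxon_ids),
            "group_effect": pd.Series(effect, index=taxon_ids),
            "base_concentration": alpha_s,
            "mean_proportion_control": alpha_s / alpha_s.sum(),
            "mean_proportion_treated": alpha_s * effect / (alpha_s * effect).sum(),
        }
    )
    truth_taxa.index.name = "taxon_id"
    return profile, SyntheticTruth(taxa=truth_taxa)


def simulate_enzyme_content(
    truth: SyntheticTruth,
    dropout_rate: float = 0.0,
    seed: int = 0,
    producer_enzyme_count: int = 1,
    rules: Optional[ButyrateRuleSet] = None,
) -> EnzymeContentTable:
    """Assign rule-consistent enzymes to taxa, with annotation dropout.

    Producer-role taxa receive ``producer_enzyme_count`` producer
    enzymes (default one, so the retention probability under dropout d
    is exactly 1 - d); consumer-role taxa receive the full consumer set
    (But, Acd, and one of Crt/Ech); dual taxa receive both.  Every
    required annotation is then independently deleted with probability
    ``dropout_rate``.  All taxa additionally receive 1-3 decoy enzymes
    outside the rule sets.
    """
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must lie in [0, 1)")
    rules = rules or ButyrateRuleSet()
    rng = np.random.default_rng(seed)
    producer_pool = sorted(rules.producer_any)
    either_pool = sorted(rules.consumer_either)
    consumer_core = sorted(rules.consumer_all)

    rows = []
    for tid, rec in truth.taxa.iterrows():
        required = set()
        role = rec["role"]
        if role in ("producer", "dual"):
            k = min(producer_enzyme_count, len(producer_pool))
            required |= set(rng.choice(producer_pool, size=k, replace=False))
        if role in ("consumer", "dual"):
            required |= set(consumer_core)
            required.add(either_pool[int(rng.integers(len(either_pool)))])
        kept = {e for e in required if rng.random() >= dropout_rate}
        n_decoy = int(rng.integers(1, 4))
        decoys = set(rng.choice(DECOY_ECS, size=n_decoy, replace=False))
        for ec in sorted(kept | decoys):
            rows.append((tid, ec, float(rng.lognormal(0.0, 0.5))))
    return EnzymeContentTable(
        pd.DataFrame(rows, columns=["taxon_id", "ec_label", "copy_value"])
    )


def simulate_disease_courses(
    n_per_group: int = 10,
    severity_shift: float = 0.0,
    cfg: Optional[PipelineConfig] = None,
    seed: int = 0,
    group_labels: tuple = ("control", "treated"),
    base_peak: float = 2.5,
    peak_sd: float = 1.0,
    onset_spread: int = 5,
    p_rise: float = 0.6,
    step: float = 1.0,
    animal_ids: Optional[Sequence[Sequence[str]]] = None,
) -> DiseaseCourseTable:
    """Simulate daily ordinal disease courses for two (or more) groups.

    Each animal is scored 0 until a random onset day drawn uniformly
    from [onset_day, onset_day + onset_spread); from onset the score
    performs a monotone random walk (upward Bernoulli(p_rise) steps)
    until it reaches the animal's peak severity, then plateaus — the
    chronic course typical of this disease model.  Peaks are
    round(Normal(base_peak + severity_shift, peak_sd)) for treated
    groups, clipped to [0, score_max].  The scoring scale is integer by
    default; ``step=0.5`` allows half-point increments.
    """
    if severity_shift < 0:
        raise ValueError("severity_shift must be non-negative")
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    days = list(range(1, cfg.course_days + 1))
    rows, meta_rows = [], []
    for gi, group in enumerate(group_labels):
        shift = severity_shift if gi > 0 else 0.0
        for j in range(n_per_group):
            if animal_ids is not None:
                aid = animal_ids[gi][j]
            else:
                aid = f"A_{group}_{j + 1:02d}"
            onset = int(cfg.onset_day + rng.integers(0, onset_spread))
            peak = rng.normal(base_peak + shift, peak_sd)
            peak = float(np.clip(round(peak / step) * step, 0, cfg.score_max))
            score, course = 0.0, []
            for d in days:
                if d >= onset and score < peak:
                    score = min(peak, score + step * (rng.random() < p_rise))
                course.append(score)
            rows.append(pd.Series(course, index=days, name=aid))
            meta_rows.append({"animal_id": aid, "group": group})
    scores = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows).set_index("animal_id")
    return DiseaseCourseTable(scores=scores, meta=meta, score_max=cfg.score_max)


def simulate_metabolites(
    profile: CommunityProfile,
    truth: SyntheticTruth,
    diet_labels: Sequence,
    coef_fiber: float = 5.0,
    coef_ratio: float = 0.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    intercept: float = 1.0,
    high_fiber_label: str = "high_fiber",
    n_decoys: int = 10,
) -> pd.DataFrame:
    """Butyrate (mg/g feces) under a fiber + producer:consumer model.

    butyrate_s = intercept + coef_fiber * [diet is high fiber]
               + coef_ratio * ratio_s + Normal(0, noise_sd)

    where ratio_s is the sample's true producer:consumer abundance
    ratio.  Decoy metabolites are drawn from an unrelated lognormal null
    model.  Negative butyrate draws are clipped at zero.  Updates
    ``truth.metabolite_coefs`` in place and returns a samples x
    metabolites DataFrame.
    """
    if coef_fiber < 0 or noise_sd < 0:
        raise ValueError("coef_fiber and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    diet = pd.Series(list(diet_labels), index=profile.sample_ids)
    ratio = role_abundances(profile, truth.classification()).table["ratio"]
    ratio = ratio.fillna(0.0)
    fiber = (diet == high_fiber_label).astype(float)
    butyrate = (
        intercept
        + coef_fiber * fiber
        + coef_ratio * ratio
        + rng.normal(0.0, noise_sd, size=len(fiber))
    )
    table = pd.DataFrame({"butyrate": np.maximum(butyrate, 0.0)},
                         index=profile.sample_ids)
    for k in range(n_decoys):
        table[f"decoy_{k + 1:02d}"] = rng.lognormal(0.0, 1.0, size=len(fiber))
    truth.metabolite_coefs = {
        "intercept": intercept,
        "coef_fiber": coef_fiber,
        "coef_ratio": coef_ratio,
        "noise_sd": noise_sd,
    }
    return table
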