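"""Pipeline-wide thresholds and tuning knobs.

All analysis stages read their thresholds from a single
:class:`PipelineConfig` so that a study's filtering and significance
conventions are declared once and travel with the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds applied across the analysis pipeline.

    Parameters
    ----------
    prune_total_min:
        Taxa whose total count summed over all samples is not strictly
        greater than this value are pruned before the rank-based
        differential test (default 500 reads).
    min_prevalence:
        Minimum fraction of samples in which a taxon must be observed
        (count > 0) to enter the log2 regression (default 0.05).
    alpha:
        Significance level for adjusted p-values (default 0.05).
    fc_min:
        Fold-change magnitude a metabolite must exceed, in addition to
        ANOVA significance, to be flagged (default 1.5).
    r_min:
        Minimum absolute Pearson correlation for the metabolite-severity
        screen (default 0.2).
    score_max:
        Upper bound of the ordinal clinical scale (default 5).
    course_days:
        Length of the disease course in days (default 30).
    onset_day:
        First day on which clinical signs may appear; scores are zero
        before it (default 10).
    n_permutations:
        Number of label permutations for permutation tests (default 999).
    rng_seed:
        Seed recorded with permutation results for reproducibility.
    pseudocount:
        Offset added inside log2 transforms of proportions.  ``None``
        selects half the smallest nonzero proportion of the dataset at
        hand, which preserves the ordering of observed values.
    """

    prune_total_min: float = 500.0
    min_prevalence: float = 0.05
    alpha: float = 0.05
    fc_min: float = 1.5
    r_min: float = 0.2
    score_max: float = 5.0
    course_days: int = 30
    onset_day: int = 10
    n_permutations: int = 999
    rng_seed: int = 0
    pseudocount: Optional[float] = None
    excluded_phyla: frozenset = field(default_factory=lambda: frozenset({"Cyanobacteria"}))
    min_phylum_prevalence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.r_min < 1.0):
            raise ValueError(f"r_min must lie in (0, 1), got {self.r_min}")
        for name in ("prune_total_min", "min_prevalence", "fc_min", "score_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive when given")
        if self.course_days < 1 or self.onset_day < 1:
            raise ValueError("course_days and onset_day must be at least 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_phyla"] = sorted(self.excluded_phyla)
        return d
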