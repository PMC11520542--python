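"""Disease-course statistics and metabolite screens.

Animals in the autoimmune neuroinflammation model are scored daily on an
ordinal 0-5 scale (1 loss of tail tone ... 5 quadriplegia or death) over
a 30-day course, with signs appearing from day 10.  Summary statistics
are the cumulative disease score (CDS, the sum of daily scores) and the
trapezoidal area under the score curve (AUC).  Group comparisons use
rank-based tests: Mann-Whitney, Kruskal-Wallis with Dunn's post-hoc
z-tests, and a Friedman-style treatment x time interaction test on
within-day ranks.  Metabolite tables are screened with one-way ANOVA
plus a fold-change floor (Fisher's LSD post hoc) and with a Pearson
correlation filter against disease severity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .config import PipelineConfig
from .differential import bh_adjust


@dataclass
class DiseaseCourseTable:
    """Daily ordinal scores per animal.

    ``scores``: DataFrame indexed by animal id with one column per day
    (1..course_days); ``meta``: DataFrame indexed by animal id with at
    least a ``group`` column (optionally ``diet``).
    """

    scores: pd.DataFrame
    meta: pd.DataFrame
    score_max: float = 5.0

    def __post_init__(self):
        self.scores = self.scores.copy()
        self.scores.columns = [int(c) for c in self.scores.columns]
        self.meta = self.meta.loc[self.scores.index].copy()
        if "group" not in self.meta.columns or self.meta["group"].isna().any():
            raise ValueError("every animal needs a group label")
        vals = self.scores.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if (finite < 0).any() or (finite > self.score_max).any():
            raise ValueError(f"scores must lie in [0, {self.score_max}]")

    @property
    def days(self) -> list:
        return list(self.scores.columns)

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    def complete_scores(self, impute: bool = False) -> pd.DataFrame:
        """Scores with missing days rejected or carried forward."""
        s = self.scores
        if s.isna().any().any():
            if not impute:
                bad = list(s.index[s.isna().any(axis=1)])
                raise ValueError(
                    f"missing daily scores for animals {bad}; "
                    "pass impute=True for last-observation carry-forward"
                )
            s = s.ffill(axis=1).fillna(0.0)
        return s

    def to_long(self) -> pd.DataFrame:
        long = (
            self.scores.rename_axis("animal_id")
            .reset_index()
            .melt(id_vars="animal_id", var_name="day", value_name="score")
        )
        return long.merge(
            self.meta.rename_axis("animal_id").reset_index(), on="animal_id"
        ).sort_values(["animal_id", "day"], ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, score_max: float = 5.0):
        scores = long.pivot(index="animal_id", columns="day", values="score")
        meta_cols = [
            c for c in long.columns if c not in {"day", "score", "animal_id"}
        ]
        meta = long.drop_duplicates("animal_id").set_index("animal_id")[meta_cols]
        return cls(scores=scores, meta=meta, score_max=score_max)


def cumulative_disease_score(
    courses: DiseaseCourseTable, impute: bool = False
) -> pd.Series:
    """CDS per animal: the sum of its daily scores over the course."""
    return courses.complete_scores(impute).sum(axis=1).rename("cds")


def disease_auc(courses: DiseaseCourseTable, impute: bool = False) -> pd.Series:
    """Trapezoidal area under each animal's daily score curve (unit day)."""
    s = courses.complete_scores(impute)
    vals = s.to_numpy(dtype=float)
    auc = np.trapezoid(vals, dx=1.0, axis=1)
    return pd.Series(auc, index=s.index, name="auc")


def friedman_interaction_test(
    courses: DiseaseCourseTable,
    n_permutations: int = 999,
    seed: Optional[int] = None,
    method: str = "permutation",
) -> dict:
    """Treatment x time interaction test on within-day ranks.

    Scores are midrank-transformed across animals within each day and a
    split-plot two-way ANOVA (group, day, group x day; animal as the
    whole plot) is computed on the ranks.  The interaction F is referred
    to a permutation distribution obtained by shuffling group labels
    across animals (``method="permutation"``, default — ordinal courses
    are strongly autocorrelated, which breaks the sphericity the
    classical F reference assumes) or to the F distribution
    (``method="f"``).  Returns a dict with the interaction F, p, and the
    procedure metadata.
    """
    s = courses.complete_scores()
    groups = courses.groups
    codes = np.asarray(pd.Categorical(groups).codes, dtype=np.int64)
    n_groups = int(codes.max() + 1)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("need at least 2 animals per group")

    # within-day midranks, animals x days
    r = s.rank(axis=0, method="average").to_numpy(dtype=float)
    n_animals, n_days = r.shape

    def interaction_f(codes: np.ndarray) -> float:
        grand = r.mean()
        animal_means = r.mean(axis=1)
        day_means = r.mean(axis=0)
        onehot = np.eye(n_groups)[codes]  # animals x groups
        ng = onehot.sum(axis=0)
        group_means = (onehot.T @ r).sum(axis=1) / (ng * n_days)
        cell_means = (onehot.T @ r) / ng[:, None]  # groups x days

        ss_between_subj = n_days * ((animal_means - grand) ** 2).sum()
        ss_group = n_days * (ng * (group_means - grand) ** 2).sum()
        ss_day = n_animals * ((day_means - grand) ** 2).sum()
        ss_cells = (ng[:, None] * (cell_means - grand) ** 2).sum()
        ss_int = ss_cells - ss_group - ss_day
        ss_total = ((r - grand) ** 2).sum()
        ss_err = ss_total - ss_between_subj - ss_day - ss_int
        df_int = (n_groups - 1) * (n_days - 1)
        df_err = (n_days - 1) * (n_animals - n_groups)
        if ss_err <= 1e-12:
            return np.inf if ss_int > 1e-12 else 0.0
        return (ss_int / df_int) / (ss_err / df_err)

    f_obs = interaction_f(codes)
    df_int = (n_groups - 1) * (n_days - 1)
    df_err = (n_days - 1) * (n_animals - n_groups)

    if np.allclose(r.std(axis=0), 0.0):  # every day fully tied
        return {
            "f": 0.0, "p_value": 1.0, "df": (df_int, df_err),
            "method": "degenerate", "n_permutations": 0, "seed": seed,
        }

    if method == "f":
        p = float(stats.f.sf(f_obs, df_int, df_err))
        return {
            "f": float(f_obs), "p_value": p, "df": (df_int, df_err),
            "method": "rank-splitplot-F", "n_permutations": 0, "seed": seed,
        }
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        f = interaction_f(rng.permutation(codes))
        if f >= f_obs:
            count += 1
    return {
        "f": float(f_obs),
        "p_value": (1 + count) / (1 + n_permutations),
        "df": (df_int, df_err),
        "method": "rank-splitplot-F-permutation",
        "n_permutations": n_permutations,
        "seed": seed,
    }


def _dunn_posthoc(values: np.ndarray, codes: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests for all group pairs on pooled midranks.

    Uses the standard tie-corrected variance
    (N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j) with
    T = sum(t^3 - t) over tie groups; BH adjustment across pairs.
    """
    n = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))
    rows = []
    for i, j in combinations(range(codes.max() + 1), 2):
        ri, rj = ranks[codes == i], ranks[codes == j]
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / ri.size + 1.0 / rj.size)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (ri.mean() - rj.mean()) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def group_rank_tests(
    values: Sequence[float], groups: Sequence, mode: str = "mann_whitney"
) -> dict:
    """Rank-based group comparison of one value per animal/sample.

    ``mode="mann_whitney"``: two-sided rank-sum test for two groups,
    exact when both n <= 10 and tie-free.  ``mode="kruskal_dunn"``:
    tie-corrected Kruskal-Wallis H plus Dunn's pairwise z-tests with BH
    adjustment.
    """
    values = np.asarray(values, dtype=float)
    cat = pd.Categorical(list(groups))
    codes = np.asarray(cat.codes, dtype=np.int64)
    levels = list(cat.categories)
    sizes = np.bincount(codes)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        raise ValueError("need at least 2 values per group")

    if mode == "mann_whitney":
        if len(levels) != 2:
            raise ValueError("mann_whitney mode requires exactly 2 groups")
        res = rank_sum_test(values[codes == 0], values[codes == 1])
        return {
            "mode": "mann_whitney",
            "groups": levels,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "method": res.method,
            "degenerate": res.degenerate,
        }
    if mode == "kruskal_dunn":
        if np.all(values == values[0]):
            pairs = pd.DataFrame(
                [
                    {"group_i": i, "group_j": j, "z": 0.0, "p_raw": 1.0, "p_adj": 1.0}
                    for i, j in combinations(range(len(levels)), 2)
                ]
            )
            return {
                "mode": "kruskal_dunn", "groups": levels, "statistic": 0.0,
                "p_value": 1.0, "degenerate": True, "pairwise": pairs,
            }
        h, p = stats.kruskal(*[values[codes == k] for k in range(len(levels))])
        pairs = _dunn_posthoc(values, codes)
        pairs["group_i"] = pairs["group_i"].map(dict(enumerate(levels)))
        pairs["group_j"] = pairs["group_j"].map(dict(enumerate(levels)))
        return {
            "mode": "kruskal_dunn", "groups": levels, "statistic": float(h),
            "p_value": float(p), "degenerate": False, "pairwise": pairs,
        }
    raise ValueError(f"unknown mode {mode!r}")


def pearson_screen(
    metabolites: pd.DataFrame,
    severity: pd.Series,
    cfg: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Correlation screen of metabolites against a severity score.

    Per metabolite column: Pearson r against ``severity`` (pairwise
    complete observations) with a two-sided t-based p.  BH adjustment is
    applied across all columns screened in the one call, and a
    metabolite is retained only when |r| >= cfg.r_min AND p_adj <=
    cfg.alpha.  A zero-variance metabolite or severity raises.
    """
    cfg = cfg or PipelineConfig()
    severity = severity.loc[metabolites.index].astype(float)
    rows = []
    for name in metabolites.columns:
        x = metabolites[name].astype(float)
        mask = x.notna() & severity.notna()
        xv, yv = x[mask].to_numpy(), severity[mask].to_numpy()
        if xv.size < 3:
            raise ValueError(f"{name}: need at least 3 paired values")
        if np.std(xv) == 0 or np.std(yv) == 0:
            raise ValueError(f"{name}: undefined correlation (zero variance)")
        r, p = stats.pearsonr(xv, yv)
        rows.append({"metabolite": name, "n": xv.size, "r": float(r), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["retained"] = (out["r"].abs() >= cfg.r_min) & (out["p_adj"] <= cfg.alpha)
    return out


def metabolite_anova_lsd(
    table: pd.DataFrame,
    groups: Sequence,
    cfg: Optional[PipelineConfig] = None,
) -> dict:
    """One-way ANOVA metabolite screen with a fold-change floor.

    Per metabolite column of ``table`` (samples x metabolites, raw
    scale, NaN = missing): values are log-transformed and mean-centered,
    a one-way ANOVA F-test is run across groups, and the fold change is
    the largest ratio of group geometric means.  A metabolite is flagged
    when p <= cfg.alpha and the fold change exceeds cfg.fc_min (in
    either direction).  For flagged metabolites, pairwise Fisher LSD
    t-tests use the pooled ANOVA mean square error.  Returns
    ``{"screen": DataFrame, "lsd": DataFrame}``.
    """
    cfg = cfg or PipelineConfig()
    cat = pd.Categorical(list(groups))
    codes = pd.Series(np.asarray(cat.codes), index=table.index)
    levels = list(cat.categories)

    screen_rows, lsd_rows = [], []
    for name in table.columns:
        x = table[name].astype(float)
        ok = x.notna() & (x > 0)
        logx = np.log(x[ok])
        logx = logx - logx.mean()  # mean-center (does not change F)
        gcodes = codes[ok]
        by_group = [logx[gcodes == k].to_numpy() for k in range(len(levels))]
        present = [g for g in by_group if g.size >= 2]
        if len(present) < 2 or any(g.size < 2 for g in by_group):
            warnings.warn(
                f"{name}: fewer than 2 observations in some group; excluded",
                stacklevel=2,
            )
            continue
        if np.all(logx.to_numpy() == logx.to_numpy()[0]):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*by_group)
            f_stat, p = float(f_stat), float(p)
        gm = np.array([g.mean() for g in by_group])  # log geometric means (centered)
        max_log_ratio = gm.max() - gm.min()
        fold_change = float(np.exp(max_log_ratio))
        flagged = (p <= cfg.alpha) and (fold_change > cfg.fc_min)
        screen_rows.append(
            {
                "metabolite": name,
                "f": f_stat,
                "p_value": p,
                "fold_change": fold_change,
                "flagged": flagged,
            }
        )
        if flagged:
            n_total = sum(g.size for g in by_group)
            df_err = n_total - len(by_group)
            mse = sum(((g - g.mean()) ** 2).sum() for g in by_group) / df_err
            for i, j in combinations(range(len(levels)), 2):
                gi, gj = by_group[i], by_group[j]
                se = np.sqrt(mse * (1.0 / gi.size + 1.0 / gj.size))
                t = (gi.mean() - gj.mean()) / se if se > 0 else 0.0
                p_ij = 2.0 * stats.t.sf(abs(t), df_err) if se > 0 else 1.0
                lsd_rows.append(
                    {
                        "metabolite": name,
                        "group_i": levels[i],
                        "group_j": levels[j],
                        "t": float(t),
                        "p_value": float(p_ij),
                    }
                )
    return {
        "screen": pd.DataFrame(screen_rows),
        "lsd": pd.DataFrame(lsd_rows),
    }
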