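"""Seeded end-to-end analysis of a synthetic study.

Simulates a two-group community with a planted producer depletion,
enzyme content, disease courses and metabolites, then runs the full
downstream analysis: contaminant filtering, role classification and
ratio comparison, diversity and PERMANOVA, both differential-abundance
engines, disease-course statistics and the metabolite screens.  All
result tables are written as TSV with a fixed float format so that two
runs at the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import butyrate, differential, disease, diversity, io_core, synth
from .config import PipelineConfig

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(
    seed: int,
    outdir,
    cfg: Optional[PipelineConfig] = None,
    community_cfg: Optional[synth.SyntheticCommunityConfig] = None,
    severity_shift: float = 1.5,
    dropout_rate: float = 0.0,
    coef_fiber: float = 3.0,
    coef_ratio: float = 1.5,
    noise_sd: float = 0.25,
) -> dict:
    """Run the full synthetic study at one seed; returns summary numbers.

    Child seeds for each generator are derived from ``seed`` via
    ``numpy.random.SeedSequence.spawn``, so every stage is independently
    reproducible.
    """
    cfg = cfg or PipelineConfig()
    community_cfg = community_cfg or synth.SyntheticCommunityConfig(
        include_contaminants=True
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(seed).spawn(6)]

    # --- community -------------------------------------------------------
    profile, truth = synth.simulate_community(community_cfg, seed=seeds[0])
    io_core.write_community_profile(
        profile,
        outdir / "counts.tsv",
        outdir / "taxonomy.tsv",
        outdir / "metadata.tsv",
    )
    _write(truth.taxa, outdir / "truth_taxa.tsv")
    filtered = io_core.filter_contaminants(profile, cfg)

    # --- butyrate roles --------------------------------------------------
    enzymes = synth.simulate_enzyme_content(truth, dropout_rate, seed=seeds[1])
    io_core.write_enzyme_content(enzymes, outdir / "enzyme_content.tsv")
    classification = butyrate.classify_butyrate_roles(enzymes)
    _write(classification.to_frame(), outdir / "classification.tsv")

    groups = filtered.sample_meta["group"]
    labels = list(dict.fromkeys(groups))
    roles_all = butyrate.role_abundances(filtered, classification)
    _write(roles_all.table, outdir / "role_abundance.tsv")
    by_group = {
        g: butyrate.RoleAbundanceResult(
            roles_all.table.loc[groups == g], subset=roles_all.subset
        )
        for g in labels
    }
    role_tests = butyrate.compare_roles(by_group[labels[0]], by_group[labels[1]])
    _write(role_tests, outdir / "role_tests.tsv", index=False)

    # --- diversity -------------------------------------------------------
    alpha = diversity.alpha_diversity(filtered)
    _write(alpha.to_frame(), outdir / "alpha_diversity.tsv")
    dist = diversity.bray_curtis_matrix(filtered, normalize=True)
    _write(dist.to_frame(), outdir / "bray_curtis.tsv")
    perma = diversity.permanova(
        dist, groups, n_permutations=cfg.n_permutations, seed=seeds[2]
    )
    pd.DataFrame(
        [
            {
                "r_squared": perma.r_squared,
                "pseudo_f": perma.pseudo_f,
                "p_value": perma.p_value,
                "n_permutations": perma.n_permutations,
                "method": perma.method,
            }
        ]
    ).to_csv(outdir / "permanova.tsv", sep="\t", float_format=_FLOAT_FMT, index=False)

    # --- differential abundance -----------------------------------------
    tss = differential.tss_log2_regression(filtered, groups, cfg)
    _write(tss.table, outdir / "tss_regression.tsv", index=False)
    wilc = differential.wilcoxon_differential(
        filtered, groups, cfg, ranks=("Genus", "Species")
    )
    _write(wilc.table, outdir / "wilcoxon_differential.tsv", index=False)

    # --- disease course --------------------------------------------------
    animal_ids = [
        list(filtered.sample_meta.loc[groups == g, "animal_id"]) for g in labels
    ]
    courses = synth.simulate_disease_courses(
        n_per_group=community_cfg.n_samples_per_group,
        severity_shift=severity_shift,
        cfg=cfg,
        seed=seeds[3],
        group_labels=tuple(labels),
        animal_ids=animal_ids,
    )
    _write(courses.to_long(), outdir / "disease_courses.tsv", index=False)
    cds = disease.cumulative_disease_score(courses)
    auc = disease.disease_auc(courses)
    _write(pd.DataFrame({"cds": cds, "auc": auc}), outdir / "disease_summary.tsv")
    cds_test = disease.group_rank_tests(cds, courses.groups, mode="mann_whitney")
    friedman = disease.friedman_interaction_test(
        courses, n_permutations=cfg.n_permutations, seed=seeds[4]
    )

    # --- metabolites -----------------------------------------------------
    diet = pd.Series(
        ["high_fiber" if i % 2 else "low_fiber" for i in range(filtered.n_samples)],
        index=filtered.sample_ids,
    )
    metabolites = synth.simulate_metabolites(
        filtered, truth, diet,
        coef_fiber=coef_fiber, coef_ratio=coef_ratio, noise_sd=noise_sd,
        seed=seeds[5],
    )
    _write(metabolites, outdir / "metabolites.tsv")
    severity = pd.Series(cds.to_numpy(), index=filtered.sample_ids)
    screen = disease.pearson_screen(metabolites, severity, cfg)
    _write(screen, outdir / "pearson_screen.tsv", index=False)
    anova = disease.metabolite_anova_lsd(metabolites, diet, cfg)
    _write(anova["screen"], outdir / "metabolite_anova.tsv", index=False)
    _write(anova["lsd"], outdir / "metabolite_lsd.tsv", index=False)

    # --- summary ---------------------------------------------------------
    planted = truth.taxa.index[truth.taxa["depleted"]]
    wilc_species = wilc.table[wilc.table["rank"] == "Species"]
    planted_hits = wilc_species[
        wilc_species["taxon_id"].str.contains("|".join(planted))
        & (wilc_species["p_adj"] < cfg.alpha)
        & (wilc_species["direction"] == "depleted")
    ]
    ratio_row = role_tests[role_tests["quantity"] == "ratio"].iloc[0]
    but_row = screen[screen["metabolite"] == "butyrate"].iloc[0]
    summary = {
        "n_taxa_after_filter": int(filtered.n_taxa),
        "n_producers": int(classification.flags["is_producer"].sum()),
        "n_consumers": int(classification.flags["is_consumer"].sum()),
        "mean_ratio_control": float(
            by_group[labels[0]].defined_ratios().mean()
        ),
        "mean_ratio_treated": float(
            by_group[labels[1]].defined_ratios().mean()
        ),
        "ratio_p_value": float(ratio_row["p_value"]),
        "permanova_r_squared": float(perma.r_squared),
        "permanova_p_value": float(perma.p_value),
        "n_tss_significant": int(tss.table["significant"].sum()),
        "n_wilcoxon_significant": int(wilc.table["significant"].sum()),
        "planted_taxa_recovered": int(len(planted_hits)),
        "n_planted": int(len(planted)),
        "mean_cds_control": float(cds[courses.groups == labels[0]].mean()),
        "mean_cds_treated": float(cds[courses.groups == labels[1]].mean()),
        "cds_p_value": float(cds_test["p_value"]),
        "friedman_interaction_p": float(friedman["p_value"]),
        "butyrate_cds_r": float(but_row["r"]),
        "butyrate_retained": bool(but_row["retained"]),
        "n_metabolites_flagged": int(anova["screen"]["flagged"].sum()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
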