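"""End-to-end orchestration of the filter and analysis stages.

These helpers tie the library modules together the way the analysis
drivers and the command-line interface use them: build the averaged
control, filter a cohort table, and run the downstream statistics battery
(group PERMANOVA per fraction, fraction PERMANOVA, NMDS, paired ALR tests,
covariate-adjusted ALR-difference regression, cytokine-load associations)
over a filtered table plus metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .filtering import ControlSet, FilteredSample, average_controls, filter_table
from .metadata import SampleMetadata, metadata_frame
from .stats import (
    alr_table,
    alr_difference_regression,
    cytokine_association,
    distance_matrix,
    nmds,
    paired_wilcoxon_by_taxon,
    permanova,
)
from .tables import TaxaCountTable, relative_abundance

__all__ = ["controls_from_table", "filter_cohort", "AnalysisOutputs", "analyze_cohort"]

logger = logging.getLogger(__name__)


def controls_from_table(controls: TaxaCountTable) -> ControlSet:
    """Average the negative-control columns of a count table."""
    profiles = [controls.profile(s) for s in controls.samples]
    return average_controls([p for p in profiles if not p.is_empty])


def filter_cohort(
    counts: TaxaCountTable,
    controls: TaxaCountTable,
    config: AnalysisConfig | None = None,
) -> tuple[TaxaCountTable, list[FilteredSample]]:
    overlap = set(counts.samples) & set(controls.samples)
    if overlap:
        raise ValueError(f"control samples also present in the experimental table: {sorted(overlap)}")
    return filter_table(counts, controls_from_table(controls), config)


@dataclass
class AnalysisOutputs:
    """Tables produced by the downstream statistics battery."""

    permanova: pd.DataFrame
    nmds: pd.DataFrame
    alr_tests: pd.DataFrame
    alr_regression: pd.DataFrame | None
    cytokine_assoc: pd.DataFrame | None


def _nonempty_samples(counts: TaxaCountTable) -> list[str]:
    depths = counts.depths()
    empty = [s for s in counts.samples if depths[s] == 0]
    if empty:
        logger.warning("excluding %d zero-read sample(s) from statistics: %s", len(empty), empty)
    return [s for s in counts.samples if depths[s] > 0]


def analyze_cohort(
    counts: TaxaCountTable,
    metadata: list[SampleMetadata],
    config: AnalysisConfig | None = None,
) -> AnalysisOutputs:
    """Run the full downstream battery on a (filtered) count table."""
    config = config or AnalysisConfig()
    meta = metadata_frame(metadata)
    keep = [s for s in _nonempty_samples(counts) if s in meta.index]
    counts = counts.subset_samples(keep)
    meta = meta.loc[keep]
    profiles = relative_abundance(counts)

    perm_rows = []
    nmds_rows = []
    rng = config.stage_rng("permanova")

    # Fraction comparison (bound vs raw) over every analysed sample.
    both = meta[meta["fraction"].isin(["raw", "igg_bound"])]
    if both["fraction"].nunique() == 2:
        dm = distance_matrix(profiles[both.index], metric=config.distance_metric)
        res = permanova(dm, both["fraction"], n_permutations=config.n_permutations, rng=rng)
        perm_rows.append(
            {
                "analysis": "fraction:all",
                "term": "fraction",
                "df": res.df_between,
                "SS": res.ss_between,
                "pseudo_F": res.pseudo_f,
                "R2": res.r2,
                "p": res.p_value,
                "method": res.method,
            }
        )
        ord_res = nmds(
            dm,
            n_components=config.nmds_dimensions,
            restarts=config.nmds_restarts,
            seed=config.rng_seed,
            grouping=both["fraction"],
        )
        block = ord_res.coordinates.copy()
        block.insert(0, "analysis", "fraction:all")
        block["stress"] = ord_res.stress
        nmds_rows.append(block)

    # Group comparison within each fraction, adjusted for covariates when present.
    covar_cols = [c for c in ("sex", "age", "pack_years") if meta[c].notna().all()]
    for fraction, sub in meta.groupby("fraction"):
        if sub["group"].nunique() < 2 or sub.groupby("group").size().min() < 2:
            continue
        dm = distance_matrix(profiles[sub.index], metric=config.distance_metric)
        covariates = sub[covar_cols] if covar_cols else None
        res = permanova(
            dm,
            sub["group"],
            covariates=covariates,
            n_permutations=config.n_permutations,
            rng=rng,
        )
        perm_rows.append(
            {
                "analysis": f"group:{fraction}",
                "term": "group",
                "df": res.df_between,
                "SS": res.ss_between,
                "pseudo_F": res.pseudo_f,
                "R2": res.r2,
                "p": res.p_value,
                "method": res.method,
            }
        )

    # Paired ALR testing: bound vs raw per taxon.
    alr = alr_table(profiles, eps=config.pseudocount, reference=config.alr_reference)
    pairs_df = meta.reset_index().pivot_table(
        index="pair_id", columns="fraction", values="sample_id", aggfunc="first"
    )
    alr_tests = pd.DataFrame()
    alr_reg = None
    if {"raw", "igg_bound"}.issubset(pairs_df.columns):
        complete = pairs_df.dropna(subset=["raw", "igg_bound"])
        pairs = list(zip(complete["igg_bound"], complete["raw"]))
        if len(pairs) >= 3:
            alr_tests = paired_wilcoxon_by_taxon(alr, alr, pairs)
            diffs = pd.DataFrame(
                {
                    pid: alr[b].to_numpy() - alr[r].to_numpy()
                    for pid, (b, r) in zip(complete.index, pairs)
                },
                index=alr.index,
            )
            cov = meta.loc[complete["igg_bound"], ["group"] + covar_cols]
            cov.index = complete.index
            if cov["group"].nunique() >= 2:
                alr_reg = alr_difference_regression(diffs, cov)
            else:
                logger.warning("single group; skipping ALR-difference regression")
        else:
            logger.warning("fewer than 3 complete pairs; skipping paired ALR tests")

    # Cytokine vs load associations on IgG-bound samples of the disease group.
    cyt_rows = []
    cytokine_cols = [c for c in meta.columns if c.startswith("cytokine_")]
    measures = [m for m in ("qpcr_copies", "flow_events") if m in meta.columns]
    bound = meta[meta["fraction"] == "igg_bound"]
    subsets = {"all": bound}
    if bound["group"].nunique() >= 2:
        subsets.update({g: sub for g, sub in bound.groupby("group")})
    for subset_name, subset in subsets.items():
        for measure in measures:
            for col in cytokine_cols:
                sub = subset[[measure, col]].dropna()
                sub = sub[(sub[measure] > 0)]
                if len(sub) < 3:
                    logger.warning("skipping %s ~ %s: fewer than 3 complete pairs", col, measure)
                    continue
                reg = cytokine_association(sub[measure], sub[col])
                cyt_rows.append(
                    {
                        "subset": subset_name,
                        "cytokine": col.removeprefix("cytokine_"),
                        "measure": measure,
                        "slope": reg.slope,
                        "R2": reg.r2,
                        "p": reg.p_value,
                        "n": reg.n,
                    }
                )
    cyt = pd.DataFrame(cyt_rows) if cyt_rows else None

    return AnalysisOutputs(
        permanova=pd.DataFrame(perm_rows),
        nmds=pd.concat(nmds_rows) if nmds_rows else pd.DataFrame(),
        alr_tests=alr_tests,
        alr_regression=alr_reg,
        cytokine_assoc=cyt,
    )
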