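"""Synthetic paired unsorted / IgG-bound BAL cohorts with known contamination.

The generator runs the contaminant mixture model forward so that every
pipeline stage has ground truth: a participant's true community actExp is
drawn Dirichlet around a fraction-specific template (oral-taxon-dominated
for unsorted BAL, Pseudomonas-enriched for the IgG-bound fraction), mixed
with a reagent/column contaminant profile at a known proportion p_true,

    obsExp = (1 - p_true) * actExp + p_true * actCont,

and read counts are drawn multinomially at a log-normal sequencing depth.
Negative-control columns are multinomial draws from the contaminant profile
itself.  A disease-group effect enters as a log-linear shift applied to the
IgG-bound template only, and per-participant cytokine concentrations are
log-linearly coupled to the true IgG-bound bacterial load in the disease
group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import stage_rng
from .errors import ValidationError
from .metadata import SampleMetadata, metadata_frame
from .tables import TaxaCountTable, TaxaProfile

__all__ = [
    "CommunityTemplate",
    "SimulationParams",
    "GroundTruth",
    "Cohort",
    "make_templates",
    "simulate_sample_pair",
    "simulate_cytokines",
    "simulate_cohort",
    "write_cohort",
]

# Anchor genera that are always present, mirroring the dominant members of
# unsorted (oral anaerobes) and IgG-bound (Pseudomonas) BAL communities.
ANCHOR_TAXA = ("Streptococcus", "Prevotella", "Veillonella", "Pseudomonas", "Tropheryma")

_COMMUNITY_POOL = (
    "Stenotrophomonas", "Rothia", "Neisseria", "Haemophilus", "Fusobacterium",
    "Gemella", "Granulicatella", "Porphyromonas", "Actinomyces", "Staphylococcus",
    "Corynebacterium", "Moraxella", "Lactobacillus", "Capnocytophaga", "Leptotrichia",
    "Campylobacter", "Selenomonas", "Atopobium", "Megasphaera", "Oribacterium",
)

# Typical reagent/kitome genera used for contaminant-only taxa.
_REAGENT_POOL = (
    "Ralstonia", "Sphingomonas", "Bradyrhizobium", "Burkholderia", "Methylobacterium",
    "Delftia", "Comamonas", "Pelomonas", "Cutibacterium", "Acinetobacter",
)

_RAW_ANCHOR_WEIGHTS = {
    "Streptococcus": 0.24,
    "Prevotella": 0.18,
    "Veillonella": 0.13,
    "Tropheryma": 0.07,
    "Pseudomonas": 0.02,
}
_IGG_ANCHOR_WEIGHTS = {
    "Pseudomonas": 0.32,
    "Streptococcus": 0.09,
    "Prevotella": 0.06,
    "Veillonella": 0.04,
    "Tropheryma": 0.01,
}

# Disease-group shift on the IgG-bound template (natural-log effects):
# more IgG-bound Pseudomonas/Stenotrophomonas and fewer oral taxa.
_DEFAULT_GROUP_SHIFT = {
    "Pseudomonas": 1.0,
    "Stenotrophomonas": 0.8,
    "Prevotella": -0.5,
    "Veillonella": -0.4,
}


@dataclass(frozen=True)
class CommunityTemplate:
    """Base community, contaminant profile, and the group's log-shift."""

    taxa: tuple[str, ...]
    base_raw: TaxaProfile
    base_igg: TaxaProfile
    contaminant: TaxaProfile
    group_shift: pd.Series = field(repr=False)

    def shifted_igg(self) -> TaxaProfile:
        """IgG-bound template with the disease-group log-shift applied."""
        shift = self.group_shift.reindex(self.base_igg.series.index, fill_value=0.0)
        shifted = self.base_igg.series * np.exp(shift)
        return TaxaProfile(shifted / shifted.sum())


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: 22 uninfected and 42 disease-group
    participants, log-normal depth with median 2e4 reads, Dirichlet
    overdispersion theta = 50, contaminant admixture p_true ~ Beta(2, 5),
    and cytokines coupled to the IgG-bound load with slope 0.5 and noise
    0.3 (natural-log scale) in the disease group only.
    """

    n_uninfected: int = 22
    n_disease: int = 42
    depth_median: float = 2e4
    depth_cv: float = 0.6
    theta: float = 50.0
    p_beta_a: float = 2.0
    p_beta_b: float = 5.0
    n_controls: int = 4
    control_depth_median: float = 3e3
    load_log_mean_uninfected: float = 9.0
    load_log_mean_disease: float = 10.5
    load_log_sd: float = 1.5
    cytokine_alpha: float = -2.0
    cytokine_beta: float = 0.5
    cytokine_sigma: float = 0.3
    measurement_sigma: float = 0.2
    cytokine_names: tuple[str, ...] = ("IL-8", "IL-1b")
    group_labels: tuple[str, str] = ("hiv_neg", "plwh")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("depth_median", "depth_cv", "theta", "p_beta_a", "p_beta_b",
                     "control_depth_median", "load_log_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.cytokine_sigma < 0 or self.measurement_sigma < 0:
            raise ValidationError("noise scales must be >= 0")
        if self.n_uninfected < 0 or self.n_disease < 0:
            raise ValidationError("participant counts must be >= 0")
        if self.n_controls < 2:
            raise ValidationError("need at least 2 negative-control columns")


@dataclass
class GroundTruth:
    """Latent state of the simulation, enough to rebuild every observation.

    ``samples`` holds one row per sequenced sample (p_true, depth, fraction,
    pairing); ``act_profiles`` the true uncontaminated profiles (taxa by
    sample); ``contaminant`` the true contaminant profile shared by all
    samples; ``participants`` per-participant load and cytokine-model rows.
    """

    samples: pd.DataFrame
    act_profiles: pd.DataFrame
    contaminant: TaxaProfile
    participants: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long single-table serialisation (one row per sample x taxon)."""
        long = (
            self.act_profiles.stack()
            .rename("act_abundance")
            .rename_axis(["taxon", "sample_id"])
            .reset_index()
        )
        cont = self.contaminant.series.rename("cont_abundance").rename_axis("taxon").reset_index()
        long = long.merge(cont, on="taxon", how="left").fillna({"cont_abundance": 0.0})
        long = long.merge(self.samples.reset_index(), on="sample_id")
        long = long.merge(self.participants.reset_index(), on="pair_id", how="left")
        return long


@dataclass
class Cohort:
    counts: TaxaCountTable
    controls: TaxaCountTable
    metadata: list[SampleMetadata]
    truth: GroundTruth
    template: CommunityTemplate


def _spread(rng: np.random.Generator, taxa: list[str], mass: float) -> pd.Series:
    if not taxa:
        return pd.Series(dtype=float)
    weights = rng.dirichlet(np.full(len(taxa), 1.0))
    return pd.Series(mass * weights, index=taxa)


def make_templates(n_taxa: int = 25, overlap: float = 0.3, seed: int = 0) -> CommunityTemplate:
    """Build deterministic community/contaminant templates.

    ``overlap`` is the fraction of contaminant taxa shared with the
    community (0 = reagent-only contaminant, 1 = contaminant support inside
    the community support).
    """
    if n_taxa < 5:
        raise ValidationError("need at least 5 taxa (the anchor genera)")
    if not 0.0 <= overlap <= 1.0:
        raise ValidationError("overlap must lie in [0, 1]")
    rng = stage_rng(seed, "templates")

    extra = [t for t in _COMMUNITY_POOL][: n_taxa - len(ANCHOR_TAXA)]
    n_generic = n_taxa - len(ANCHOR_TAXA) - len(extra)
    extra += [f"Taxon_{i:03d}" for i in range(n_generic)]
    community = list(ANCHOR_TAXA) + extra

    n_cont = max(3, n_taxa // 3)
    n_shared = int(round(overlap * n_cont))
    shared = list(rng.choice(community, size=min(n_shared, len(community)), replace=False))
    reagent_only = list(_REAGENT_POOL)[: n_cont - len(shared)]
    reagent_only += [f"Reagent_{i:03d}" for i in range(n_cont - len(shared) - len(reagent_only))]
    cont_taxa = shared + reagent_only

    taxa = tuple(community + reagent_only)

    def base(anchors: dict[str, float]) -> TaxaProfile:
        filler = [t for t in community if t not in anchors]
        series = pd.concat([pd.Series(anchors), _spread(rng, filler, 1.0 - sum(anchors.values()))])
        series = series.reindex(taxa, fill_value=0.0)
        return TaxaProfile(series / series.sum())

    base_raw = base(_RAW_ANCHOR_WEIGHTS)
    base_igg = base(_IGG_ANCHOR_WEIGHTS)

    cont_vals = np.sort(rng.dirichlet(np.full(len(cont_taxa), 1.5)))[::-1]
    contaminant = TaxaProfile(
        pd.Series(cont_vals, index=cont_taxa).reindex(taxa, fill_value=0.0)
    )
    group_shift = pd.Series(_DEFAULT_GROUP_SHIFT, dtype=float).reindex(taxa, fill_value=0.0)
    return CommunityTemplate(
        taxa=taxa,
        base_raw=base_raw,
        base_igg=base_igg,
        contaminant=contaminant,
        group_shift=group_shift,
    )


def _dirichlet_around(base: TaxaProfile, theta: float, rng: np.random.Generator) -> pd.Series:
    """Dirichlet(theta * base) draw embedded over the full taxon set."""
    support = base.support()
    alpha = theta * base.series.loc[support].to_numpy()
    draw = rng.dirichlet(alpha)
    return pd.Series(draw, index=support).reindex(base.series.index, fill_value=0.0)


def _lognormal_depth(median: float, cv: float, rng: np.random.Generator) -> int:
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return max(1, int(round(rng.lognormal(mean=math.log(median), sigma=sigma))))


def simulate_sample_pair(
    template: CommunityTemplate,
    params: SimulationParams,
    participant: dict,
    rng: np.random.Generator,
):
    """Simulate the paired raw / IgG-bound counts for one participant.

    Returns ``(counts_by_fraction, truth_rows, act_profiles)`` where
    ``counts_by_fraction`` maps fraction label to an integer count Series.
    """
    is_disease = participant["group"] == params.group_labels[1]
    bases = {
        "raw": template.base_raw,
        "igg_bound": template.shifted_igg() if is_disease else template.base_igg,
    }
    cont = template.contaminant.series
    counts: dict[str, pd.Series] = {}
    truth_rows: dict[str, dict] = {}
    act_profiles: dict[str, pd.Series] = {}
    for fraction, base in bases.items():
        act = _dirichlet_around(base, params.theta, rng)
        p_true = float(rng.beta(params.p_beta_a, params.p_beta_b))
        obs = (1.0 - p_true) * act + p_true * cont
        depth = _lognormal_depth(params.depth_median, params.depth_cv, rng)
        drawn = rng.multinomial(depth, obs.to_numpy() / obs.to_numpy().sum())
        sample_id = f"{participant['pair_id']}_{'igg' if fraction == 'igg_bound' else 'raw'}"
        counts[fraction] = pd.Series(drawn, index=obs.index, name=sample_id)
        act_profiles[sample_id] = act
        truth_rows[sample_id] = {
            "sample_id": sample_id,
            "pair_id": participant["pair_id"],
            "fraction": fraction,
            "p_true": p_true,
            "depth": depth,
        }
    return counts, truth_rows, act_profiles


def simulate_cytokines(
    load,
    alpha: float,
    beta: float,
    sigma: float,
    rng: np.random.Generator,
):
    """Cytokine concentration (pg/mL) log-linearly coupled to bacterial load.

    log(cytokine) = alpha + beta * log(load) + Normal(0, sigma).
    """
    load = np.asarray(load, dtype=float)
    if np.any(load <= 0):
        raise ValidationError("bacterial load must be positive")
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    noise = rng.normal(0.0, sigma, size=load.shape) if sigma > 0 else 0.0
    out = np.exp(alpha + beta * np.log(load) + noise)
    return float(out) if out.ndim == 0 else out


def simulate_cohort(
    params: SimulationParams | None = None,
    template: CommunityTemplate | None = None,
) -> Cohort:
    """Simulate the full two-group paired cohort plus negative controls."""
    params = params or SimulationParams()
    template = template or make_templates(seed=params.seed)

    rng_part = stage_rng(params.seed, "participants")
    rng_ctrl = stage_rng(params.seed, "controls")
    rng_cyt = stage_rng(params.seed, "cytokines")

    group_sizes = {
        params.group_labels[0]: params.n_uninfected,
        params.group_labels[1]: params.n_disease,
    }
    columns: list[pd.Series] = []
    truth_sample_rows: list[dict] = []
    act_profiles: dict[str, pd.Series] = {}
    participant_rows: list[dict] = []
    records: list[SampleMetadata] = []

    idx = 0
    for group, size in group_sizes.items():
        is_disease = group == params.group_labels[1]
        for _ in range(size):
            idx += 1
            pair_id = f"P{idx:03d}"
            load_mu = (
                params.load_log_mean_disease if is_disease else params.load_log_mean_uninfected
            )
            load = float(np.exp(rng_cyt.normal(load_mu, params.load_log_sd)))
            beta = params.cytokine_beta if is_disease else 0.0
            alpha = params.cytokine_alpha + (0.0 if is_disease else params.cytokine_beta * load_mu)
            cytokines = {
                name: simulate_cytokines(load, alpha, beta, params.cytokine_sigma, rng_cyt)
                for name in params.cytokine_names
            }
            qpcr = float(load * np.exp(rng_cyt.normal(0.0, params.measurement_sigma)))
            flow = float(load / 50.0 * np.exp(rng_cyt.normal(0.0, params.measurement_sigma)))
            participant = {
                "pair_id": pair_id,
                "group": group,
                "sex": "male" if rng_part.random() < 0.68 else "female",
                "age": int(rng_part.integers(35, 71)),
                "pack_years": round(float(rng_part.exponential(10.0)), 1),
            }
            counts, truth_rows, acts = simulate_sample_pair(template, params, participant, rng_part)
            for fraction in ("raw", "igg_bound"):
                col = counts[fraction]
                columns.append(col)
                records.append(
                    SampleMetadata(
                        sample_id=str(col.name),
                        fraction=fraction,
                        pair_id=pair_id,
                        group=group,
                        sex=participant["sex"],
                        age=participant["age"],
                        pack_years=participant["pack_years"],
                        cytokines=dict(cytokines),
                        qpcr_copies=qpcr,
                        flow_events=round(flow),
                    )
                )
            truth_sample_rows.extend(truth_rows.values())
            act_profiles.update(acts)
            participant_rows.append(
                {
                    "pair_id": pair_id,
                    "group": group,
                    "true_load": load,
                    "cytokine_alpha": alpha,
                    "cytokine_beta": beta,
                    "cytokine_sigma": params.cytokine_sigma,
                }
            )

    taxa_index = pd.Index(template.taxa, name="taxon")
    if columns:
        counts_df = pd.concat(columns, axis=1).reindex(taxa_index, fill_value=0)
    else:
        counts_df = pd.DataFrame(index=taxa_index)
    counts_table = TaxaCountTable(counts_df.astype(np.int64) if columns else counts_df)

    cont_vec = template.contaminant.series.reindex(taxa_index, fill_value=0.0).to_numpy()
    ctrl_cols = {}
    for c in range(params.n_controls):
        depth = _lognormal_depth(params.control_depth_median, params.depth_cv, rng_ctrl)
        ctrl_cols[f"CTRL{c + 1:02d}"] = rng_ctrl.multinomial(depth, cont_vec / cont_vec.sum())
    controls_table = TaxaCountTable(pd.DataFrame(ctrl_cols, index=taxa_index))

    truth = GroundTruth(
        samples=pd.DataFrame(truth_sample_rows).set_index("sample_id")
        if truth_sample_rows
        else pd.DataFrame(columns=["pair_id", "fraction", "p_true", "depth"]).rename_axis("sample_id"),
        act_profiles=pd.DataFrame(act_profiles).reindex(taxa_index, fill_value=0.0)
        if act_profiles
        else pd.DataFrame(index=taxa_index),
        contaminant=template.contaminant,
        participants=pd.DataFrame(
            participant_rows,
            columns=["pair_id", "group", "true_load", "cytokine_alpha", "cytokine_beta", "cytokine_sigma"],
        ).set_index("pair_id"),
    )
    return Cohort(
        counts=counts_table,
        controls=controls_table,
        metadata=records,
        truth=truth,
        template=template,
    )


def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write counts.tsv, controls.tsv, metadata.tsv and truth.tsv."""
    from pathlib import Path

    from .tables import write_count_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "controls": out / "controls.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
    }
    write_count_table(cohort.counts, paths["counts"])
    write_count_table(cohort.controls, paths["controls"])
    metadata_frame(cohort.metadata).to_csv(paths["metadata"], sep="\t", na_rep="NA")
    cohort.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
    return {k: str(v) for k, v in paths.items()}
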