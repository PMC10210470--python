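"""Distribution-based contaminant filtering for low-biomass count tables.

Reagent and column contamination in low-biomass 16S data is modelled as a
per-sample compositional mixture: an observed experimental profile obsExp is
assumed to contain a proportion ``p`` of the contaminant profile and
``1 - p`` of the true community.  With the averaged negative-control profile
obsCont standing in for the unobservable contaminant, ``p`` is estimated per
sample by minimising the shape-matching least-squares objective

    J(p) = sum_i (p * obsCont[i] - (1 - p) * obsExp[i])^2

where the sum runs over the taxa present in the control; taxa found only in
the experimental sample are excluded so that community-specific taxa carry
no mismatch penalty.  The estimate p-hat is then used to subtract
``p * obsCont`` from obsExp, clamp negative remainders to zero, renormalise
to sum one, and scale the read depth by ``1 - p`` so a filtered read count
can be reported.

Note the objective is fit exactly as written above: its minimiser is the
argmin of J, not the mixture weight of the generative equation.  A sample
identical in composition to the control minimises J to exactly 0 (attained
at p-hat = 0.5), and a noiseless admixture of proportion ``p`` with a
community disjoint from the control is recovered as p-hat = p / (1 + p).
These fixed points are properties of the printed objective and are relied
on by the test suite; see docs/methods.md for discussion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import ValidationError
from .tables import TaxaCountTable, TaxaProfile

__all__ = [
    "ControlSet",
    "MixtureFit",
    "FilteredSample",
    "average_controls",
    "mixture_objective",
    "estimate_contaminant_proportion",
    "subtract_contaminant",
    "scale_read_depth",
    "largest_remainder_counts",
    "filter_table",
]

logger = logging.getLogger(__name__)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class ControlSet:
    """Negative-control profiles and their arithmetic mean (the working obsCont)."""

    profiles: tuple[TaxaProfile, ...]
    mean_profile: TaxaProfile


@dataclass(frozen=True)
class MixtureFit:
    """Estimated contaminant proportion for one sample."""

    p_hat: float
    objective_value: float
    shared_taxa: tuple[str, ...]

    @property
    def n_shared(self) -> int:
        return len(self.shared_taxa)


@dataclass(frozen=True)
class FilteredSample:
    """Per-sample filtering report: post-subtraction profile and fit."""

    sample_id: str
    profile: TaxaProfile
    scaled_depth: int
    fit: MixtureFit
    fully_removed: bool
    depth_in: int = 0
    empty_input: bool = False


def average_controls(controls: list[TaxaProfile]) -> ControlSet:
    """Average the negative-control profiles into the working contaminant.

    The mean is the plain arithmetic mean of relative abundances over the
    union of control taxa (a taxon absent from a control contributes 0),
    renormalised to sum one.
    """
    if not controls:
        raise ValidationError("need at least one control profile")
    nonempty = [c for c in controls if not c.is_empty]
    if not nonempty:
        raise ValidationError("all control profiles are empty")
    if len(nonempty) < len(controls):
        logger.warning("dropping %d empty control profile(s)", len(controls) - len(nonempty))
    frame = pd.concat([c.series for c in nonempty], axis=1).fillna(0.0)
    mean = frame.mean(axis=1)
    mean = mean / mean.sum()
    return ControlSet(profiles=tuple(nonempty), mean_profile=TaxaProfile(mean))


def _aligned_cont_exp(obs_exp: TaxaProfile, obs_cont: TaxaProfile):
    """Control and experimental abundances over the control's support."""
    support = obs_cont.support()
    c = obs_cont.series.loc[support].to_numpy(dtype=float)
    e = obs_exp.series.reindex(support, fill_value=0.0).to_numpy(dtype=float)
    return support, c, e


def mixture_objective(p: float, obs_exp: TaxaProfile, obs_cont: TaxaProfile) -> float:
    """The least-squares shape-matching objective J(p).

    Summation runs over the control's support only; experimental-only taxa
    contribute nothing, control taxa missing from the sample enter with
    abundance 0.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    _, c, e = _aligned_cont_exp(obs_exp, obs_cont)
    resid = p * c - (1.0 - p) * e
    return float(np.dot(resid, resid))


def _golden_section(f, lo: float, hi: float, tol: float = 1e-10) -> float:
    """Golden-section minimiser on [lo, hi]; ties drift toward the lower end."""
    a, b = lo, hi
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > tol:
        if f1 <= f2:  # keep the left bracket on ties -> smaller p
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = f(x2)
    return a if f(a) <= f(b) else b


def estimate_contaminant_proportion(
    obs_exp: TaxaProfile,
    control: ControlSet | TaxaProfile,
    resolution: float = 1e-3,
) -> MixtureFit:
    """Estimate the contaminant proportion by minimising J(p) over [0, 1].

    Dense grid search at ``resolution`` followed by golden-section
    refinement in the winning bracket; grid ties break toward the smaller
    ``p`` (the less aggressive filter).  An empty shared-taxon set is
    treated as no evidence of contamination (p-hat = 0).
    """
    obs_cont = control.mean_profile if isinstance(control, ControlSet) else control
    if obs_exp.is_empty:
        raise ValidationError("cannot estimate contamination of an empty sample")
    support, c, e = _aligned_cont_exp(obs_exp, obs_cont)
    shared = tuple(t for t, ev in zip(support, e) if ev > 0)
    if not shared:
        return MixtureFit(p_hat=0.0, objective_value=0.0, shared_taxa=())

    def objective(p: float) -> float:
        resid = p * c - (1.0 - p) * e
        return float(np.dot(resid, resid))

    grid = np.arange(0.0, 1.0 + 0.5 * resolution, resolution)
    grid[-1] = 1.0
    vals = np.square(np.outer(grid, c) - np.outer(1.0 - grid, e)).sum(axis=1)
    best = int(np.argmin(vals))  # first occurrence -> smaller p on exact ties
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    p_hat = _golden_section(objective, lo, hi)
    if objective(grid[best]) < objective(p_hat):
        p_hat = float(grid[best])
    p_hat = float(min(max(p_hat, 0.0), 1.0))
    return MixtureFit(p_hat=p_hat, objective_value=objective(p_hat), shared_taxa=shared)


def subtract_contaminant(obs_exp: TaxaProfile, obs_cont: TaxaProfile, p: float) -> TaxaProfile:
    """Subtract ``p * obsCont`` from obsExp, clamp negatives to 0, renormalise.

    Taxa absent from the control pass through untouched.  If everything is
    removed the all-zero sentinel profile is returned.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    e, c = obs_exp.series.align(obs_cont.series, fill_value=0.0)
    raw = (e - p * c).clip(lower=0.0)
    # restrict back to the experimental taxon set (control-only taxa clamp to 0 anyway)
    raw = raw.reindex(obs_exp.series.index, fill_value=0.0)
    total = raw.sum()
    if total == 0.0:
        return TaxaProfile(raw)
    return TaxaProfile(raw / total)


def scale_read_depth(depth: int, p: float) -> int:
    """Scaled filtered read depth round(depth * (1 - p)), half away from zero."""
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    return int(math.floor(depth * (1.0 - p) + 0.5))


def largest_remainder_counts(profile: TaxaProfile, total: int) -> pd.Series:
    """Integer counts apportioned so they sum exactly to ``total``.

    Largest-remainder (Hamilton) rounding of ``profile * total``; remainder
    ties resolve by taxon order for determinism.
    """
    shares = profile.values * float(total)
    floors = np.floor(shares).astype(np.int64)
    short = int(total - floors.sum())
    if short > 0:
        order = np.argsort(-(shares - floors), kind="stable")
        floors[order[:short]] += 1
    return pd.Series(floors, index=profile.series.index)


def filter_table(
    table: TaxaCountTable,
    controls: ControlSet,
    config: AnalysisConfig | None = None,
    *,
    resolution: float | None = None,
) -> tuple[TaxaCountTable, list[FilteredSample]]:
    """Run the full filter over every sample of a count table.

    Per sample: estimate p-hat, subtract the scaled control profile, clamp,
    renormalise, scale the read depth, and emit integer counts whose column
    sum equals the scaled depth exactly.  Zero-read samples are passed
    through untouched and flagged rather than filtered, mirroring their
    exclusion from downstream statistics.
    """
    if config is not None and resolution is None:
        resolution = config.p_grid_resolution
    resolution = resolution or 1e-3
    obs_cont = controls.mean_profile
    if not set(table.taxa) & set(obs_cont.support()):
        logger.warning(
            "control taxa share no taxa with the experimental table; output is the identity"
        )
    out = pd.DataFrame(0, index=table.counts.index, columns=table.counts.columns, dtype=np.int64)
    reports: list[FilteredSample] = []
    for sample in table.samples:
        depth = table.depth(sample)
        if depth == 0:
            logger.warning("sample %r has zero reads; excluded from filtering", sample)
            reports.append(
                FilteredSample(
                    sample_id=sample,
                    profile=table.profile(sample),
                    scaled_depth=0,
                    fit=MixtureFit(math.nan, math.nan, ()),
                    fully_removed=True,
                    depth_in=0,
                    empty_input=True,
                )
            )
            continue
        obs_exp = table.profile(sample)
        fit = estimate_contaminant_proportion(obs_exp, controls, resolution=resolution)
        filtered = subtract_contaminant(obs_exp, obs_cont, fit.p_hat)
        scaled = scale_read_depth(depth, fit.p_hat)
        fully_removed = filtered.is_empty
        if not fully_removed:
            counts = largest_remainder_counts(filtered, scaled)
            out.loc[counts.index, sample] = counts
        reports.append(
            FilteredSample(
                sample_id=sample,
                profile=filtered,
                scaled_depth=scaled,
                fit=fit,
                fully_removed=fully_removed,
                depth_in=depth,
            )
        )
    return TaxaCountTable(out), reports


def report_frame(reports: list[FilteredSample]) -> pd.DataFrame:
    """Flatten per-sample filter reports to the TSV report schema."""
    rows = [
        {
            "sample_id": r.sample_id,
            "p_hat": r.fit.p_hat,
            "objective": r.fit.objective_value,
            "n_shared": r.fit.n_shared,
            "depth_in": r.depth_in,
            "depth_out": r.scaled_depth,
            "fully_removed": r.fully_removed,
        }
        for r in reports
    ]
    return pd.DataFrame(rows).set_index("sample_id")
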