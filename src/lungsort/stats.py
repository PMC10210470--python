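"""Compositional statistics downstream of contaminant filtering.

Implements the analysis battery run on filtered relative abundances:
additive log-ratio (ALR) transforms with pseudocount smoothing, paired
Wilcoxon signed-rank tests per taxon (exact tie-aware null for small n),
covariate-adjusted regression of paired ALR differences, Manhattan /
Bray-Curtis distance matrices, PERMANOVA with permutation or exact
enumeration p-values and sequential covariate adjustment, non-metric
multidimensional scaling, and log-log regression of cytokine levels on
bacterial load.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance as ssd
import scipy.stats
import statsmodels.api as sm
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tables import TaxaProfile

__all__ = [
    "default_pseudocount",
    "alr_transform",
    "alr_table",
    "signed_rank_test",
    "paired_wilcoxon_by_taxon",
    "alr_difference_regression",
    "DistanceMatrix",
    "distance_matrix",
    "PermanovaResult",
    "permanova",
    "OrdinationResult",
    "nmds",
    "SimpleRegression",
    "cytokine_association",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ALR transform
# ---------------------------------------------------------------------------

def default_pseudocount(profiles: pd.DataFrame) -> float:
    """Half the smallest nonzero relative abundance in the table."""
    vals = profiles.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValidationError("cannot derive a pseudocount from an all-zero table")
    return float(nonzero.min() / 2.0)


def _as_series(profile) -> pd.Series:
    if isinstance(profile, TaxaProfile):
        return profile.series
    return pd.Series(profile, dtype=float)


def alr_transform(profile, eps: float, reference: str = "remainder") -> pd.Series:
    """Additive log-ratio of each taxon.

    ``reference="remainder"`` uses the per-taxon remainder pseudo-component,
    ALR_i = ln((x_i + eps) / (1 - x_i + eps)), so each taxon has a
    self-contained log-ratio; any fixed taxon name may be given instead, in
    which case ALR_i = ln((x_i + eps) / (x_ref + eps)) and the reference's
    own ALR is identically 0.
    """
    if eps is None or eps < 0:
        raise ValidationError("eps must be >= 0")
    x = _as_series(profile)
    if reference == "remainder":
        return np.log((x + eps) / ((1.0 - x) + eps))
    if reference not in x.index:
        raise ValidationError(f"ALR reference taxon {reference!r} absent from profile")
    return np.log((x + eps) / (x.loc[reference] + eps))


def alr_table(
    profiles: pd.DataFrame,
    eps: float | None = None,
    reference: str = "remainder",
) -> pd.DataFrame:
    """ALR-transform a taxa-by-sample relative-abundance table column-wise."""
    if eps is None:
        eps = default_pseudocount(profiles)
    return pd.DataFrame(
        {s: alr_transform(profiles[s], eps, reference) for s in profiles.columns}
    )


# ---------------------------------------------------------------------------
# Paired signed-rank tests
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ under the sign-flip null, ties allowed.

    Doubled ranks keep arithmetic integral; the null distribution of the
    doubled statistic is built by polynomial convolution over all 2^n sign
    patterns.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    dist = np.zeros(int(r2.sum()) + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    total = int(r2.sum())
    mirror = total - w2
    lo, hi = min(w2, mirror), max(w2, mirror)
    p = dist[hi:].sum() + dist[: lo + 1].sum()
    return float(min(1.0, p))


def signed_rank_test(diffs) -> tuple[float, float, int]:
    """Wilcoxon signed-rank statistic W+ and two-sided p for paired diffs.

    Zero differences are dropped (Wilcoxon convention); ties in |d| share
    mid-ranks.  Exact enumeration null for n <= 25, normal approximation
    with continuity and tie corrections above.

    Returns ``(w_plus, p, n_used)``; fewer than 3 informative pairs yields
    NaN with a warning.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0.0]
    n = d.size
    if n < 3:
        logger.warning("fewer than 3 informative pairs; signed-rank test is NA")
        return math.nan, math.nan, n
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return w_plus, _exact_signed_rank_p(ranks, w_plus), n
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    diff = w_plus - mean
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / math.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p)), n


def paired_wilcoxon_by_taxon(
    alr_bound: pd.DataFrame,
    alr_raw: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-taxon paired signed-rank tests of ALR(bound) - ALR(raw).

    ``pairs`` lists (bound_sample, raw_sample) column pairs.  Returns a
    taxon-indexed frame with W, p, BH q, direction, and n (informative
    pairs).
    """
    for b, r in pairs:
        if b not in alr_bound.columns:
            raise ValidationError(f"bound sample {b!r} missing from ALR table")
        if r not in alr_raw.columns:
            raise ValidationError(f"raw sample {r!r} missing from ALR table")
    taxa = alr_bound.index
    rows = []
    for taxon in taxa:
        diffs = np.array(
            [alr_bound.at[taxon, b] - alr_raw.at[taxon, r] for b, r in pairs], dtype=float
        )
        w, p, n = signed_rank_test(diffs)
        med = float(np.median(diffs)) if diffs.size else math.nan
        direction = "igg_bound" if med > 0 else ("raw" if med < 0 else "none")
        rows.append({"taxon": taxon, "W": w, "p": p, "n": n, "direction": direction})
    out = pd.DataFrame(rows).set_index("taxon")
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Covariate-adjusted ALR-difference regression
# ---------------------------------------------------------------------------

def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + dummy-coded categoricals + numeric covariates."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, _, pivots = scipy.linalg.qr(X.to_numpy(), pivoting=True)
        aliased = [X.columns[i] for i in pivots[rank:]]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    return X


def alr_difference_regression(
    alr_diff: pd.DataFrame,
    covariates: pd.DataFrame,
    group_col: str = "group",
) -> pd.DataFrame:
    """OLS of each taxon's paired ALR difference on group + covariates.

    ``alr_diff`` is taxa by pair; ``covariates`` is pair by covariate and
    must include ``group_col``.  Each taxon is fit against the identical
    design; the group coefficient's p-values are BH-adjusted across taxa.
    """
    covariates = covariates.loc[list(alr_diff.columns)]
    X = _design_matrix(covariates)
    group_terms = [c for c in X.columns if c.startswith(f"{group_col}_") or c == group_col]
    if not group_terms:
        raise ValidationError(f"no group term {group_col!r} in the design")
    group_term = group_terms[0]
    rows = []
    for taxon in alr_diff.index:
        y = alr_diff.loc[taxon].to_numpy(dtype=float)
        fit = sm.OLS(y, X.to_numpy()).fit()
        k = list(X.columns).index(group_term)
        rows.append(
            {
                "taxon": taxon,
                "coef_group": fit.params[k],
                "se_group": fit.bse[k],
                "t_group": fit.tvalues[k],
                "p_group": fit.pvalues[k],
                "r2": fit.rsquared,
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    out["q_group"] = multipletests(out["p_group"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Distances, PERMANOVA, NMDS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample distances."""

    ids: tuple[str, ...]
    data: np.ndarray = field(repr=False)
    metric: str = "manhattan"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "data", d)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(profiles: pd.DataFrame, metric: str = "manhattan") -> DistanceMatrix:
    """Pairwise distances between sample columns of a relative-abundance table.

    Manhattan: sum |x_i - y_i|; Bray-Curtis: sum |x_i - y_i| / sum (x_i + y_i).
    """
    if metric not in ("manhattan", "bray_curtis"):
        raise ValidationError(f"unsupported metric {metric!r}")
    X = profiles.to_numpy(dtype=float).T  # samples as rows
    scipy_name = "cityblock" if metric == "manhattan" else "braycurtis"
    condensed = ssd.pdist(X, metric=scipy_name)
    return DistanceMatrix(
        ids=tuple(str(c) for c in profiles.columns),
        data=ssd.squareform(condensed),
        metric=metric,
    )


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based multivariate ANOVA for a grouping factor."""

    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    method: str  # "exact" or "monte_carlo"
    ss_total: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    permuted_f: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def permuted_summary(self) -> dict[str, float]:
        f = self.permuted_f
        if f.size == 0:
            return {}
        return {
            "mean": float(f.mean()),
            "q95": float(np.quantile(f, 0.95)),
            "max": float(f.max()),
        }


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    return c @ a @ c


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _multiset_permutations(labels: np.ndarray):
    """Yield every distinct arrangement of a label multiset."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = labels.size

    def rec(prefix, remaining):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for i, u in enumerate(uniq):
            if remaining[i] > 0:
                remaining[i] -= 1
                yield from rec(prefix + [u], remaining)
                remaining[i] += 1

    yield from rec([], counts.copy())


def _n_distinct_arrangements(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = math.factorial(int(labels.size))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    dm: DistanceMatrix,
    grouping,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    exact_limit: int = 10_000,
) -> PermanovaResult:
    """PERMANOVA pseudo-F, R² and permutation p for a grouping factor.

    Sums of squares are partitioned on the Gower-centred squared-distance
    matrix; with covariates supplied the group effect is assessed
    sequentially (covariates entered first) and raw observations are
    permuted.  Without covariates, when the number of distinct relabelings
    is at most ``exact_limit`` the null is enumerated exactly and
    p = #(F_perm >= F_obs) / #relabelings; otherwise Monte Carlo label
    permutations with the (1 + B) / (1 + N) estimator, so p is never zero.
    """
    groups = pd.Series(list(grouping), index=list(dm.ids)) if not isinstance(grouping, pd.Series) else grouping.loc[list(dm.ids)]
    n = len(dm)
    labels, level_index = pd.factorize(groups.to_numpy())
    k = len(level_index)
    if k < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(labels)
    if sizes.min() < 2:
        raise ValidationError("every group needs at least 2 samples")

    G = _gower_center(dm.data)
    ss_total = float(np.trace(G))

    if covariates is not None:
        Z = _design_matrix(covariates.loc[list(dm.ids)]).to_numpy()
    else:
        Z = np.ones((n, 1))
    dummies = np.eye(k)[labels][:, 1:]  # drop-first coding
    X_full = np.hstack([Z, dummies])
    Hz, Hf = _hat(Z), _hat(X_full)
    df_between = k - 1
    df_within = n - X_full.shape[1]
    if df_within <= 0:
        raise ValidationError("no residual degrees of freedom")

    def f_stat(Gp: np.ndarray) -> tuple[float, float]:
        ss_cov = float(np.sum(Hz * Gp))
        ss_full = float(np.sum(Hf * Gp))
        ss_between_ = ss_full - ss_cov
        ss_within_ = float(np.trace(Gp)) - ss_full
        return (ss_between_ / df_between) / (ss_within_ / df_within), ss_between_

    f_obs, ss_between = f_stat(G)
    ss_within = ss_total - float(np.sum(Hf * G))
    r2 = ss_between / ss_total

    use_exact = covariates is None and _n_distinct_arrangements(labels) <= exact_limit
    if use_exact:
        f_perm = []
        for arrangement in _multiset_permutations(labels):
            perm_dummies = np.eye(k)[arrangement][:, 1:]
            Xp = np.hstack([Z, perm_dummies])
            Hp = _hat(Xp)
            ss_full = float(np.sum(Hp * G))
            ssb = ss_full - float(np.sum(Hz * G))
            ssw = ss_total - ss_full
            f_perm.append((ssb / df_between) / (ssw / df_within))
        f_perm = np.array(f_perm)
        n_enum = f_perm.size
        p = float((f_perm >= f_obs - 1e-12).sum() / n_enum)
        method, n_used = "exact", n_enum
    else:
        rng = rng or np.random.default_rng()
        f_perm = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            f_perm[b], _ = f_stat(Gp)
        hits = int((f_perm >= f_obs - 1e-12).sum())
        p = (1.0 + hits) / (1.0 + n_permutations)
        method, n_used = "monte_carlo", n_permutations

    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(r2),
        p_value=float(p),
        n_permutations=n_used,
        method=method,
        ss_total=ss_total,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        df_between=df_between,
        df_within=df_within,
        permuted_f=np.asarray(f_perm, dtype=float),
    )


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS embedding with Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    centroids: pd.DataFrame | None = None


def nmds(
    dm: DistanceMatrix,
    n_components: int = 2,
    restarts: int = 8,
    seed: int = 0,
    grouping=None,
    max_iter: int = 500,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a distance matrix.

    Kruskal stress-1 is minimised by SMACOF with isotonic (monotone)
    regression; the best of ``restarts`` random starts is kept and the
    configuration is mean-centred.  Optional ``grouping`` adds per-group
    centroid coordinates.
    """
    n = len(dm)
    if n < n_components + 2:
        raise ValidationError("need at least n_components + 2 samples for NMDS")
    model = MDS(
        n_components=n_components,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=restarts,
        max_iter=max_iter,
        eps=1e-6,
        normalized_stress=True,
        random_state=int(seed),
    )
    coords = model.fit_transform(dm.data)
    coords = coords - coords.mean(axis=0, keepdims=True)
    converged = bool(model.n_iter_ < max_iter)
    if not converged:
        logger.warning("NMDS did not converge in %d iterations; returning best-so-far", max_iter)
    frame = pd.DataFrame(
        coords,
        index=pd.Index(list(dm.ids), name="sample_id"),
        columns=[f"dim{i + 1}" for i in range(n_components)],
    )
    centroids = None
    if grouping is not None:
        groups = pd.Series(list(grouping), index=frame.index) if not isinstance(grouping, pd.Series) else grouping.loc[frame.index]
        centroids = frame.groupby(groups).mean()
    return OrdinationResult(
        coordinates=frame,
        stress=float(model.stress_),
        converged=converged,
        centroids=centroids,
    )


# ---------------------------------------------------------------------------
# Cytokine-load association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimpleRegression:
    """Simple OLS of log(cytokine) on log(load)."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def _log_with_zero_shift(values: np.ndarray, name: str) -> np.ndarray:
    if np.any(values < 0):
        raise ValidationError(f"{name} must be non-negative")
    if np.any(values == 0):
        positive = values[values > 0]
        if positive.size == 0:
            raise ValidationError(f"{name} is identically zero")
        shift = positive.min() / 2.0
        logger.info("%s contains zeros; shifting by half-minimum %.3g", name, shift)
        values = values + shift
    return np.log(values)


def cytokine_association(load, cytokine) -> SimpleRegression:
    """Log-log OLS association between bacterial load and a cytokine.

    Zeros are shifted by half the smallest positive value before the log;
    incomplete pairs are dropped; fewer than 3 complete pairs is an error.
    """
    s_load = pd.Series(load, dtype=float)
    s_cyt = pd.Series(cytokine, dtype=float)
    frame = pd.concat([s_load.rename("load"), s_cyt.rename("cytokine")], axis=1).dropna()
    if len(frame) < 3:
        raise ValidationError("need at least 3 complete (load, cytokine) pairs")
    x = _log_with_zero_shift(frame["load"].to_numpy(), "load")
    y = _log_with_zero_shift(frame["cytokine"].to_numpy(), "cytokine")
    fit = scipy.stats.linregress(x, y)
    return SimpleRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(frame),
    )
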