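# Methods

## The contaminant mixture model

Low-biomass 16S profiles are modelled compositionally. An observed
experimental sample `obsExp` is assumed to be a two-component mixture

    (1 - p) * actExp + p * actCont = obsExp

of the true community `actExp` and a contaminant `actCont`, with one mixing
proportion `p` per sample. Neither latent profile is observable; the
arithmetic mean of the negative-control profiles (`obsCont`) stands in for
the contaminant. The mean is unweighted — control sequencing depth is
ignored and controls are treated purely compositionally — because the
filter's premise is that the controls vary little and differ strongly from
the experimental samples; an empty control is dropped with a warning.

`p` is estimated per sample as the argmin over [0, 1] of

    J(p) = sum_{i in support(obsCont)} ( p * obsCont[i] - (1 - p) * obsExp[i] )^2 .

Two index-set conventions needed fixing where the verbal description is
ambiguous:

* the sum runs over **all** taxa present in the control; a control taxon
  absent from the sample enters with `obsExp[i] = 0` (this is the most
  literal reading — only taxa *absent from the control* are excluded, so
  that community-specific taxa carry no mismatch penalty);
* when the sample and control share no taxa at all, the objective reduces
  to `sum (p * obsCont[i])^2`, which carries no information about the
  sample; we adopt `p̂ = 0` (no evidence of contamination) and pass the
  sample through unchanged.

### Fixed points of the objective as printed

`J` is a convex quadratic in `p`, minimised in closed form at
`p* = Σ e(c+e) / Σ (c+e)²` (clamped to [0, 1]). Two consequences follow and
are worth being explicit about, because they differ from what the mixture
equation alone would suggest:

* a sample **identical** to the control minimises `J` to exactly 0, at
  `p̂ = 0.5` (not 1);
* a noiseless forward mixture with `support(actExp) ∩ support(obsCont) = ∅`
  is recovered as `p̂ = p / (1 + p)` (not `p`).

The filter is defined by the objective as printed, and `p̂` is used
downstream exactly as the argmin of `J` — it is not reinterpreted as the
mixture weight of the generative equation. The test suite and the synthetic
cohorts validate against these analytic fixed points (`p/(1+p)` under
disjoint support), not against `p` itself.

### Optimisation

Dense grid search on [0, 1] at the configured resolution (default 1e-3)
followed by golden-section refinement (tolerance 1e-10) in the winning
bracket; ties break toward the smaller `p`, i.e. the less aggressive
filter. Since `J` is quadratic this is more machinery than strictly needed,
but it makes no smoothness assumption and the closed-form argmin and a 1e-6
brute-force grid serve as independent oracles in the tests (agreement to
1e-4 on random instances).

### Subtraction, clamping, renormalisation, depth scaling

Given `p̂`: `raw[i] = max(obsExp[i] - p̂ * obsCont[i], 0)` for every taxon
(taxa absent from the control pass through untouched), renormalised to sum
one; if everything is removed the all-zero sentinel is returned and the
sample flagged. The read depth is scaled to `round(depth * (1 - p̂))`
(half-away-from-zero; the convention is ours, the source procedure only
asks for an estimate). Integer output counts use largest-remainder
(Hamilton) apportionment of `profile * scaled_depth` so each filtered
column sums exactly to its scaled depth; remainder ties resolve by taxon
order for determinism. Zero-read samples are never filtered: they are
passed through, flagged, and excluded from downstream statistics with a
logged warning.

## Synthetic cohorts

The generator runs the mixture model forward with Dirichlet-multinomial
noise, which the source procedure does not specify; all of the following
are this package's modelling choices, fixed once:

* **Templates.** 25 taxa by default: a fixed oral-dominated unsorted
  template (Streptococcus 0.24, Prevotella 0.18, Veillonella 0.13,
  Tropheryma 0.07, Pseudomonas 0.02, remainder spread by a seeded
  Dirichlet), a Pseudomonas-enriched IgG-bound template (Pseudomonas 0.32),
  and a reagent contaminant over `max(3, n_taxa/3)` taxa of which a
  fraction `overlap` (default 0.3) is shared with the community and the
  rest are kitome genera (Ralstonia, Sphingomonas, ...).
* **Per-sample draw.** `actExp ~ Dirichlet(θ · base)` with θ = 50
  (moderate overdispersion, plausible for BAL 16S);
  `p_true ~ Beta(2, 5)` (mean 0.29 — substantial but sub-dominant
  background, as expected for low-biomass specimens); depth log-normal
  with median 2×10⁴ reads and CV 0.6; counts multinomial at that depth
  from `(1-p_true)·actExp + p_true·contaminant`. Controls are multinomial
  draws from the contaminant at median depth 3×10³.
* **Cohort shape.** 22 + 42 participants in two groups, two fractions per
  participant, 4 negative-control columns.
* **Group effect.** A natural-log shift applied to the IgG-bound template
  only (+1.0 Pseudomonas, +0.8 Stenotrophomonas, −0.5 Prevotella,
  −0.4 Veillonella), so the between-group signal exists in the IgG-bound
  fraction and the raw fraction is exactly null — the qualitative
  structure the pipeline is meant to detect.
* **Cytokines and load.** Per-participant true load is log-normal
  (log-mean 10.5 disease / 9.0 uninfected, log-sd 1.5); qPCR copies and
  flow-cytometry events are the load with multiplicative log-normal
  measurement error (σ = 0.2); cytokines follow
  `log(cyt) = α + β·log(load) + N(0, σ)` with β = 0.5, σ = 0.3 in the
  disease group and β = 0 in the uninfected group.

Every stochastic stage draws from an independent substream derived from the
global seed plus a stable hash of the stage name, so integer outputs are
bit-reproducible and adding a stage never perturbs another.

What the generator does **not** emulate: taxonomic misclassification, PCR
and chimera artefacts, batch-varying contaminant composition, correlated
taxon dynamics beyond the Dirichlet, and zero-inflation beyond multinomial
sampling. Passing tests therefore demonstrate correctness of the procedure
under its own model assumptions, not performance on real sorted BAL data.

## Downstream statistics

* **ALR.** `ALR_i = ln((x_i + ε)/(x_ref + ε))`. Default reference is the
  per-taxon "remainder" pseudo-component `1 − x_i`, giving each taxon a
  self-contained log-ratio (the taxa are tested one at a time); a fixed
  reference taxon is selectable. ε defaults to half the smallest nonzero
  relative abundance in the table.
* **Paired tests.** Wilcoxon signed-rank on ALR(bound) − ALR(raw); zero
  differences dropped, mid-ranks for ties; exact tie-aware null by
  polynomial convolution for n ≤ 25, normal approximation with continuity
  and tie corrections above; Benjamini-Hochberg across taxa. Fewer than 3
  informative pairs yields NA with a warning.
* **ALR-difference regression.** Parallel per-taxon OLS with one shared
  design (intercept + group + sex + age + pack-years), BH across taxa for
  the group coefficient. A rank-deficient design is an error naming the
  aliased columns. (A true multivariate test with cross-taxon covariance
  is deliberately not attempted.)
* **Distances.** Manhattan (default) and Bray-Curtis, both computed on
  post-filter relative abundances — the filter's output is compositional
  by construction. For profiles summing to one, Bray-Curtis equals
  Manhattan/2; both are kept because both appear in practice.
* **PERMANOVA.** Sums of squares partitioned on the Gower-centred squared
  distance matrix; `pseudo-F = (SS_between/df_b)/(SS_within/df_w)`,
  `R² = SS_between/SS_total`. Without covariates, when the label multiset
  admits ≤ 10,000 distinct relabelings the null is enumerated exactly and
  `p = #(F_perm ≥ F_obs)/#relabelings`; otherwise Monte Carlo with the
  `(1+B)/(1+N)` estimator so p is never zero. Covariates are adjusted
  sequentially (entered before group, Type-I style) permuting raw
  observations; exact enumeration is disabled in that case because label
  exchangeability no longer holds.
* **NMDS.** scikit-learn SMACOF with isotonic regression
  (`metric_mds=False`), best of 8 random restarts, Kruskal stress-1
  reported, coordinates mean-centred; group centroids are member means.
* **Cytokine association.** Simple OLS of log(cytokine) on log(load);
  zeros shifted by half the smallest positive value before the log; fewer
  than 3 complete pairs is an error.

## Problem sizes used by the tests and drivers

The analysis drivers and the acceptance checks run the default 64-participant
cohort; property checks use 100–1,000 random instances (optimizer-oracle
agreement, renormalisation), 10 seeded replicate cohorts for the
end-to-end structure-recovery check, and 200 replicate cohorts for the
cytokine-coupling coverage check. These sizes were chosen so each law is
tested at the scale where its statistical tolerance is meaningful.

## Known limitations

* The filter assumes one contaminant composition shared by all samples;
  batch-matched controls (sensible once > 20 controls exist) are not
  implemented.
* `p̂` estimates the argmin of the printed objective, not the generative
  mixture weight; users who need the latter should invert `p̂ = p/(1+p)`
  under the disjoint-support assumption, which the package deliberately
  does not do automatically.
* PERMANOVA covariate adjustment permutes raw observations, which is
  approximate when covariates correlate with the grouping.
* The exact Wilcoxon null treats ties via mid-ranks within the sign-flip
  distribution; other tie policies exist.
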