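# lungsort

Contaminant filtering and compositional statistics for **sorted, low-biomass
lung microbiome** count data.

Low-biomass 16S surveys — bronchoalveolar lavage (BAL) above all — are
dominated by the reagent and column "kitome": every observed community is
partly background. When BAL is additionally passed through magnetic-activated
cell sorting (MACS) to isolate immunoglobulin-G-bound bacteria, the sorted
fractions are even sparser and the column contributes its own contaminants.
This package implements, and exercises end-to-end on synthetic cohorts with
known ground truth, the distribution-based filter that subtracts the negative
controls' taxon distribution from each sample, plus the downstream battery
used to compare sorted and unsorted communities.

## The model

Each observed experimental profile `obsExp` (a relative-abundance vector) is
treated as a compositional mixture of the true community and a contaminant:

    (1 - p) * actExp + p * actCont = obsExp

The contaminant is approximated by the arithmetic mean of the negative-control
profiles (`obsCont`), and `p` is estimated per sample by minimising

    J(p) = sum_i ( p * obsCont[i] - (1 - p) * obsExp[i] )^2 ,

the sum running over the control's taxa only, so taxa unique to the sample
carry no mismatch penalty. The estimate is then used to subtract
`p * obsCont` from `obsExp`, clamp negative remainders to zero, renormalise
to sum one, and scale the read depth by `1 - p`. The objective is
implemented exactly as written: its analytic fixed points (a
control-identical sample minimises J to 0 at `p̂ = 0.5`; a noiseless
disjoint-support admixture of proportion `p` is recovered as `p̂ = p/(1+p)`)
are verified by the test suite. See `docs/methods.md` for the full account.

Downstream, the package provides additive log-ratio (ALR) transforms with
pseudocount smoothing, paired Wilcoxon signed-rank tests per taxon (exact
tie-aware null for small n), covariate-adjusted regression of paired ALR
differences, Manhattan / Bray-Curtis distance matrices, PERMANOVA (exact
enumeration when feasible, sequential covariate adjustment otherwise), NMDS
ordination (Kruskal stress-1), and log-log regression of cytokine levels on
IgG-bound bacterial load.

A synthetic-cohort generator produces paired raw / IgG-bound communities —
oral-taxon-dominated unsorted profiles, *Pseudomonas*-enriched IgG-bound
profiles, a reagent contaminant admixed at a known per-sample proportion, a
group-dependent shift on the IgG-bound template, and cytokines log-linearly
coupled to bacterial load — so every stage can be checked against ground
truth.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_filter_contaminants.py
python analysis/03_community_analysis.py
python analysis/04_cytokine_association.py
```

The first script simulates the default cohort (22 uninfected + 42
disease-group participants, paired raw/IgG-bound samples, 4 negative-control
columns). The second filters it and checks recovery against truth:

    filtered 128 samples; median p_hat 0.221
    |p_hat - p_true/(1+p_true)|: median 0.0027, 90th pct 0.0164 (corr 0.992)
    mean depth retained: 78.32%

i.e. the estimator tracks the analytic fixed point `p/(1+p)` of the printed
objective to a few thousandths, and about 22% of reads are attributed to the
column background. The third script reports

    PERMANOVA (Manhattan distance):
      fraction:all       R2=0.689  p=0.001
      group:igg_bound    R2=0.267  p=0.001
      group:raw          R2=0.010  p=0.769

— IgG-bound and raw communities differ strongly, and the simulated group
effect is visible only in the IgG-bound fraction (it was injected only
there). The per-taxon paired ALR tests rank *Streptococcus*, *Prevotella*
and *Veillonella* higher in raw BAL and *Pseudomonas* higher in the
IgG-bound fraction. The fourth script regresses log cytokine on log
IgG-bound load: slopes near the simulated 0.5 with R² ≈ 0.85 in the disease
group, and flat (p > 0.35) in the uninfected group, where the generator
couples nothing.

The same stages are available as a CLI (`lungsort simulate`,
`lungsort filter`, `lungsort analyze`; see `--help`), each accepting
`--config config.yaml` and `--seed`.

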