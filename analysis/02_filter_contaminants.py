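#!/usr/bin/env python
"""Estimate and subtract the reagent contaminant from every cohort sample.

Averages the negative-control columns into the working contaminant profile,
estimates each sample's contaminant proportion by least squares, subtracts,
renormalises and rescales read depth.  Writes filtered.tsv and
filter_report.tsv under results/ and, because the cohort is synthetic,
checks the estimates against the known ground truth: under the printed
objective a noise-free admixture of proportion p is recovered as p/(1+p).
"""

import argparse

import numpy as np
import pandas as pd

from lungsort import filter_cohort, read_count_table, write_count_table
from lungsort.filtering import report_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort-dir", default="results/cohort")
    parser.add_argument("--out-dir", default="results")
    args = parser.parse_args()

    counts = read_count_table(f"{args.cohort_dir}/counts.tsv")
    controls = read_count_table(f"{args.cohort_dir}/controls.tsv")
    filtered, reports = filter_cohort(counts, controls)

    write_count_table(filtered, f"{args.out_dir}/filtered.tsv")
    rep = report_frame(reports)
    rep.to_csv(f"{args.out_dir}/filter_report.tsv", sep="\t")

    truth = pd.read_csv(f"{args.cohort_dir}/truth.tsv", sep="\t")
    p_true = truth.drop_duplicates("sample_id").set_index("sample_id")["p_true"]
    joined = rep.join(p_true).dropna()
    expected = joined["p_true"] / (1 + joined["p_true"])
    err = (joined["p_hat"] - expected).abs()
    print(f"filtered {len(rep)} samples; median p_hat {rep['p_hat'].median():.3f}")
    print(f"|p_hat - p_true/(1+p_true)|: median {err.median():.4f}, "
          f"90th pct {err.quantile(0.9):.4f} "
          f"(corr {np.corrcoef(joined['p_hat'], expected)[0, 1]:.3f})")
    print(f"mean depth retained: {(rep['depth_out'] / rep['depth_in']).mean():.2%}")
    print(f"wrote {args.out_dir}/filtered.tsv and {args.out_dir}/filter_report.tsv")


if __name__ == "__main__":
    main()
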