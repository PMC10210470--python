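#!/usr/bin/env python
"""Associate IgG-bound bacterial load with airway cytokine levels.

Log-log linear regression of each simulated cytokine on the per-participant
IgG-bound bacterial quantity, measured both by 16S qPCR copy number and by
flow-cytometry double-positive events, within each participant group.
Writes cytokine_assoc.tsv under results/ and prints slopes and R2: the
coupling exists only in the disease group, mirroring the generative model.
"""

import argparse

import pandas as pd

from lungsort import cytokine_association, read_metadata
from lungsort.metadata import metadata_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--metadata", default="results/cohort/metadata.tsv")
    parser.add_argument("--out-dir", default="results")
    args = parser.parse_args()

    meta = metadata_frame(read_metadata(args.metadata))
    bound = meta[meta["fraction"] == "igg_bound"]
    cytokines = [c for c in meta.columns if c.startswith("cytokine_")]
    rows = []
    for group, sub in bound.groupby("group"):
        for measure in ("qpcr_copies", "flow_events"):
            for col in cytokines:
                pairs = sub[[measure, col]].dropna()
                pairs = pairs[pairs[measure] > 0]
                if len(pairs) < 3:
                    continue
                reg = cytokine_association(pairs[measure], pairs[col])
                rows.append({
                    "group": group,
                    "cytokine": col.removeprefix("cytokine_"),
                    "measure": measure,
                    "slope": reg.slope,
                    "R2": reg.r2,
                    "p": reg.p_value,
                    "n": reg.n,
                })
    out = pd.DataFrame(rows)
    out.to_csv(f"{args.out_dir}/cytokine_assoc.tsv", sep="\t", index=False)
    for _, row in out.iterrows():
        print(f"{row['group']:<9} {row['cytokine']:<6} ~ {row['measure']:<12} "
              f"slope={row['slope']:+.3f}  R2={row['R2']:.3f}  p={row['p']:.3g}")


if __name__ == "__main__":
    main()
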