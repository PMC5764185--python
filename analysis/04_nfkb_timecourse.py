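#!/usr/bin/env python
"""Translocation dynamics: NF-kB-like nuclear-fraction time course.

Simulates a stimulation time course (0-120 min, 15-min sampling, 100 cells
per timepoint) whose true median nuclear fraction peaks at 60 min, runs the
full quantification pipeline at every timepoint and summarizes the per-cell
nuclear-fraction distributions (median, IQR, nonparametric skew) plus the
time-to-peak.  Writes results/nfkb_timecourse.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from sc2wb import quantify_images, simulate_timecourse, timecourse
from sc2wb.scenarios import nfkb_timecourse


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sc = nfkb_timecourse(100)
    sims = simulate_timecourse(
        sc.layout, sc.panel, sc.sim_kwargs["timepoints"], sc.sim_kwargs["curve"],
        sc.n_cells, seed=args.seed,
    )
    records = {}
    for tp, (images, _) in sims.items():
        _, cells, _ = quantify_images(images, sc.layout, sc.panel)
        records[tp] = cells.loc[cells["detected"], "nuc_fraction"].to_numpy()
    tc = timecourse(records)

    df = pd.DataFrame(
        [
            {"timepoint_min": tp, "n": s.n, "median_nuc": s.median, "iqr": s.iqr,
             "skew": s.skew, "mean": s.mean, "sd": s.sd}
            for tp, s in zip(tc.timepoints, tc.summaries)
        ]
    )
    df.to_csv(args.out / "nfkb_timecourse.csv", index=False)
    print(df.round(3).to_string(index=False))
    print(
        f"\nMedian nuclear fraction rises from ~{df['median_nuc'].iloc[0]:.2f} to "
        f"{df['median_nuc'].max():.2f} with a time-to-peak of "
        f"{tc.time_to_peak:.0f} min, then relaxes toward baseline."
    )


if __name__ == "__main__":
    main()
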