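#!/usr/bin/env python
"""Cohort report: initiation/outcome/class counts and tract-length medians
with bootstrap confidence limits, from the event calls of script 02.

Re-runs the same seeded cohort (the calls TSV has no strand detail), then
writes results/cohort_summary.json and prints the summary.
"""

import argparse
import json
from pathlib import Path

import hetdna as h

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=60)
    ap.add_argument("--seed", type=int, default=20250926)
    ap.add_argument("--sigma", type=float, default=0.1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    marker_map = h.chr5_like_map(args.seed)
    cfg = h.SimConfig(seed=args.seed)
    analyses = h.run_cohort(
        cfg, marker_map, args.n, seed=args.seed, noise_sigma=args.sigma
    )
    summary = h.summarize_cohort(
        [a.call for a in analyses], seed=args.seed, n_boot=10_000
    )

    print(f"Colonies: {summary.n_colonies}")
    print(f"Initiation: {summary.initiation_counts}")
    print(f"Outcomes:   {summary.outcome_counts}")
    print(f"Classes:    {dict(sorted(summary.class_counts.items(), key=str))}")
    if summary.nco_median is not None:
        lo, hi = summary.nco_cl
        print(
            f"NCO tract median {summary.nco_median / 1000:.1f} kb"
            f" (95% CL {lo / 1000:.1f}-{hi / 1000:.1f})"
        )
    if summary.co_median is not None:
        lo, hi = summary.co_cl
        print(
            f"CO tract median {summary.co_median / 1000:.1f} kb"
            f" (95% CL {lo / 1000:.1f}-{hi / 1000:.1f}; per-event sums over"
            " the two crossover chromatids)"
        )
    if summary.all_median is not None:
        lo, hi = summary.all_cl
        print(
            f"All tracts median {summary.all_median / 1000:.1f} kb"
            f" (95% CL {lo / 1000:.1f}-{hi / 1000:.1f})"
        )

    with open(OUT / "cohort_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    print(f"Wrote {OUT / 'cohort_summary.json'}")


if __name__ == "__main__":
    main()
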