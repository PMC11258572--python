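#!/usr/bin/env python
"""Run the six-hypothesis nonparametric battery on the synthetic cohort.

Uses the cohort's generated (true) aTSC values — imaging noise is studied
separately in 05 — and writes the full comparison table and verdicts to
results/.  Prints one line per hypothesis.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from natsc.cohort import CohortDesign, generate_cohort
from natsc.pipeline import run_h_battery, score_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-resamples", type=int, default=100_000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    scored = score_cohort(generate_cohort(CohortDesign(seed=args.seed)))
    reports = run_h_battery(scored, n_resamples=args.n_resamples, seed=args.seed)

    with open(args.out / "hypothesis_reports.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2, sort_keys=True)

    rows = []
    for r in reports:
        for c in r.comparisons:
            rows.append({
                "hypothesis": c.hypothesis, "variable": c.variable,
                "pairing": c.pairing, "test": c.test,
                "statistic": None if c.result is None else c.result.statistic,
                "p_value": None if c.result is None else c.result.p_value,
                "n": None if c.result is None else c.result.n,
                "effect_size": None if c.result is None else c.result.effect_size,
                "method": None if c.result is None else c.result.method,
                "note": c.note,
            })
    pd.DataFrame(rows).to_csv(args.out / "hypothesis_comparisons.csv", index=False)

    for r in reports:
        sig = sum(c.result is not None and c.result.p_value < r.alpha for c in r.comparisons)
        print(f"{r.hypothesis}: {r.verdict:<20} ({sig}/{len(r.comparisons)} "
              f"comparisons significant at alpha={r.alpha})")
    print(f"wrote {args.out / 'hypothesis_reports.json'}")


if __name__ == "__main__":
    main()
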