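#!/usr/bin/env python
"""Parameter-recovery study: how well does the partial-volume regression
recover the true tissue concentrations across noise levels?

For each noise level (0, 2%, 5% of the mean parenchymal signal) the same
head geometry is imaged with 20 noise seeds, calibrated with the
partial-volume-corrected vitreous reference, and quantified.  Writes
results/phantom_recovery.csv and prints the error summary.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from natsc.phantom import PhantomGeometry, PhantomTruth
from natsc.pipeline import ImagingSimulator

TRUE_GM, TRUE_WM = 35.0, 30.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-phantoms", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geometry = PhantomGeometry()
    truth = PhantomTruth(hi_res_voxel_mm=(2.0, 2.0, 2.0))
    seeds = np.random.SeedSequence(args.seed).generate_state(args.n_phantoms) % (2**31)

    rows = []
    for level in (0.0, 0.02, 0.05):
        sim = ImagingSimulator(geometry, truth, noise_level=level)
        for s in seeds:
            gm, wm = sim.quantify(sim.acquire(TRUE_GM, TRUE_WM, int(s)))
            rows.append({"noise_level": level, "seed": int(s),
                         "atsc_gm": gm, "atsc_wm": wm,
                         "err_gm": gm - TRUE_GM, "err_wm": wm - TRUE_WM})
            if level == 0.0:
                break  # noiseless run is deterministic

    df = pd.DataFrame(rows)
    df.to_csv(args.out / "phantom_recovery.csv", index=False)
    print(f"true concentrations: GM {TRUE_GM} mM, WM {TRUE_WM} mM")
    for level, sub in df.groupby("noise_level"):
        print(f"noise {level:4.0%}:  median |err| GM {sub.err_gm.abs().median():.3f} mM, "
              f"WM {sub.err_wm.abs().median():.3f} mM  (n={len(sub)})")
    print(f"wrote {args.out / 'phantom_recovery.csv'}")


if __name__ == "__main__":
    main()
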