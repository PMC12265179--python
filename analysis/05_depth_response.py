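#!/usr/bin/env python
"""Depth of origin of detected backscattered electrons.

Monte Carlo depth-of-origin histograms (5 nm bins) for 1.5 keV electrons in
plain resin and in 25/50 at.% Ga-implanted resin, with the 700 eV ESB
acceptance floor.  The compression of this distribution by the implant is the
mechanism behind the improved z-resolution.  Writes results/depth_response.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fibsemga import materials as M
from fibsemga import montecarlo as mc

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=100_000)
    args = ap.parse_args()

    beam = mc.BeamConfig(energy=1.5)
    esb = mc.ESBFilter(700.0)
    rows = []
    for i, name in enumerate(["epon_araldite", "epon_ga25", "epon_ga50"]):
        counts, edges, depths = mc.depth_response(
            M.preset(name), beam, args.n, esb, np.random.default_rng(args.seed + i)
        )
        frac = counts / max(depths.size, 1)
        for lo, hi, f in zip(edges[:-1], edges[1:], frac):
            rows.append({"material": name, "depth_lo_nm": lo, "depth_hi_nm": hi,
                         "fraction": f})
        print(
            f"{name:>14}: accepted yield {depths.size / args.n:.4f}, "
            f"median depth {np.median(depths):.1f} nm, "
            f"p90 {np.percentile(depths, 90):.1f} nm, "
            f"fraction beyond 20 nm {(depths > 20).mean():.3f}"
        )

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "depth_response.csv", index=False)


if __name__ == "__main__":
    main()
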