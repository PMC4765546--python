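#!/usr/bin/env python
"""Per-population selfing-rate likelihood profiles.

Fits the multilocus-heterozygosity mixture to every population, writes the
full profiles (s, log-likelihood) and a summary table of MLEs with 95 %
likelihood intervals, and compares each estimate against the ground truth
recorded by the simulation step.
"""

import json
from pathlib import Path

import pandas as pd

from plantmating import geno_io, selfing

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "selfing"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pops = geno_io.from_csv(ROOT / "data" / "populations.csv")
    truth = json.loads((ROOT / "data" / "truth.json").read_text())
    true_s = {n: v["s"] for n, v in truth["metapopulation"]["populations"].items()}

    rows = []
    for name, g in pops.items():
        prof = selfing.fit_selfing(g, grid_step=0.001)
        prof.to_frame().to_csv(OUT / f"profile_{name}.tsv", sep="\t",
                               index=False, float_format="%.6g")
        lo, hi = prof.ci95
        covered = lo <= true_s[name] <= hi
        rows.append({"population": name, "ecotype": g.meta.ecotype,
                     "s_true": round(true_s[name], 3),
                     "s_hat": round(prof.s_hat, 3),
                     "ci_low": round(lo, 3), "ci_high": round(hi, 3),
                     "true_in_ci": covered})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "selfing_rates.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\n{int(df.true_in_ci.sum())}/{len(df)} true rates inside their "
          "95% likelihood interval")


if __name__ == "__main__":
    main()
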