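#!/usr/bin/env python
"""Generate the synthetic study data set every later step analyses.

Emulated design: 10 populations (5 metallicolous + 5 non-metallicolous),
45 plants each, 14 microsatellite loci with ~6 alleles, ecotype mean selfing
0.25 vs 0.40, Balding-Nichols divergence theta = 0.25; 20-mother progeny
arrays of 15 seeds; two consecutive seasonal samples per population drifting
at Ne = 100.  Writes Genepop + CSV inputs plus the ground-truth record under
results/data/.
"""

import json
from pathlib import Path

from plantmating import geno_io, synthdata

SEED = 20260929
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthdata.SimConfig(seed=SEED)
    pops, truth = synthdata.sim_metapopulation(cfg)
    arrays, progeny_truth = synthdata.sim_progeny_arrays(cfg)
    pair, temporal_truth = synthdata.sim_temporal(cfg)

    (OUT / "populations.gen").write_text(geno_io.write_genepop(pops))
    geno_io.to_csv(pops, OUT / "populations.csv")
    geno_io.progeny_to_csv(arrays, OUT / "progeny.csv")
    pair.sample0.meta.population = "t0"
    pair.sample1.meta.population = "t1"
    geno_io.to_csv({"t0": pair.sample0, "t1": pair.sample1},
                   OUT / "temporal_pair.csv")
    (OUT / "truth.json").write_text(json.dumps(
        {"seed": SEED, "metapopulation": truth, "progeny": progeny_truth,
         "temporal": {k: v for k, v in temporal_truth.items()
                      if k in ("Ne", "g")}}, indent=1))
    true_s = {n: round(v["s"], 4) for n, v in truth["populations"].items()}
    print(f"wrote {len(pops)} populations, {arrays.n_families} families, "
          f"1 temporal pair to {OUT}")
    print("true population selfing rates:", true_s)


if __name__ == "__main__":
    main()
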