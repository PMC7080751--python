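#!/usr/bin/env python
"""Generate the synthetic datasets every downstream analysis step consumes.

Emulates the two experimental designs at the esophageal (and dorsal) inferred
parameter values: a lineage-tracing clone table (~300 clones per time point
at 10/30/84/180 days across 3-6 mice) and H2B-GFP chase intensity tables
(chases 0/7/12/18 days, 5 fields of view per animal, CD45+ leukocyte
contaminants).  Writes CSVs under results/data/.
"""

import numpy as np

import epiclone as ec
from epiclone import io

SEED = 1
OUT = "results/data"


def main():
    rng = np.random.default_rng(np.random.SeedSequence([SEED, 1]))

    truth = ec.get_preset("esophagus-lrig1").params()
    clones = ec.generate_lineage_experiment(truth, ec.LineageDesign(), rng)
    io.write_table(clones, f"{OUT}/esophagus_lrig1_clones.csv")
    per_time = clones.groupby("time_days").size()
    print(f"esophageal clone table: {len(clones)} surviving clones "
          f"({', '.join(f'{int(t)}d: {n}' for t, n in per_time.items())})")

    for preset in ("esophagus-lrig1", "dorsum"):
        chase = ec.generate_h2bgfp_experiment(
            ec.get_preset(preset).params(), ec.ChaseDesign(), rng
        )
        path = f"{OUT}/{preset.replace('-', '_')}_chase.csv"
        io.write_table(chase, path)
        print(f"{preset} chase table: {len(chase)} nuclei "
              f"({int(chase['is_leukocyte'].sum())} leukocytes) -> {path}")


if __name__ == "__main__":
    main()
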