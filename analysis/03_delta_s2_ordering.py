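#!/usr/bin/env python
"""Delta-S2 ordering analysis of a ligand-induced loop-folding event.

Generates apo/bound order-parameter sets for a 150-residue protein in which
one 13-residue loop (residues 130-142, the catalytic-loop scenario) gains
+0.3 in S2 on ligand binding, then runs the trimmed-mean + 3 SD threshold
and contiguous-stretch caller. Writes results/delta_s2.csv and prints the
stretch report.
"""

from pathlib import Path

import pandas as pd

from akfray.order_change import call_ordering
from akfray.synthetic import gen_order_sets

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 3


def main() -> None:
    OUT.mkdir(exist_ok=True)
    apo, bound = gen_order_sets(
        n_res=150, spike_range=(130, 142), spike=0.3, noise=0.01, seed=SEED
    )
    result = call_ordering(apo, bound)
    pd.DataFrame(
        {"residue": list(result.deltas), "delta_S2": list(result.deltas.values())}
    ).to_csv(OUT / "delta_s2.csv", index=False)
    print(f"threshold (trimmed mean + 3 SD): {result.threshold:.4f}")
    print(f"significant residues: {len(result.significant)}")
    for a, b in result.stretches:
        print(f"contiguous stretch: {a}-{b} ({b - a + 1} residues)")
    for r in result.isolated:
        print(f"isolated significant residue (flagged, not a stretch): {r}")
    print("\nExactly one contiguous stretch covering the programmed loop is "
          "the expected signature of a coupled folding-and-binding event.")


if __name__ == "__main__":
    main()
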