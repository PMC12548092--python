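#!/usr/bin/env python
"""Helix tilt / translation / fraying recovery on programmed structures.

Builds ideal two-state helix pairs embedded next to a static core: state B
is tilted 21 degrees, translated 5.8 A and frayed over its last 3 residues
(the magnitude of the helix rearrangement accompanying subdomain closure in
the archaeal adenylate kinase). Superposes on the core, fits helix axes and
recovers the programmed geometry across 20 seeds of 0.01 A coordinate
jitter. Writes results/helix_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from akfray.helix import compare_helix
from akfray.synthetic import gen_helix
from akfray.validation import helix_recovery

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 5


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ref, moved = gen_helix(16, tilt_deg=21.0, translation_ang=5.8, n_fray=3, seed=SEED)
    cmp = compare_helix(ref, moved, (1, 16), (101, 120))
    print("single noiseless pair:")
    print(f"  tilt        {cmp.tilt_deg:6.2f} deg   (programmed 21.00)")
    print(f"  translation {cmp.translation_ang:6.3f} A     (programmed 5.800)")
    print(f"  frayed C-terminal residues: {cmp.frayed_c_terminal} (programmed last 3)")
    print(f"  core RMSD after superposition: {cmp.core_rmsd_ang:.2e} A")

    stats = helix_recovery(seed=SEED, n_seeds=20)
    pd.DataFrame([stats]).to_csv(OUT / "helix_recovery.csv", index=False)
    print(f"\nacross {stats['n']} jittered seeds:")
    print(f"  worst tilt error        {stats['max_tilt_err_deg']:.3f} deg (tolerance 0.5)")
    print(f"  worst translation error {stats['max_translation_err_ang']:.4f} A (tolerance 0.05)")
    print(f"  frayed set exact in all seeds: {stats['fray_exact_all_seeds']}")


if __name__ == "__main__":
    main()
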