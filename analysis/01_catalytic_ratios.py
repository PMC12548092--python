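#!/usr/bin/env python
"""Fold-change arithmetic on the published AKeco catalytic parameters.

Computes specificity constants (kcat/K_M) and fold changes of kcat, K_M and
specificity for the Lys47Ala and Glu114Ala helix-terminus variants relative
to wild type, with propagated errors, and writes the ratio table to
results/catalytic_ratios.csv.
"""

from pathlib import Path

from akfray.validation import table1_ratios

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = table1_ratios()
    table.to_csv(OUT / "catalytic_ratios.csv")
    wt, k47a, e114a = (table.loc[v] for v in ("wild_type", "K47A", "E114A"))
    print("Specificity constants (uM^-1 s^-1):")
    for name, row in table.iterrows():
        print(f"  {name:10s} {row.specificity_uM_s:5.2f} +- {row.specificity_err:.2f}")
    print(f"\nK47A:  kcat fold {k47a.kcat_fold:.2f}, K_M fold {k47a.KM_fold:.2f}, "
          f"specificity fold {k47a.specificity_fold:.2f}")
    print(f"E114A: kcat fold {e114a.kcat_fold:.2f}, K_M fold {e114a.KM_fold:.2f}, "
          f"specificity fold {e114a.specificity_fold:.2f}")
    print("\nThe Lys47Ala substitution raises turnover ~1.3-fold at unchanged K_M "
          "(specificity x1.22); Glu114Ala lowers K_M ~3-fold, more than doubling "
          "the specificity constant despite a slightly reduced kcat.")


if __name__ == "__main__":
    main()
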