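"""Change-in-order statistic between ligation states.

Delta-S2 = S2(bound) - S2(apo) per residue; a positive value means the
amide became more ordered on ligand binding. Significance is called
against a threshold of the trimmed mean plus three standard deviations of
the trimmed sample, and significant residues are reported as maximal
contiguous stretches of sequence (isolated single residues are flagged,
since a lone significant residue is not evidence of a folding segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrderParameterSet",
    "DeltaS2Result",
    "delta_s2",
    "significance_threshold",
    "find_stretches",
    "call_ordering",
]


@dataclass
class OrderParameterSet:
    """Per-residue generalized order parameters of one state."""

    label: str
    s2: dict[int, float]
    s2_err: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.s2) != len(set(self.s2)):  # dict keys are unique by nature
            raise ValueError("duplicate residues")
        for res, v in self.s2.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"S2 out of [0,1] at residue {res}: {v}")


def delta_s2(apo: OrderParameterSet, bound: OrderParameterSet) -> dict[int, float]:
    """S2(bound) - S2(apo) on the shared residues."""
    shared = sorted(set(apo.s2) & set(bound.s2))
    if not shared:
        raise ValueError("no shared residues between the two states")
    return {r: bound.s2[r] - apo.s2[r] for r in shared}


def significance_threshold(deltas, trim_fraction: float = 0.1) -> float:
    """Trimmed mean + 3 * SD of the trimmed sample.

    trim_fraction is removed from each tail before computing both moments.
    """
    values = np.sort(np.asarray(list(deltas), dtype=float))
    if values.size < 10:
        raise ValueError("need >= 10 values for a threshold")
    k = int(np.floor(trim_fraction * values.size))
    trimmed = values[k : values.size - k] if values.size > 2 * k else values
    return float(np.mean(trimmed) + 3.0 * np.std(trimmed, ddof=0))


def find_stretches(residues) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residue numbers as inclusive [start, end]."""
    ids = sorted(set(int(r) for r in residues))
    stretches: list[tuple[int, int]] = []
    for r in ids:
        if stretches and r == stretches[-1][1] + 1:
            stretches[-1] = (stretches[-1][0], r)
        else:
            stretches.append((r, r))
    return stretches


@dataclass
class DeltaS2Result:
    deltas: dict[int, float]
    threshold: float
    significant: list[int]
    stretches: list[tuple[int, int]]
    isolated: list[int]


def call_ordering(
    apo: OrderParameterSet, bound: OrderParameterSet, trim_fraction: float = 0.1
) -> DeltaS2Result:
    """Full pipeline: deltas, threshold, significant set, stretch calling.

    Significance is strict (> threshold). Stretches of length one are kept
    in the result but reported separately as isolated.
    """
    deltas = delta_s2(apo, bound)
    thr = significance_threshold(deltas.values(), trim_fraction=trim_fraction)
    sig = [r for r, d in sorted(deltas.items()) if d > thr]
    stretches = find_stretches(sig)
    isolated = [a for a, b in stretches if a == b]
    return DeltaS2Result(
        deltas=deltas,
        threshold=thr,
        significant=sig,
        stretches=[s for s in stretches if s[0] != s[1]],
        isolated=isolated,
    )
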