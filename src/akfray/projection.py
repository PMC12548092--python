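"""Chemical-shift projection analysis of the open-closed equilibrium.

For each amide, a reference vector A is built from the wild-type open ->
closed shift change, A = (d_dH, w * d_dN) in ppm with w the 15N weight of
the compound amide shift. The corresponding shift change B of a variant is
projected onto A:

    cos(theta) = A.B / (|A||B|)    -- directionality of the change
    X          = A.B / |A|^2       -- degree of closure relative to wild type

so a variant whose peaks move exactly as far along the wild-type trajectory
has X = 1, and X = 0 means no motion along the open-closed direction.
Residues with |A| below a magnitude cutoff are excluded (near-zero
denominators carry no directional information) and listed with the reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShiftRecord",
    "ProjectionResult",
    "ProjectionSummary",
    "reference_vector",
    "project",
    "project_tables",
    "summarize",
]

N15_WEIGHT_DEFAULT = 0.2
A_CUTOFF_PPM = 0.025


@dataclass
class ShiftRecord:
    """Amide 1H/15N chemical shift of one residue in one state."""

    residue: int
    d_h_ppm: float
    d_n_ppm: float
    state: str


@dataclass
class ProjectionResult:
    residue: int
    cos_theta: float
    x: float
    a_mag_ppm: float
    flagged: str = ""


def _to_map(records) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    for r in records:
        if r.residue in out:
            raise ValueError(f"duplicate residue {r.residue} in state {r.state}")
        out[r.residue] = (r.d_h_ppm, r.d_n_ppm)
    return out


def reference_vector(
    open_wt, closed_wt, n15_weight: float = N15_WEIGHT_DEFAULT
) -> dict[int, np.ndarray]:
    """Weighted open->closed shift vectors A per shared residue."""
    o = _to_map(open_wt)
    c = _to_map(closed_wt)
    shared = sorted(set(o) & set(c))
    return {
        r: np.array([c[r][0] - o[r][0], n15_weight * (c[r][1] - o[r][1])])
        for r in shared
    }


def project(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(cos_theta, X) of variant vector b against reference a.

    b = 0 gives (nan, 0): the direction of a zero change is undefined.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0:
        raise ValueError("reference vector has zero magnitude")
    if nb == 0.0:
        return float("nan"), 0.0
    dot = float(a @ b)
    return dot / (na * nb), dot / (na * na)


def project_tables(
    open_wt,
    closed_wt,
    variant_apo,
    variant_bound,
    n15_weight: float = N15_WEIGHT_DEFAULT,
    a_cutoff_ppm: float = A_CUTOFF_PPM,
) -> tuple[list[ProjectionResult], list[tuple[int, str]]]:
    """Per-residue projection of the variant open->bound change onto the
    wild-type open->closed reference. Returns results plus the excluded
    residues with reasons.
    """
    refs = reference_vector(open_wt, closed_wt, n15_weight)
    va = _to_map(variant_apo)
    vb = _to_map(variant_bound)
    results: list[ProjectionResult] = []
    excluded: list[tuple[int, str]] = []
    for r in sorted(set(refs) & set(va) & set(vb)):
        a = refs[r]
        na = float(np.linalg.norm(a))
        if na < a_cutoff_ppm:
            excluded.append((r, f"|A|={na:.4f} ppm below cutoff {a_cutoff_ppm}"))
            continue
        b = np.array(
            [vb[r][0] - va[r][0], n15_weight * (vb[r][1] - va[r][1])]
        )
        cos_t, x = project(a, b)
        flagged = "zero variant vector" if np.isnan(cos_t) else ""
        results.append(ProjectionResult(r, cos_t, x, na, flagged))
    return results, excluded


@dataclass
class ProjectionSummary:
    mean_x: float
    sd_x: float
    n_retained: int


def summarize(results, cos_cutoff: float = 0.9) -> ProjectionSummary:
    """Mean +- SD of X over residues with cos_theta > cos_cutoff."""
    xs = np.array(
        [r.x for r in results if np.isfinite(r.cos_theta) and r.cos_theta > cos_cutoff]
    )
    if xs.size == 0:
        return ProjectionSummary(float("nan"), float("nan"), 0)
    sd = float(np.std(xs, ddof=1)) if xs.size > 1 else 0.0
    return ProjectionSummary(float(np.mean(xs)), sd, int(xs.size))
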