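"""Seeded synthetic-data generators for every analysis stage.

Each generator produces data with the statistical structure its paired
analysis stage assumes — exponential peak-height decays around model-free
predicted T1/T2, four-state amide shift tables with a known closure
fraction, ideal alpha-helices with programmed tilt/translation/fraying,
Michaelis-Menten velocity tables, reversible-kinase progress curves and
two-state thermal melts — together with the ground truth used to make
them, so every fitting operation can be tested by parameter recovery
without external data. Noise is Gaussian with a stated fraction of the
maximum signal; seeds are explicit arguments and never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import helix as hx
from .constants import PhysicalConstants
from .kinetics import KEQ_DEFAULT, mm_velocity, progress_model, melt_model
from .modelfree import ModelFreeParams, predict_rates
from .order_change import OrderParameterSet
from .projection import N15_WEIGHT_DEFAULT, A_CUTOFF_PPM, ShiftRecord
from .relaxation import T1_DELAYS_S, T2_DELAYS_S, RelaxationRecord

__all__ = [
    "GroundTruth",
    "gen_relaxation",
    "gen_shift_table",
    "gen_helix",
    "gen_kinked_helix",
    "gen_order_sets",
    "gen_kinetics",
    "gen_progress",
    "gen_melt",
    "write_manifest",
]


@dataclass
class GroundTruth:
    """Truth values a recovery test compares against."""

    s2: dict[int, float] = field(default_factory=dict)  # per-residue, unitless
    tau_e_ps: dict[int, float] = field(default_factory=dict)
    tau_m_ns: float = 9.0
    field_mhz: float = 850.0
    closure_x: float = 1.0
    helix_rise: float = 1.5  # A/residue (ideal construction)
    helix_twist: float = 100.0  # deg/residue
    helix_radius: float = 2.3  # A (CA)
    kcat: float = 360.0  # s^-1
    km_um: float = 110.0
    tm_c: float = 52.0
    dh_kj: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for res, v in self.s2.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"non-physical S2={v} at residue {res}")
        for res, v in self.tau_e_ps.items():
            if v < 0:
                raise ValueError("tau_e must be >= 0")
        if self.tau_m_ns <= 0:
            raise ValueError("tau_m must be > 0")


# ---------------------------------------------------------------------------
# Relaxation peak tables


def _delay_columns(delays_s) -> list[str]:
    cols, seen = [], {}
    for d in delays_s:
        ms = d * 1000.0
        key = f"d{ms:g}ms"
        seen[key] = seen.get(key, 0) + 1
        cols.append(key if seen[key] == 1 else f"{key}#{seen[key]}")
    return cols


def gen_relaxation(
    truth: GroundTruth,
    delays_t1=None,
    delays_t2=None,
    noise_fraction: float = 0.01,
    i0: float = 100.0,
):
    """Synthetic peak-intensity tables for T1, T2 and NOE experiments.

    Intensities decay exponentially around the T1/T2 predicted by the
    model-free forward model from the per-residue truth; the NOE table
    carries saturated/unsaturated intensities whose ratio is the predicted
    NOE. Duplicated delays in the default schedules are emitted as repeated
    columns. Returns (tables, true_records) where tables is a dict with
    keys "T1", "T2", "noe" holding DataFrames.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    delays_t1 = np.asarray(T1_DELAYS_S if delays_t1 is None else delays_t1, float)
    delays_t2 = np.asarray(T2_DELAYS_S if delays_t2 is None else delays_t2, float)
    if np.any(delays_t1 <= 0) or np.any(delays_t2 <= 0):
        raise ValueError("delays must be positive")
    rng = np.random.default_rng(truth.seed)
    consts = PhysicalConstants(field_mhz=truth.field_mhz)

    rows_t1, rows_t2, rows_noe, records = [], [], [], []
    sigma = noise_fraction * i0
    for res in sorted(truth.s2):
        p = ModelFreeParams(
            s2=truth.s2[res],
            tau_e_ps=truth.tau_e_ps.get(res, 0.0),
            tau_m_ns=truth.tau_m_ns,
        )
        t1, t2, noe = predict_rates(p, consts)
        y1 = i0 * np.exp(-delays_t1 / t1) + rng.normal(0.0, sigma, delays_t1.shape)
        y2 = i0 * np.exp(-delays_t2 / t2) + rng.normal(0.0, sigma, delays_t2.shape)
        i_unsat = i0 + rng.normal(0.0, sigma)
        i_sat = noe * i0 + rng.normal(0.0, sigma)
        rows_t1.append([res, f"X{res}N-H", *y1])
        rows_t2.append([res, f"X{res}N-H", *y2])
        rows_noe.append([res, i_sat, i_unsat, sigma, sigma])
        records.append(
            RelaxationRecord(
                residue=res, t1=t1, t1_err=0.0, t2=t2, t2_err=0.0,
                noe=noe, noe_err=0.0, field_mhz=truth.field_mhz,
            )
        )
    tables = {
        "T1": pd.DataFrame(
            rows_t1, columns=["residue", "assignment", *_delay_columns(delays_t1)]
        ),
        "T2": pd.DataFrame(
            rows_t2, columns=["residue", "assignment", *_delay_columns(delays_t2)]
        ),
        "noe": pd.DataFrame(
            rows_noe,
            columns=["residue", "I_sat", "I_unsat", "sigma_sat", "sigma_unsat"],
        ),
    }
    return tables, records


# ---------------------------------------------------------------------------
# Four-state shift tables


def gen_shift_table(
    n_residues: int,
    closure_x: float,
    off_pathway_amplitude: float = 0.0,
    seed: int = 0,
    n15_weight: float = N15_WEIGHT_DEFAULT,
    shift_noise_ppm: float = 0.0,
):
    """Four-state amide shift table with a known closure fraction.

    The wild-type open->closed vectors are drawn with weighted magnitudes
    above the |A| cutoff; the variant-apo state equals open-wt and the
    variant-bound state is displaced by closure_x along the reference
    vector plus an orthogonal perturbation of the stated amplitude (ppm,
    weighted space). shift_noise_ppm adds Gaussian peak-position noise
    (1H scale; 15N noise scaled by 1/weight) to every state independently,
    emulating measurement uncertainty. Returns a dict
    state -> list[ShiftRecord].
    """
    if off_pathway_amplitude < 0:
        raise ValueError("off-pathway amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    states = {s: [] for s in ("open-wt", "closed-wt", "variant-apo", "variant-bound")}
    for res in range(1, n_residues + 1):
        h0 = rng.normal(8.3, 0.4)
        n0 = rng.normal(119.0, 3.0)
        mag = rng.uniform(3.0 * A_CUTOFF_PPM, 0.3)  # weighted |A|, safely above cutoff
        ang = rng.uniform(0.0, 2.0 * math.pi)
        a = mag * np.array([math.cos(ang), math.sin(ang)])  # weighted space
        orth = np.array([-a[1], a[0]]) / mag
        b = closure_x * a + off_pathway_amplitude * orth * rng.choice([-1.0, 1.0])
        # back to unweighted ppm: (dH, dN) with dN = component / weight
        da = (a[0], a[1] / n15_weight)
        db = (b[0], b[1] / n15_weight)
        shifts = {
            "open-wt": (h0, n0),
            "closed-wt": (h0 + da[0], n0 + da[1]),
            "variant-apo": (h0, n0),
            "variant-bound": (h0 + db[0], n0 + db[1]),
        }
        for state, (dh, dn) in shifts.items():
            if shift_noise_ppm > 0:
                dh += rng.normal(0.0, shift_noise_ppm)
                dn += rng.normal(0.0, shift_noise_ppm / n15_weight)
            states[state].append(ShiftRecord(res, dh, dn, state))
    return states


# ---------------------------------------------------------------------------
# Helices

CORE_FIRST, CORE_LAST = 101, 120
CORE_OFFSET = np.array([40.0, 0.0, 0.0])


def _helix_torsions(n_res: int) -> list[tuple[float, float]]:
    return [(hx.PHI_HELIX, hx.PSI_HELIX)] * n_res


def _frayed_torsions(n_res: int, n_fray: int, terminus: str) -> list[tuple[float, float]]:
    tor = list(_helix_torsions(n_res))
    if n_fray <= 0:
        return tor
    if terminus == "C":
        # the psi of the residue preceding the frayed run must move too,
        # otherwise the first frayed residue keeps its amide donor H-bond
        i0 = n_res - n_fray
        tor[i0 - 1] = (hx.PHI_HELIX, hx.PSI_EXT)
        for i in range(i0, n_res):
            tor[i] = (hx.PHI_EXT, hx.PSI_EXT)
    elif terminus == "N":
        for i in range(n_fray):
            tor[i] = (hx.PHI_EXT, hx.PSI_EXT)
        tor[n_fray] = (hx.PHI_EXT, hx.PSI_HELIX)
    else:
        raise ValueError("terminus must be 'N' or 'C'")
    return tor


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * k + (1.0 - math.cos(a)) * (k @ k)


def _add_core(model: hx.StructureModel) -> None:
    core = hx.build_backbone(
        _helix_torsions(CORE_LAST - CORE_FIRST + 1), first_residue=CORE_FIRST
    )
    for num, res in core.chains["A"].items():
        for a in res.atoms:
            res.atoms[a] = res.atoms[a] + CORE_OFFSET
        model.chains["A"][num] = res


def gen_helix(
    n_res: int,
    tilt_deg: float = 0.0,
    translation_ang: float = 0.0,
    n_fray: int = 0,
    seed: int = 0,
    terminus: str = "C",
    include_core: bool = True,
    coord_noise_ang: float = 0.0,
):
    """Reference/transformed ideal alpha-helix pair with programmed geometry.

    The reference is an ideal helix (phi=-57, psi=-47) at residues
    1..n_res; the transformed copy is rotated by tilt_deg about an axis
    perpendicular to the helix axis through the centroid of the folded
    part's helix-center points, displaced by translation_ang perpendicular
    to the helix axis, and frayed (extended phi/psi) over n_fray terminal
    residues. With include_core, a static helix at residues 101-120 is
    added to both states as a superposition reference. coord_noise_ang
    adds independent Gaussian coordinate jitter (A) to both states,
    emulating coordinate error of refined models.
    """
    if n_res < 8:
        raise ValueError("need n_res >= 8 for axis fitting (>= 2 turns)")
    if n_fray >= n_res - 4:
        raise ValueError("fraying would leave no folded helix")
    ref = hx.build_backbone(_helix_torsions(n_res))
    frayed = hx.build_backbone(_frayed_torsions(n_res, n_fray, terminus))

    if terminus == "C":
        folded = list(range(1, n_res - n_fray + 1))
    else:
        folded = list(range(n_fray + 1, n_res + 1))
    ca = np.array([ref.chains["A"][i].atoms["CA"] for i in folded])
    axis = hx.fit_axis(ca)
    rot_axis = np.cross(axis.direction, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(rot_axis) < 1e-6:
        rot_axis = np.cross(axis.direction, np.array([0.0, 1.0, 0.0]))
    rot_axis /= np.linalg.norm(rot_axis)
    rot = _rotation_about(rot_axis, tilt_deg)
    shift_dir = np.cross(axis.direction, rot_axis)
    shift_dir /= np.linalg.norm(shift_dir)
    anchor = axis.anchor
    moved = frayed.copy()
    for res in moved.chains["A"].values():
        for a in res.atoms:
            res.atoms[a] = rot @ (res.atoms[a] - anchor) + anchor + translation_ang * shift_dir

    if include_core:
        _add_core(ref)
        _add_core(moved)
    if coord_noise_ang > 0:
        rng = np.random.default_rng(seed)
        for model in (ref, moved):
            for res in model.chains["A"].values():
                for a in res.atoms:
                    res.atoms[a] = res.atoms[a] + rng.normal(0.0, coord_noise_ang, 3)
    return ref, moved


def gen_kinked_helix(n_res: int, kink_deg: float, split: int) -> hx.StructureModel:
    """Ideal helix with a programmed kink: residues > split rotated by
    kink_deg about an axis perpendicular to the helix axis through the
    CA of the split residue."""
    model = hx.build_backbone(_helix_torsions(n_res))
    residues = model.chains["A"]
    ca = np.array([residues[i].atoms["CA"] for i in range(1, n_res + 1)])
    axis = hx.fit_axis(ca)
    rot_axis = np.cross(axis.direction, np.array([1.0, 0.0, 0.0]))
    rot_axis /= np.linalg.norm(rot_axis)
    rot = _rotation_about(rot_axis, kink_deg)
    pivot = residues[split].atoms["CA"]
    for num in range(split + 1, n_res + 1):
        for a in residues[num].atoms:
            residues[num].atoms[a] = rot @ (residues[num].atoms[a] - pivot) + pivot
    return model


# ---------------------------------------------------------------------------
# Order-parameter sets with a spiked loop


def gen_order_sets(
    n_res: int = 150,
    spike_range: tuple[int, int] = (130, 142),
    spike: float = 0.3,
    noise: float = 0.01,
    base_s2: float = 0.85,
    seed: int = 0,
) -> tuple[OrderParameterSet, OrderParameterSet]:
    """Apo/bound order-parameter sets where one contiguous loop gains order."""
    rng = np.random.default_rng(seed)
    apo, bound = {}, {}
    lo, hi = spike_range
    for res in range(1, n_res + 1):
        a = base_s2 - (spike if lo <= res <= hi else 0.0)
        b = base_s2
        apo[res] = float(np.clip(a + rng.normal(0.0, noise), 0.0, 1.0))
        bound[res] = float(np.clip(b + rng.normal(0.0, noise), 0.0, 1.0))
    return (
        OrderParameterSet("apo", apo, {r: noise for r in apo}),
        OrderParameterSet("bound", bound, {r: noise for r in bound}),
    )


# ---------------------------------------------------------------------------
# Kinetics, progress curves, melts


def gen_kinetics(
    kcat: float,
    km_um: float,
    s_grid_um=None,
    noise_fraction: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis-Menten velocity table with replicate noise.

    The default concentration grid spans ~K_M/8 to ~9 K_M so the
    half-saturation point is bracketed.
    """
    if kcat <= 0 or km_um <= 0:
        raise ValueError("kcat and K_M must be positive")
    if s_grid_um is None:
        s_grid_um = km_um * np.array([0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 9.0])
    s = np.asarray(s_grid_um, float)
    if not (s.min() < km_um < s.max()):
        raise ValueError("S grid must span below and above K_M")
    rng = np.random.default_rng(seed)
    v_clean = mm_velocity(s, kcat, km_um)
    sigma = noise_fraction * float(np.max(v_clean))
    rows = []
    for rep in range(replicates):
        v = v_clean + rng.normal(0.0, sigma, s.shape)
        for si, vi in zip(s, v):
            rows.append(dict(S_uM=si, v_per_s=vi, replicate=rep))
    return pd.DataFrame(rows)


def gen_progress(
    kcat: float,
    km_atp_um: float,
    km_amp_um: float,
    atp0_um: float = 1000.0,
    amp0_um: float = 300.0,
    adp0_um: float = 0.0,
    e_um: float = 1.0,
    t_end_s: float = 600.0,
    n_points: int = 60,
    noise_fraction: float = 0.0,
    keq: float = KEQ_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Reversible-kinase progress curve (default start: 1 mM ATP, 300 uM AMP,
    1 uM enzyme). Noise is added to the concentration columns; the
    underlying trajectory conserves adenine and phosphate exactly."""
    t = np.linspace(0.0, t_end_s, n_points)
    df = progress_model(t, kcat, e_um, atp0_um, amp0_um, adp0_um, km_atp_um, km_amp_um, keq)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_fraction * atp0_um
        for col in ("ATP_uM", "ADP_uM", "AMP_uM"):
            df[col] = df[col] + rng.normal(0.0, sigma, len(df))
    return df


def gen_melt(
    tm_c: float = 52.0,
    dh_kj: float = 300.0,
    baselines: tuple[float, float, float, float] = (-20.0, 0.02, -2.0, 0.01),
    noise_fraction: float = 0.0,
    t_min_c: float = 20.0,
    t_max_c: float = 80.0,
    n_points: int = 121,
    seed: int = 0,
) -> pd.DataFrame:
    """Sigmoidal CD melt (ellipticity at 220 nm vs temperature)."""
    t = np.linspace(t_min_c, t_max_c, n_points)
    y = melt_model(t, tm_c, dh_kj, *baselines)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_fraction * float(np.max(np.abs(y))), t.shape)
    return pd.DataFrame({"T_C": t, "signal": y})


def write_manifest(truth: GroundTruth, path) -> None:
    """Record the truth values of a generated dataset (YAML)."""
    data = {
        "tau_m_ns": truth.tau_m_ns,
        "field_mhz": truth.field_mhz,
        "closure_x": truth.closure_x,
        "kcat": truth.kcat,
        "km_um": truth.km_um,
        "tm_c": truth.tm_c,
        "dh_kj": truth.dh_kj,
        "seed": truth.seed,
        "s2": {int(k): float(v) for k, v in truth.s2.items()},
        "tau_e_ps": {int(k): float(v) for k, v in truth.tau_e_ps.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
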