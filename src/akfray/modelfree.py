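"""Lipari-Szabo model-free analysis of backbone 15N relaxation.

The generalized order parameter S2 describes the amplitude of ps-ns motion
of each amide N-H bond vector (1 = rigid, 0 = isotropic disorder); tau_e is
the effective internal correlation time and tau_m the overall rotational
correlation time. The spectral density is the familiar two-Lorentzian form

    J(w) = S2*tau_m/(1+w^2 tau_m^2) + (1-S2)*tau/(1+w^2 tau^2),
    1/tau = 1/tau_m + 1/tau_e,

returned here without the conventional 2/5 normalization, which is applied
inside the rate expressions. T1, T2 and the heteronuclear NOE follow from
J at {0, wN, wH-wN, wH, wH+wN} through the standard dipolar + CSA linear
combinations. Per-residue fitting minimizes the chi-square over the three
observables, choosing among three motional models (S2 only; S2+tau_e;
extended Sf2/Ss2 with a slow internal time) by Akaike's criterion, with
Monte-Carlo parameter errors from refits of noise-perturbed records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .constants import GAMMA_H, GAMMA_N, PhysicalConstants
from .relaxation import RelaxationRecord

__all__ = [
    "ModelFreeParams",
    "DiffusionModel",
    "ModelFreeResult",
    "spectral_density",
    "predict_rates",
    "chi2",
    "estimate_tau_m",
    "optimize_tau_m",
    "fit_residue",
    "local_tau_m",
    "axial_tau_eff",
]


@dataclass
class ModelFreeParams:
    """Motional parameters of one amide bond vector.

    model "M1": S2 only (tau_e = 0); "M2": S2 and tau_e; "M5": extended
    model with fast/slow order parameters, S2 = sf2 * ss2 and tau_e playing
    the role of the slow internal time tau_s.
    """

    s2: float
    tau_e_ps: float = 0.0
    tau_m_ns: float = 9.0
    model: str = "M2"
    sf2: float | None = None
    ss2: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.s2 <= 1.0):
            raise ValueError(f"S2 must lie in [0, 1], got {self.s2}")
        if self.tau_e_ps < 0:
            raise ValueError("tau_e must be >= 0")
        if self.tau_m_ns <= 0:
            raise ValueError("tau_m must be > 0")
        for name in ("sf2", "ss2"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sf2 is not None and self.ss2 is not None:
            if abs(self.s2 - self.sf2 * self.ss2) > 1e-9:
                raise ValueError("S2 must equal Sf2 * Ss2 for the extended model")


@dataclass
class DiffusionModel:
    """Overall rotational diffusion: isotropic or axially symmetric."""

    kind: str  # "isotropic" | "axial"
    tau_m_ns: float
    ratio: float = 1.0  # D_par / D_perp
    axis: np.ndarray | None = None  # unit vector, frame of supplied structure

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic", "axial"):
            raise ValueError("kind must be 'isotropic' or 'axial'")
        if self.tau_m_ns <= 0:
            raise ValueError("tau_m must be > 0")
        if self.ratio <= 0:
            raise ValueError("anisotropy ratio must be > 0")
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            n = np.linalg.norm(self.axis)
            if n == 0:
                raise ValueError("axis must be non-zero")
            self.axis = self.axis / n


def spectral_density(p: ModelFreeParams, omega) -> np.ndarray | float:
    """Two-Lorentzian spectral density J(omega) in s/rad (reduced form, no 2/5).

    For the extended model (M5), S2 = Sf2*Ss2 and tau_e holds the slow
    internal correlation time.
    """
    omega = np.asarray(omega, dtype=float)
    tm = p.tau_m_ns * 1e-9
    te = p.tau_e_ps * 1e-12
    s2 = p.s2
    j = s2 * tm / (1.0 + (omega * tm) ** 2)
    if te > 0.0 and s2 < 1.0:
        tau = 1.0 / (1.0 / tm + 1.0 / te)
        j = j + (1.0 - s2) * tau / (1.0 + (omega * tau) ** 2)
    return j if j.ndim else float(j)


def _rates(p: ModelFreeParams, c: PhysicalConstants) -> tuple[float, float, float]:
    """R1 (s^-1), R2 (s^-1), NOE (unitless) from the model-free forward model."""
    wh, wn = c.omega_h, c.omega_n
    if wh <= 0 or wn <= 0:
        raise ValueError("frequencies must be positive")
    freqs = np.array([0.0, wn, wh - wn, wh, wh + wn])
    # 2/5 normalization of the orientational correlation function applied here.
    j0, jn, jhmn, jh, jhpn = 0.4 * spectral_density(p, freqs)
    d2, c2 = c.d2, c.c2
    r1 = (d2 / 4.0) * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (d2 / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) + (
        c2 / 6.0
    ) * (4.0 * j0 + 3.0 * jn)
    noe = 1.0 + (GAMMA_H / GAMMA_N) * (d2 / 4.0) * (6.0 * jhpn - jhmn) / r1
    return r1, r2, noe


def predict_rates(p: ModelFreeParams, c: PhysicalConstants) -> tuple[float, float, float]:
    """Predict (T1 s, T2 s, NOE) for one residue at the given field."""
    r1, r2, noe = _rates(p, c)
    return 1.0 / r1, 1.0 / r2, noe


def chi2(p: ModelFreeParams, rec: RelaxationRecord, c: PhysicalConstants) -> float:
    """Weighted sum of squared residuals over (T1, T2, NOE)."""
    if rec.t1_err <= 0 or rec.t2_err <= 0 or rec.noe_err <= 0:
        raise ValueError("all uncertainties must be > 0 for chi2")
    t1c, t2c, noec = predict_rates(p, c)
    return (
        ((rec.t1 - t1c) / rec.t1_err) ** 2
        + ((rec.t2 - t2c) / rec.t2_err) ** 2
        + ((rec.noe - noec) / rec.noe_err) ** 2
    )


# ---------------------------------------------------------------------------
# Overall diffusion


def _t1t2_ratio_rigid(tau_m_ns: float, c: PhysicalConstants) -> float:
    p = ModelFreeParams(s2=1.0, tau_e_ps=0.0, tau_m_ns=tau_m_ns, model="M1")
    t1, t2, _ = predict_rates(p, c)
    return t1 / t2

def local_tau_m(rec: RelaxationRecord, c: PhysicalConstants) -> float:
    """Effective tau_m (ns) of one residue from its T1/T2 ratio (rigid model)."""
    target = rec.t1 / rec.t2
    f = lambda tm: _t1t2_ratio_rigid(tm, c) - target
    lo, hi = 0.3, 100.0
    if f(lo) > 0:
        return lo
    return brentq(f, lo, hi, xtol=1e-6)


def _rigid_mask(records: Sequence[RelaxationRecord], noe_cutoff: float = 0.65) -> np.ndarray:
    """Residues usable for tensor estimation: high NOE, T1/T2 within 1.5 IQR."""
    ratios = np.array([r.t1 / r.t2 for r in records])
    noes = np.array([r.noe for r in records])
    q1, q3 = np.percentile(ratios, [25, 75])
    iqr = q3 - q1
    # Tukey fences around the central T1/T2 cluster
    ok = (noes > noe_cutoff) & (ratios >= q1 - 1.5 * iqr) & (ratios <= q3 + 1.5 * iqr)
    return ok


def axial_tau_eff(tau_m_ns: float, ratio: float, alpha: float) -> float:
    """Effective correlation time (ns) of a bond vector at angle alpha (rad)
    from the unique axis of an axially symmetric diffusion tensor.

    Woessner three-exponential correlation function; tau_eff is its time
    integral. tau_m = 1/(6 Diso) with Diso = (2 Dperp + Dpar)/3.
    """
    diso = 1.0 / (6.0 * tau_m_ns)  # ns^-1
    dperp = 3.0 * diso / (2.0 + ratio)
    dpar = ratio * dperp
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    a1 = 0.25 * (3.0 * ca**2 - 1.0) ** 2
    a2 = 3.0 * ca**2 * sa**2
    a3 = 0.75 * sa**4
    t1 = 1.0 / (6.0 * dperp)
    t2 = 1.0 / (5.0 * dperp + dpar)
    t3 = 1.0 / (2.0 * dperp + 4.0 * dpar)
    return a1 * t1 + a2 * t2 + a3 * t3


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def estimate_tau_m(
    records: Sequence[RelaxationRecord],
    c: PhysicalConstants,
    nh_vectors: dict[int, np.ndarray] | None = None,
    trim_fraction: float = 0.1,
    min_rigid: int = 10,
) -> DiffusionModel:
    """Estimate the overall rotational diffusion model from T1/T2 ratios.

    Isotropic: trimmed mean of per-residue effective tau_m over rigid
    residues. Axially symmetric (requires per-residue N->H unit vectors in
    a common frame): least-squares fit of the Woessner effective tau_m
    versus the angle to a candidate unique axis, multistarted over axis
    seeds. The simpler model is kept unless the axial fit lowers the
    reduced residual.
    """
    records = list(records)
    mask = _rigid_mask(records)
    rigid = [r for r, m in zip(records, mask) if m]
    if len(rigid) < min_rigid:
        raise ValueError(
            f"need >= {min_rigid} rigid residues for tau_m estimation, got {len(rigid)}"
        )
    taus = np.array([local_tau_m(r, c) for r in rigid])
    order = np.sort(taus)
    k = int(np.floor(trim_fraction * len(order)))
    trimmed = order[k : len(order) - k] if len(order) > 2 * k else order
    tau_iso = float(np.mean(trimmed))
    iso = DiffusionModel(kind="isotropic", tau_m_ns=tau_iso)
    if nh_vectors is None:
        return iso

    ids = [r.residue for r in rigid]
    missing = [i for i in ids if i not in nh_vectors]
    if missing:
        raise ValueError(f"NH vectors missing for residues {missing[:5]}...")
    vecs = np.array([nh_vectors[i] / np.linalg.norm(nh_vectors[i]) for i in ids])

    def residuals(x):
        tm, ratio, theta, phi = x
        axis = _axis_from_angles(theta, phi)
        cosa = np.clip(vecs @ axis, -1.0, 1.0)
        alpha = np.arccos(np.abs(cosa))
        pred = np.array([axial_tau_eff(tm, ratio, a) for a in alpha])
        return pred - taus

    best = None
    for theta0 in (0.3, 1.0, 1.5):
        for phi0 in (0.5, 2.5):
            try:
                sol = least_squares(
                    residuals,
                    x0=[tau_iso, 1.2, theta0, phi0],
                    bounds=([0.5, 0.2, 0.0, -np.pi], [50.0, 5.0, np.pi, 2 * np.pi]),
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    iso_ss = float(np.sum((taus - tau_iso) ** 2))
    red_iso = iso_ss / max(len(taus) - 1, 1)
    if best is None:
        return iso
    red_ax = 2.0 * best.cost / max(len(taus) - 4, 1)
    if red_ax >= red_iso:
        return iso
    tm, ratio, theta, phi = best.x
    return DiffusionModel(
        kind="axial", tau_m_ns=float(tm), ratio=float(ratio), axis=_axis_from_angles(theta, phi)
    )


def optimize_tau_m(
    records: Sequence[RelaxationRecord],
    c: PhysicalConstants,
    tau0_ns: float,
    model: str = "M2",
    rel_window: float = 0.15,
) -> float:
    """Refine a global tau_m against the full relaxation data.

    The T1/T2-ratio estimate is slightly biased low whenever internal
    motion (tau_e > 0) contributes; this step re-optimizes tau_m by
    minimizing the summed per-residue chi2 (each residue refitted with the
    stated internal-motion model) over a window around the initial value.
    """
    from scipy.optimize import minimize_scalar

    def total_chi2(tau_m: float) -> float:
        tot = 0.0
        for rec in records:
            out = _fit_one_model(model, rec, tau_m, c)
            tot += out[1] if out is not None else 1e6
        return tot

    res = minimize_scalar(
        total_chi2,
        bounds=(tau0_ns * (1 - rel_window), tau0_ns * (1 + rel_window)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Per-residue fitting


@dataclass
class ModelFreeResult:
    residue: int
    params: ModelFreeParams | None
    chi2: float = np.inf
    s2_err: float = 0.0
    tau_e_err_ps: float = 0.0
    ok: bool = True
    reason: str = ""
    model: str = ""


_MODELS = ("M1", "M2", "M5")


def _fit_one_model(
    model: str, rec: RelaxationRecord, tau_m_ns: float, c: PhysicalConstants
) -> tuple[ModelFreeParams, float] | None:
    def make_params(x) -> ModelFreeParams:
        if model == "M1":
            return ModelFreeParams(s2=x[0], tau_e_ps=0.0, tau_m_ns=tau_m_ns, model="M1")
        if model == "M2":
            return ModelFreeParams(s2=x[0], tau_e_ps=x[1], tau_m_ns=tau_m_ns, model="M2")
        sf2, ss2, ts = x
        return ModelFreeParams(
            s2=sf2 * ss2, tau_e_ps=ts, tau_m_ns=tau_m_ns, model="M5", sf2=sf2, ss2=ss2
        )

    def resid(x):
        p = make_params(np.clip(x, lo, hi))
        t1c, t2c, noec = predict_rates(p, c)
        return np.array(
            [
                (rec.t1 - t1c) / rec.t1_err,
                (rec.t2 - t2c) / rec.t2_err,
                (rec.noe - noec) / rec.noe_err,
            ]
        )

    if model == "M1":
        lo, hi = np.array([0.0]), np.array([1.0])
        starts = [[0.85], [0.5]]
    elif model == "M2":
        lo, hi = np.array([0.0, 0.0]), np.array([1.0, 5000.0])
        starts = [[0.85, 50.0], [0.5, 500.0], [0.95, 10.0]]
    else:
        lo, hi = np.array([0.0, 0.0, 0.0]), np.array([1.0, 1.0, 10000.0])
        starts = [[0.9, 0.9, 1000.0], [0.8, 0.5, 3000.0]]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None
    p = make_params(np.clip(best.x, lo, hi))
    return p, float(2.0 * best.cost)


_N_PARAMS = {"M1": 1, "M2": 2, "M5": 3}


def fit_residue(
    rec: RelaxationRecord,
    diff: DiffusionModel,
    c: PhysicalConstants,
    n_mc: int = 500,
    nh_vector: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ModelFreeResult:
    """Fit internal-motion parameters of one residue at fixed overall diffusion.

    Model selection among M1/M2/M5 by AIC = chi2 + 2k. For an axial tensor
    with a known NH orientation, the residue-specific effective tau_m is used
    in the spectral density. Monte-Carlo errors from n_mc refits of records
    perturbed by their stated uncertainties.
    """
    tau_m = diff.tau_m_ns
    if diff.kind == "axial" and nh_vector is not None and diff.axis is not None:
        v = np.asarray(nh_vector, float)
        v = v / np.linalg.norm(v)
        alpha = float(np.arccos(np.clip(abs(v @ diff.axis), -1.0, 1.0)))
        tau_m = axial_tau_eff(diff.tau_m_ns, diff.ratio, alpha)

    fits = {}
    for model in _MODELS:
        out = _fit_one_model(model, rec, tau_m, c)
        if out is not None:
            fits[model] = out
    if not fits:
        return ModelFreeResult(
            residue=rec.residue, params=None, ok=False, reason="all models failed"
        )
    aic = {m: x2 + 2.0 * _N_PARAMS[m] for m, (_, x2) in fits.items()}
    model = min(aic, key=aic.get)
    params, x2 = fits[model]

    s2_err = tau_e_err = 0.0
    if n_mc > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        s2s, tes = [], []
        for _ in range(n_mc):
            pert = RelaxationRecord(
                residue=rec.residue,
                t1=max(rec.t1 + rng.normal(0.0, rec.t1_err), 1e-6),
                t1_err=rec.t1_err,
                t2=max(rec.t2 + rng.normal(0.0, rec.t2_err), 1e-6),
                t2_err=rec.t2_err,
                noe=rec.noe + rng.normal(0.0, rec.noe_err),
                noe_err=rec.noe_err,
                field_mhz=rec.field_mhz,
            )
            out = _fit_one_model(model, pert, tau_m, c)
            if out is None:
                continue
            s2s.append(out[0].s2)
            tes.append(out[0].tau_e_ps)
        if len(s2s) > 1:
            s2_err = float(np.std(s2s, ddof=1))
            tau_e_err = float(np.std(tes, ddof=1))

    return ModelFreeResult(
        residue=rec.residue,
        params=params,
        chi2=x2,
        s2_err=s2_err,
        tau_e_err_ps=tau_e_err,
        model=model,
    )
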