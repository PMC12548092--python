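"""Enzyme kinetics and thermal stability fitting.

Michaelis-Menten fits of normalized velocities V/[E]tot = kcat [S] /
(K_M + [S]) with errors from technical replicates; fold-change / specificity
ratio tables with first-order error propagation; kcat extraction from
31P-NMR progress curves of the adenylate-kinase reaction ATP + AMP <-> 2 ADP
by integrating a reversible two-substrate rate law; and two-state van't Hoff
fits of CD thermal melts with linear native/unfolded baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "MMFit",
    "MeltFit",
    "ProgressFit",
    "mm_velocity",
    "fit_mm",
    "specificity_ratios",
    "progress_model",
    "fit_progress",
    "melt_model",
    "fit_melt",
]

R_GAS_KJ = 8.31446261815324e-3  # kJ mol^-1 K^-1
KEQ_DEFAULT = 0.5  # [ADP]^2 / ([ATP][AMP]) at equilibrium, kinase direction


def mm_velocity(s, kcat: float, km: float):
    """Michaelis-Menten normalized velocity kcat*[S]/(K_M+[S]) (s^-1)."""
    s = np.asarray(s, dtype=float)
    return kcat * s / (km + s)


@dataclass
class MMFit:
    kcat: float
    kcat_err: float
    km: float
    km_err: float
    ok: bool = True
    reason: str = ""

    @property
    def specificity(self) -> float:
        """kcat/K_M in uM^-1 s^-1."""
        return self.kcat / self.km

    @property
    def specificity_err(self) -> float:
        if self.kcat <= 0 or self.km <= 0:
            return float("nan")
        rel = math.sqrt((self.kcat_err / self.kcat) ** 2 + (self.km_err / self.km) ** 2)
        return self.specificity * rel


def _fit_mm_single(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    kcat0 = float(np.max(v)) * 1.2
    half = kcat0 / 2.4
    km0 = float(s[np.argmin(np.abs(v - half))])
    km0 = km0 if km0 > 0 else float(np.median(s))
    popt, _ = curve_fit(mm_velocity, s, v, p0=[kcat0, km0], maxfev=10000)
    return float(popt[0]), float(popt[1])


def fit_mm(data: pd.DataFrame) -> MMFit:
    """Fit the Michaelis-Menten equation to a velocity table.

    data columns: S_uM, v_per_s, replicate. With more than one replicate
    the fit is done per technical replicate and kcat/K_M are reported as
    mean +- SD over replicates; with a single replicate the pooled fit and
    covariance errors are used. Concentrations must bracket K_M.
    """
    s_all = data["S_uM"].to_numpy(float)
    v_all = data["v_per_s"].to_numpy(float)
    if np.any(s_all < 0):
        raise ValueError("substrate concentrations must be >= 0")
    if len(np.unique(s_all)) < 5:
        raise ValueError("need >= 5 distinct substrate concentrations")
    reps = data["replicate"].unique() if "replicate" in data.columns else [0]
    try:
        if len(reps) > 1:
            fits = []
            for rep in reps:
                sub = data[data["replicate"] == rep]
                fits.append(
                    _fit_mm_single(sub["S_uM"].to_numpy(float), sub["v_per_s"].to_numpy(float))
                )
            kcats = np.array([f[0] for f in fits])
            kms = np.array([f[1] for f in fits])
            fit = MMFit(
                kcat=float(np.mean(kcats)),
                kcat_err=float(np.std(kcats, ddof=1)),
                km=float(np.mean(kms)),
                km_err=float(np.std(kms, ddof=1)),
            )
        else:
            popt, pcov = curve_fit(
                mm_velocity, s_all, v_all,
                p0=[float(np.max(v_all)) * 1.2, float(np.median(s_all))], maxfev=10000,
            )
            perr = np.sqrt(np.diag(pcov))
            fit = MMFit(float(popt[0]), float(perr[0]), float(popt[1]), float(perr[1]))
    except RuntimeError as exc:
        return MMFit(np.nan, np.nan, np.nan, np.nan, ok=False, reason=str(exc))
    if not (s_all.min() < fit.km < s_all.max()):
        return MMFit(fit.kcat, fit.kcat_err, fit.km, fit.km_err, ok=False,
                     reason="K_M not bracketed by the concentration grid")
    return fit


def specificity_ratios(fits: dict[str, MMFit], reference: str) -> pd.DataFrame:
    """Fold changes of kcat, K_M and specificity versus a reference variant.

    First-order (relative-error quadrature) propagation on each ratio.
    """
    if reference not in fits:
        raise ValueError(f"reference '{reference}' not among fits")
    ref = fits[reference]
    rows = []
    for name, f in fits.items():
        def fold(x, xe, y, ye):
            r = x / y
            rel = math.sqrt((xe / x) ** 2 + (ye / y) ** 2) if x > 0 and y > 0 else np.nan
            return r, r * rel
        kf, kfe = fold(f.kcat, f.kcat_err, ref.kcat, ref.kcat_err)
        mf, mfe = fold(f.km, f.km_err, ref.km, ref.km_err)
        sf, sfe = fold(f.specificity, f.specificity_err, ref.specificity, ref.specificity_err)
        rows.append(
            dict(
                variant=name,
                kcat_per_s=f.kcat, kcat_err=f.kcat_err,
                KM_uM=f.km, KM_err=f.km_err,
                specificity_uM_s=f.specificity, specificity_err=f.specificity_err,
                kcat_fold=kf, kcat_fold_err=kfe,
                KM_fold=mf, KM_fold_err=mfe,
                specificity_fold=sf, specificity_fold_err=sfe,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Progress curves (31P NMR assay)


def progress_model(
    t: np.ndarray,
    kcat: float,
    e_um: float,
    atp0: float,
    amp0: float,
    adp0: float,
    km_atp: float,
    km_amp: float,
    keq: float = KEQ_DEFAULT,
) -> pd.DataFrame:
    """Integrate the reversible two-substrate rate law ATP + AMP <-> 2 ADP.

        v = kcat [E] ([ATP][AMP] - [ADP]^2/Keq) / ((Km_ATP+[ATP])(Km_AMP+[AMP]))

    The state is reduced to a single reaction extent xi (ATP = ATP0 - xi,
    AMP = AMP0 - xi, ADP = ADP0 + 2 xi), so adenine count and total
    phosphate are conserved exactly by construction.
    """
    t = np.asarray(t, float)

    def rate(_t, y):
        xi = y[0]
        atp = atp0 - xi
        amp = amp0 - xi
        adp = adp0 + 2.0 * xi
        v = (
            kcat * e_um * (atp * amp - adp * adp / keq)
            / ((km_atp + atp) * (km_amp + amp))
        )
        return [v]

    sol = solve_ivp(
        rate, (0.0, float(t[-1])), [0.0], t_eval=t, rtol=1e-10, atol=1e-12,
        method="LSODA",
    )
    xi = sol.y[0]
    return pd.DataFrame(
        {
            "t_s": t,
            "ATP_uM": atp0 - xi,
            "AMP_uM": amp0 - xi,
            "ADP_uM": adp0 + 2.0 * xi,
        }
    )


@dataclass
class ProgressFit:
    kcat: float
    kcat_err: float
    ok: bool = True
    reason: str = ""
    metadata: dict = field(default_factory=dict)


def fit_progress(
    curve: pd.DataFrame,
    e_um: float,
    km_atp: float,
    km_amp: float,
    keq: float = KEQ_DEFAULT,
) -> ProgressFit:
    """Extract kcat from a progress curve (columns t_s, ATP_uM, ADP_uM, AMP_uM).

    K_M values and the equilibrium constant are fixed; kcat is the single
    free parameter of the integrated rate model, fitted to the ADP buildup.
    """
    t = curve["t_s"].to_numpy(float)
    adp = curve["ADP_uM"].to_numpy(float)
    atp0 = float(curve["ATP_uM"].iloc[0])
    amp0 = float(curve["AMP_uM"].iloc[0])
    adp0 = float(adp[0])

    early = adp[: max(3, len(adp) // 4)]
    noise = float(np.std(np.diff(adp))) if len(adp) > 3 else 0.0
    if len(early) > 2 and np.any(np.diff(early) < -3.0 * max(noise, 1e-9)):
        import warnings

        warnings.warn("non-monotone early ADP buildup beyond noise level")

    def resid(x):
        model = progress_model(t, x[0], e_um, atp0, amp0, adp0, km_atp, km_amp, keq)
        return model["ADP_uM"].to_numpy() - adp

    slope = (adp[min(2, len(adp) - 1)] - adp0) / max(t[min(2, len(t) - 1)] - t[0], 1e-9)
    v0 = (
        e_um * (atp0 * amp0 - adp0**2 / keq) / ((km_atp + atp0) * (km_amp + amp0))
    )
    k0 = max(slope / (2.0 * v0), 1.0) if v0 > 0 else 100.0
    sol = least_squares(resid, x0=[k0], bounds=([0.0], [np.inf]))
    kcat = float(sol.x[0])
    if kcat <= 0:
        return ProgressFit(kcat, np.nan, ok=False, reason="non-positive kcat")
    # 1-sigma from the Jacobian at the optimum
    jac = sol.jac
    dof = max(len(t) - 1, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        var = s2 * np.linalg.inv(jac.T @ jac)[0, 0]
        err = float(np.sqrt(var))
    except np.linalg.LinAlgError:
        err = float("nan")
    return ProgressFit(
        kcat, err,
        metadata={
            "model": "reversible bi-bi, separable Michaelis terms, fixed Keq",
            "keq": keq, "km_atp_uM": km_atp, "km_amp_uM": km_amp,
        },
    )


# ---------------------------------------------------------------------------
# Thermal melts (CD at 220 nm)


def melt_model(t_c, tm_c, dh_kj, bn0, bn1, bu0, bu1):
    """Two-state van't Hoff melt with linear baselines.

    K(T) = exp(-dH (1 - T/Tm) / (R T)), T absolute; signal =
    (native_baseline + unfolded_baseline * K) / (1 + K). At T = Tm, K = 1
    and the signal is the midpoint of the two baselines.
    """
    t_c = np.asarray(t_c, float)
    t_k = t_c + 273.15
    tm_k = tm_c + 273.15
    k = np.exp(-dh_kj * (1.0 - t_k / tm_k) / (R_GAS_KJ * t_k))
    bn = bn0 + bn1 * t_c
    bu = bu0 + bu1 * t_c
    return (bn + bu * k) / (1.0 + k)


@dataclass
class MeltFit:
    tm_c: float
    tm_err: float
    dh_kj: float
    dh_err: float
    baselines: tuple[float, float, float, float]
    ok: bool = True
    reason: str = ""


def fit_melt(curve: pd.DataFrame) -> MeltFit:
    """Fit a two-state thermal melt (columns T_C, signal)."""
    t = curve["T_C"].to_numpy(float)
    y = curve["signal"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    mid = 0.5 * (y[0] + y[-1])
    tm0 = float(t[np.argmin(np.abs(y - mid))])
    if not (t[2] < tm0 < t[-3]):
        return MeltFit(np.nan, np.nan, np.nan, np.nan, (np.nan,) * 4, ok=False,
                       reason="no transition inside the scanned range")
    p0 = [tm0, 300.0, y[0], 0.0, y[-1], 0.0]
    try:
        popt, pcov = curve_fit(melt_model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return MeltFit(np.nan, np.nan, np.nan, np.nan, (np.nan,) * 4, ok=False,
                       reason=str(exc))
    perr = np.sqrt(np.diag(pcov))
    if not (t[0] < popt[0] < t[-1]):
        return MeltFit(float(popt[0]), float(perr[0]), float(popt[1]), float(perr[1]),
                       tuple(float(v) for v in popt[2:]), ok=False,
                       reason="fitted Tm outside the scanned range")
    return MeltFit(
        tm_c=float(popt[0]), tm_err=float(perr[0]),
        dh_kj=float(popt[1]), dh_err=float(perr[1]),
        baselines=tuple(float(v) for v in popt[2:]),
    )
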