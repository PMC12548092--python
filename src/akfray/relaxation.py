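"""Fitting of 15N T1/T2 relaxation decays and heteronuclear NOE ratios.

Peak heights I(t) of each amide cross-peak, measured over a series of
relaxation delays, are fitted to a single exponential

    I(t) = I0 * exp(-t / Td),

with parameter uncertainties from Monte-Carlo refits of residual-bootstrap
synthetic datasets. The steady-state heteronuclear NOE is the ratio
I_sat/I_unsat of peak intensities with and without proton saturation, with
its error propagated from the RMS noise of empty spectral regions:

    sigma_NOE = |NOE| * sqrt((sigma_sat/I_sat)^2 + (sigma_unsat/I_unsat)^2).

Duplicated delays are kept as separate observations, which weights them
naturally in the least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecaySeries",
    "NoePair",
    "RelaxationRecord",
    "DecayFit",
    "fit_decay",
    "compute_noe",
    "build_relaxation_table",
]

# Printed delay schedules (s) for the T1 and T2 series; duplicated delays
# appear twice because they were measured twice.
T1_DELAYS_S = [0.05, 0.1, 0.1, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0, 1.0, 1.2, 1.5]
T2_DELAYS_S = [
    0.01696, 0.03392, 0.05088, 0.08480, 0.10176, 0.11872, 0.13568,
    0.15264, 0.16960, 0.16960, 0.18656, 0.20352, 0.25440, 0.28832,
]


@dataclass
class DecaySeries:
    """One residue's peak heights versus relaxation delay."""

    residue: int
    kind: str  # "T1" | "T2"
    delays_s: np.ndarray
    intensities: np.ndarray
    field_mhz: float = 850.0
    code: str = "X"  # one-letter residue code

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.kind not in ("T1", "T2"):
            raise ValueError("kind must be 'T1' or 'T2'")
        if self.delays_s.shape != self.intensities.shape:
            raise ValueError("delays and intensities must align")
        if np.any(self.delays_s < 0):
            raise ValueError("delays must be >= 0")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if len(np.unique(self.delays_s)) < 4:
            raise ValueError("need >= 4 distinct delays")


@dataclass
class NoePair:
    """Saturated/unsaturated peak intensities and spectral noise levels."""

    residue: int
    i_sat: float
    i_unsat: float
    sigma_sat: float
    sigma_unsat: float

    def __post_init__(self) -> None:
        if self.i_unsat == 0:
            raise ValueError("I_unsat must be non-zero")
        if self.sigma_sat < 0 or self.sigma_unsat < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class RelaxationRecord:
    """Per-residue T1, T2 and NOE with uncertainties at one field."""

    residue: int
    t1: float
    t1_err: float
    t2: float
    t2_err: float
    noe: float
    noe_err: float
    field_mhz: float = 850.0
    code: str = "X"

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"T1 and T2 must be > 0 (residue {self.residue})")
        if min(self.t1_err, self.t2_err, self.noe_err) < 0:
            raise ValueError("uncertainties must be >= 0")


@dataclass
class DecayFit:
    residue: int
    kind: str
    i0: float
    td: float
    i0_err: float
    td_err: float
    rmse: float
    ok: bool = True
    reason: str = ""


def _exp_model(t, i0, td):
    return i0 * np.exp(-t / td)


def fit_decay(
    series: DecaySeries, n_mc: int = 500, rng: np.random.Generator | None = None
) -> DecayFit:
    """Least-squares fit of I(t)=I0 exp(-t/Td) with Monte-Carlo errors.

    The MC uncertainty is the standard deviation of (I0, Td) over n_mc
    refits of synthetic series perturbed by Gaussian noise equal to the fit
    RMSE (residual bootstrap). With n_mc=0 the covariance-matrix errors of
    the least-squares fit are reported instead.
    """
    t = series.delays_s
    y = series.intensities
    i0_guess = float(np.max(np.abs(y)))
    # delay whose intensity is nearest I0/e: robust, derivative-free start
    target = i0_guess / math.e
    td_guess = float(t[np.argmin(np.abs(np.abs(y) - target))])
    if td_guess <= 0:
        td_guess = float(np.median(t[t > 0]))
    try:
        popt, pcov = curve_fit(
            _exp_model, t, y, p0=[i0_guess, td_guess], maxfev=10000
        )
    except RuntimeError as exc:
        return DecayFit(series.residue, series.kind, np.nan, np.nan, np.nan,
                        np.nan, np.nan, ok=False, reason=str(exc))
    i0, td = popt
    if td <= 0 or not np.isfinite(td):
        return DecayFit(series.residue, series.kind, i0, td, np.nan, np.nan,
                        np.nan, ok=False, reason="non-physical decay constant")
    resid = y - _exp_model(t, i0, td)
    rmse = float(np.sqrt(np.mean(resid**2)))

    if n_mc <= 0:
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [0.0, 0.0]
        return DecayFit(series.residue, series.kind, float(i0), float(td),
                        float(perr[0]), float(perr[1]), rmse)

    rng = rng if rng is not None else np.random.default_rng(0)
    ideal = _exp_model(t, i0, td)
    i0s, tds = [], []
    for _ in range(n_mc):
        y_mc = ideal + rng.normal(0.0, rmse if rmse > 0 else 1e-12, size=t.shape)
        try:
            p_mc, _ = curve_fit(_exp_model, t, y_mc, p0=[i0, td], maxfev=5000)
        except RuntimeError:
            continue
        if p_mc[1] > 0:
            i0s.append(p_mc[0])
            tds.append(p_mc[1])
    if len(tds) > 1:
        i0_err = float(np.std(i0s, ddof=1))
        td_err = float(np.std(tds, ddof=1))
    else:
        i0_err = td_err = 0.0
    return DecayFit(series.residue, series.kind, float(i0), float(td),
                    i0_err, td_err, rmse)


def compute_noe(pair: NoePair) -> tuple[float, float]:
    """NOE = I_sat/I_unsat with the propagated sigma_NOE."""
    if pair.i_sat == 0.0:
        return 0.0, abs(pair.sigma_sat / pair.i_unsat)
    noe = pair.i_sat / pair.i_unsat
    sigma = abs(noe) * math.sqrt(
        (pair.sigma_sat / pair.i_sat) ** 2 + (pair.sigma_unsat / pair.i_unsat) ** 2
    )
    return noe, sigma


def build_relaxation_table(
    t1_fits: Sequence[DecayFit],
    t2_fits: Sequence[DecayFit],
    noe_results: Sequence[tuple[int, float, float]],
    field_mhz: float = 850.0,
) -> tuple[list[RelaxationRecord], list[tuple[int, str]]]:
    """Join per-experiment results into complete per-residue records.

    noe_results entries are (residue, NOE, sigma_NOE). Returns the complete
    records plus an incomplete-report of (residue, what is missing).
    Residues whose decay fit failed count as missing that experiment.
    """

    def index(fits: Sequence[DecayFit], label: str) -> dict[int, DecayFit]:
        out: dict[int, DecayFit] = {}
        for f in fits:
            if f.residue in out:
                raise ValueError(f"duplicate residue {f.residue} in {label} fits")
            out[f.residue] = f
        return out

    t1_by = index(t1_fits, "T1")
    t2_by = index(t2_fits, "T2")
    noe_by: dict[int, tuple[float, float]] = {}
    for res, noe, err in noe_results:
        if res in noe_by:
            raise ValueError(f"duplicate residue {res} in NOE results")
        noe_by[res] = (noe, err)

    records: list[RelaxationRecord] = []
    incomplete: list[tuple[int, str]] = []
    for res in sorted(set(t1_by) | set(t2_by) | set(noe_by)):
        missing = []
        if res not in t1_by or not t1_by[res].ok:
            missing.append("T1")
        if res not in t2_by or not t2_by[res].ok:
            missing.append("T2")
        if res not in noe_by:
            missing.append("NOE")
        if missing:
            incomplete.append((res, "+".join(missing)))
            continue
        f1, f2 = t1_by[res], t2_by[res]
        noe, noe_err = noe_by[res]
        records.append(
            RelaxationRecord(
                residue=res, t1=f1.td, t1_err=f1.td_err, t2=f2.td,
                t2_err=f2.td_err, noe=noe, noe_err=noe_err, field_mhz=field_mhz,
            )
        )
    return records, incomplete
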