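"""Delimited-text readers/writers and run configuration.

All tables are CSV with mandatory named headers (units embedded in the
column names, e.g. T1_s, S_uM); no positional columns. Peak tables carry
one intensity column per relaxation delay, named d<ms>ms with a #k suffix
for duplicated delays. Every writer's output is readable by its reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .modelfree import ModelFreeResult
from .projection import ShiftRecord
from .relaxation import DecaySeries, NoePair, RelaxationRecord

__all__ = [
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "read_noe_table",
    "read_relaxation_table",
    "write_relaxation_table",
    "write_modelfree_table",
    "read_modelfree_table",
    "read_shift_table",
    "write_shift_table",
    "read_velocity_table",
    "read_progress_table",
    "read_melt_table",
    "write_run_manifest",
]


def require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


_DELAY_RE = re.compile(r"^d([0-9.]+)ms(?:#\d+)?$")


def read_peak_table(path, kind: str, field_mhz: float = 850.0) -> list[DecaySeries]:
    """Read a peak-height table (residue, assignment, d<ms>ms columns)."""
    df = pd.read_csv(path)
    require_columns(df, ["residue"], path)
    delays, delay_cols = [], []
    for col in df.columns:
        m = _DELAY_RE.match(col)
        if m:
            delays.append(float(m.group(1)) / 1000.0)
            delay_cols.append(col)
    if len(delays) < 4:
        raise ValueError(f"{path}: found {len(delays)} delay columns, need >= 4")
    series = []
    for _, row in df.iterrows():
        series.append(
            DecaySeries(
                residue=int(row["residue"]),
                kind=kind,
                delays_s=np.array(delays),
                intensities=row[delay_cols].to_numpy(float),
                field_mhz=field_mhz,
            )
        )
    return series


def write_peak_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_noe_table(path) -> list[NoePair]:
    df = pd.read_csv(path)
    require_columns(df, ["residue", "I_sat", "I_unsat", "sigma_sat", "sigma_unsat"], path)
    return [
        NoePair(int(r.residue), float(r.I_sat), float(r.I_unsat),
                float(r.sigma_sat), float(r.sigma_unsat))
        for r in df.itertuples()
    ]


RELAX_COLUMNS = ["residue", "T1_s", "T1_err", "T2_s", "T2_err", "NOE", "NOE_err", "field_MHz"]


def write_relaxation_table(records, path) -> None:
    rows = [
        [r.residue, r.t1, r.t1_err, r.t2, r.t2_err, r.noe, r.noe_err, r.field_mhz]
        for r in records
    ]
    pd.DataFrame(rows, columns=RELAX_COLUMNS).to_csv(path, index=False)


def read_relaxation_table(path) -> list[RelaxationRecord]:
    df = pd.read_csv(path)
    require_columns(df, RELAX_COLUMNS, path)
    return [
        RelaxationRecord(
            residue=int(r.residue), t1=r.T1_s, t1_err=r.T1_err, t2=r.T2_s,
            t2_err=r.T2_err, noe=r.NOE, noe_err=r.NOE_err, field_mhz=r.field_MHz,
        )
        for r in df.itertuples()
    ]


MF_COLUMNS = ["residue", "model", "S2", "S2_err", "Sf2", "Ss2", "tau_e_ps", "tau_e_err", "chi2"]


def write_modelfree_table(results, path) -> None:
    rows = []
    for r in results:
        if not r.ok or r.params is None:
            continue
        p = r.params
        rows.append(
            [r.residue, r.model, p.s2, r.s2_err,
             p.sf2 if p.sf2 is not None else "",
             p.ss2 if p.ss2 is not None else "",
             p.tau_e_ps, r.tau_e_err_ps, r.chi2]
        )
    pd.DataFrame(rows, columns=MF_COLUMNS).to_csv(path, index=False)


def read_modelfree_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ["residue", "S2"], path)
    return df


def read_shift_table(path, state: str) -> list[ShiftRecord]:
    df = pd.read_csv(path)
    require_columns(df, ["residue", "dH_ppm", "dN_ppm"], path)
    return [
        ShiftRecord(int(r.residue), float(r.dH_ppm), float(r.dN_ppm), state)
        for r in df.itertuples()
    ]


def write_shift_table(records, path) -> None:
    rows = [[r.residue, r.d_h_ppm, r.d_n_ppm] for r in records]
    pd.DataFrame(rows, columns=["residue", "dH_ppm", "dN_ppm"]).to_csv(path, index=False)


def read_velocity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ["S_uM", "v_per_s"], path)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


def read_progress_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ["t_s", "ATP_uM", "ADP_uM", "AMP_uM"], path)
    return df


def read_melt_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, ["T_C", "signal"], path)
    return df


@dataclass
class RunConfig:
    """Tunables of a pipeline run; round-trips losslessly through YAML."""

    inputs: dict = field(default_factory=dict)
    field_mhz: float = 850.0
    n_mc: int = 500
    trim_fraction: float = 0.1
    n15_weight: float = 0.2
    cos_cutoff: float = 0.9
    chain: str = ""
    ranges: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    verbosity: int = 1

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def write_run_manifest(path, command: str, config: dict, inputs: list, seed) -> None:
    """Record what a run did: command, config, inputs, seed, versions."""
    from importlib.metadata import version as pkg_version

    try:
        ver = pkg_version("akfray")
    except Exception:
        ver = "unknown"
    manifest = {
        "command": command,
        "config": config,
        "inputs": [str(p) for p in inputs],
        "seed": seed,
        "akfray_version": ver,
        "numpy_version": np.__version__,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def parse_selection(sel: str) -> tuple[str, tuple[int, int]]:
    """Parse a chain/range selection like 'A:59-75'."""
    m = re.match(r"^([A-Za-z0-9]+):(-?\d+)-(-?\d+)$", sel)
    if not m:
        raise ValueError(f"bad selection '{sel}', expected CHAIN:START-END")
    return m.group(1), (int(m.group(2)), int(m.group(3)))
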