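"""Readers and writers for the plain-text formats the tool exchanges.

Quantification tables are TSV/CSV with one row per protein: the first column
is the protein id, the remaining columns are named ``g<group>r<replicate>``
(case-insensitive, e.g. ``g1r1 .. g4r3``) and hold the per-gel summary
statistic for that protein.  z-value files are one float per line with an
optional single header line.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import MixtureFit, NullParams
from .teststats import EffectTests, QuantTable

__all__ = ["read_z_values", "read_quant_table", "write_effect_tests",
           "write_fdr_table", "fit_record", "write_json"]

_COL_RE = re.compile(r"^g(\d+)r(\d+)$", re.IGNORECASE)


def read_z_values(path) -> np.ndarray:
    """One float per line; a single non-numeric header line is tolerated."""
    lines = Path(path).read_text().splitlines()
    vals, bad = [], []
    for k, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        try:
            vals.append(float(s))
        except ValueError:
            bad.append(k)
    if bad and (len(bad) > 1 or bad[0] != 1):
        raise ValueError(f"{path}: non-numeric z value at line(s) "
                         f"{bad[:5]}{'...' if len(bad) > 5 else ''}")
    if not vals:
        raise ValueError(f"{path}: no z-values found")
    return np.asarray(vals, dtype=float)


def read_quant_table(path, already_log: bool = True) -> QuantTable:
    """Read a factorial quantification table (see module docstring).

    With ``already_log=False`` the values are log-transformed here and must
    be strictly positive.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus g<g>r<l> columns")
    id_col = df.columns[0]
    cells = {}
    for col in df.columns[1:]:
        m = _COL_RE.match(str(col).strip())
        if not m:
            raise ValueError(f"{path}: column {col!r} does not match the "
                             "g<group>r<replicate> convention")
        cells[(int(m.group(1)), int(m.group(2)))] = col
    groups = sorted({g for g, _ in cells})
    reps = sorted({l for _, l in cells})
    if groups != [1, 2, 3, 4]:
        raise ValueError(f"{path}: need exactly groups 1..4, found {groups}")
    missing = [(g, l) for g in groups for l in reps if (g, l) not in cells]
    if missing:
        raise ValueError(f"{path}: incomplete layout, missing cells {missing}")
    K = df.shape[0]
    values = np.empty((4, len(reps), K))
    for g in groups:
        for j, l in enumerate(reps):
            values[g - 1, j] = df[cells[(g, l)]].to_numpy(dtype=float)
    if not already_log:
        if np.any(values <= 0):
            raise ValueError(f"{path}: non-positive values cannot be "
                             "log-transformed")
        values = np.log(values)
    return QuantTable(values=values, protein_ids=df[id_col].to_numpy())


def write_effect_tests(tests: EffectTests, ids, path) -> None:
    """TSV of protein id, t, df, z for one effect."""
    df = pd.DataFrame({"id": np.asarray(ids), "t": tests.t,
                       "df": tests.df,
                       "z": tests.z if tests.z is not None else np.nan})
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_fdr_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def fit_record(fit: MixtureFit, null_params: NullParams | None = None,
               provenance: dict | None = None) -> dict:
    """JSON-serialisable record of a fit, including the raw (uncapped) p0."""
    if null_params is None and fit.beta is not None:
        null_params = fit.null_params()
    rec = {
        "method": fit.method,
        "df": fit.design.df,
        "deviance": fit.deviance,
        "iterations": fit.iterations,
        "converged": bool(fit.converged),
        "theta": [float(v) for v in fit.theta],
        "beta": [float(v) for v in fit.beta] if fit.beta is not None else None,
        "null_interval": list(fit.design.null_interval),
        "bins": fit.hist.nbins,
        "n": fit.hist.total,
    }
    if null_params is not None:
        rec.update({"delta": null_params.delta, "sigma": null_params.sigma,
                    "p0": null_params.p0, "p0_raw": null_params.p0_raw})
    if provenance is not None:
        rec["provenance"] = provenance
    return rec


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
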