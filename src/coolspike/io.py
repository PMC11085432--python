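"""CSV/JSON file I/O for observation tables, regimes and fit results.

All files are comma-separated UTF-8 with dot decimals.  Percentages are on
the 0-100 scale everywhere.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .model import SigmoidParams
from .thermal import TemperatureRegime

__all__ = [
    "read_observations",
    "write_observations",
    "read_regimes",
    "read_regime",
    "read_params_json",
    "write_params_json",
]

OBS_COLUMNS = ["group", "act_c_h", "pct_spiked", "n_plants"]


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation table.

    Expected header ``group,act_c_h,pct_spiked[,n_plants]``.  Errors cite
    the offending data row (1-based, excluding the header) and column.
    """
    frame = pd.read_csv(path)
    missing = {"group", "act_c_h", "pct_spiked"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    def _bad_row(mask, column, why):
        row = int(np.argmax(mask.to_numpy())) + 1
        raise ValueError(f"{path}: row {row}, column '{column}': {why}")

    act = pd.to_numeric(frame["act_c_h"], errors="coerce")
    if act.isna().any():
        _bad_row(act.isna(), "act_c_h", "non-numeric ACT value")
    if (act < 0).any():
        _bad_row(act < 0, "act_c_h", "ACT must be >= 0")
    pct = pd.to_numeric(frame["pct_spiked"], errors="coerce")
    if pct.isna().any():
        _bad_row(pct.isna(), "pct_spiked", "non-numeric percentage")
    bad = (pct < 0) | (pct > 100)
    if bad.any():
        _bad_row(bad, "pct_spiked", f"percentage {pct[bad].iloc[0]} outside [0, 100]")
    frame["act_c_h"] = act
    frame["pct_spiked"] = pct
    if "n_plants" in frame.columns:
        n = pd.to_numeric(frame["n_plants"], errors="coerce")
        if ((n < 1) & n.notna()).any():
            _bad_row((n < 1) & n.notna(), "n_plants", "cohort size must be >= 1")
        frame["n_plants"] = n
    return frame


def write_observations(frame: pd.DataFrame, path) -> None:
    """Write an observation table in the canonical column order."""
    cols = [c for c in OBS_COLUMNS if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame[cols].to_csv(path, index=False)


def read_regimes(path) -> dict[str, TemperatureRegime]:
    """Read a regime file: header ``name,T_vd,T_vn,T_cd,T_cn,H_d,H_n``."""
    frame = pd.read_csv(path)
    expected = ["name", "T_vd", "T_vn", "T_cd", "T_cn", "H_d", "H_n"]
    missing = set(expected) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing regime column(s) {sorted(missing)}")
    out = {}
    for _, row in frame.iterrows():
        out[str(row["name"])] = TemperatureRegime(
            t_vd=float(row["T_vd"]),
            t_vn=float(row["T_vn"]),
            t_cd=float(row["T_cd"]),
            t_cn=float(row["T_cn"]),
            h_d=float(row["H_d"]),
            h_n=float(row["H_n"]),
        )
    return out


def read_regime(spec: str) -> TemperatureRegime:
    """Resolve ``path`` or ``path:NAME`` to a single regime."""
    path, _, name = spec.partition(":")
    regimes = read_regimes(path)
    if name:
        if name not in regimes:
            raise KeyError(f"regime {name!r} not found in {path}; available: {sorted(regimes)}")
        return regimes[name]
    if len(regimes) != 1:
        raise ValueError(f"{path} holds {len(regimes)} regimes; select one with '{path}:NAME'")
    return next(iter(regimes.values()))


def read_params_json(path) -> SigmoidParams:
    """Read sigmoid parameters from a fit-result JSON (or a bare params dict)."""
    with open(path) as fh:
        payload = json.load(fh)
    block = payload.get("params", payload)
    return SigmoidParams(ymax=float(block["ymax"]), b=float(block["b"]), k=float(block["k"]))


def write_params_json(params: SigmoidParams, path) -> None:
    with open(path, "w") as fh:
        json.dump({"params": {"ymax": params.ymax, "b": params.b, "k": params.k}}, fh, indent=2)
        fh.write("\n")
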