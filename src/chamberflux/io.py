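"""Reading and writing chamber-closure tables, decisions and grid results.

Chamber flux data has no community-standard file format, so the package
reads plain delimited text (comma by default, tab accepted) with one row
per gas sample:

    closure,time_min,conc_ppb
    A1,0,325.2
    A1,12,338.9
    ...

Times may be given as ``time_min`` or ``time_s``; the unit is declared
by the column name.  Chamber metadata (volume, area, optional height
override, temperature, pressure, sd_gc, c0_ambient) comes from a YAML
config, either a sidecar file or an in-memory mapping.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd
import yaml

from .core import (
    ChamberSystem,
    ConcentrationSeries,
    InvalidInputError,
    ParseError,
)
from .schemes import FluxDecision
from .simframe import SimGridResult

__all__ = [
    "load_config",
    "system_from_config",
    "read_chamber_table",
    "write_series_table",
    "write_decisions",
    "write_grid_result",
    "read_decisions",
]

_SYSTEM_KEYS = (
    "volume",
    "area",
    "height",
    "temperature",
    "pressure",
    "sd_gc",
    "c0_ambient",
)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} must be a mapping")
    return cfg


def system_from_config(cfg: dict) -> ChamberSystem:
    """Build a :class:`ChamberSystem` from a config mapping.

    Accepts either a top-level ``system:`` block or the fields inline.
    """
    block = cfg.get("system", cfg)
    unknown = set(block) - set(_SYSTEM_KEYS)
    if "system" in cfg and unknown:
        raise ParseError(f"unknown system fields: {sorted(unknown)}")
    kwargs = {k: block[k] for k in _SYSTEM_KEYS if k in block}
    if "volume" not in kwargs or "area" not in kwargs:
        raise ParseError("system config needs at least volume and area")
    return ChamberSystem(**kwargs)


def _sniff_delimiter(path: Union[str, Path]) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def _read_table(path: Union[str, Path], delimiter: Optional[str]) -> pd.DataFrame:
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    try:
        # round_trip parsing keeps every float bit-identical through a
        # write/read cycle
        df = pd.read_csv(
            path, sep=delimiter, comment="#", float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"could not read {path}: {exc}") from exc
    return df


def read_chamber_table(
    path: Union[str, Path],
    system: ChamberSystem,
    delimiter: Optional[str] = None,
) -> List[ConcentrationSeries]:
    """Read a delimited closure table into validated concentration series.

    Required columns: ``closure``, a time column (``time_s`` or
    ``time_min``) and a concentration column (``conc_ppb`` or
    ``concentration_ppb``).  Times are converted to seconds; rows are
    grouped by closure in file order.  Malformed closures raise
    :class:`ParseError` naming the closure id.
    """
    df = _read_table(path, delimiter)
    cols = {c.lower(): c for c in df.columns}
    if "closure" not in cols:
        raise ParseError(f"{path}: missing required column 'closure'")
    if "time_s" in cols:
        tcol, tscale = cols["time_s"], 1.0
    elif "time_min" in cols:
        tcol, tscale = cols["time_min"], 60.0
    else:
        raise ParseError(f"{path}: missing time column ('time_s' or 'time_min')")
    ccol = cols.get("conc_ppb") or cols.get("concentration_ppb")
    if ccol is None:
        raise ParseError(
            f"{path}: missing concentration column ('conc_ppb' or 'concentration_ppb')"
        )

    bad = df[pd.to_numeric(df[tcol], errors="coerce").isna()
             | pd.to_numeric(df[ccol], errors="coerce").isna()]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header line and 1-based
        raise ParseError(f"{path}: non-numeric sample values at lines {lines}")

    series: List[ConcentrationSeries] = []
    for cid, grp in df.groupby(cols["closure"], sort=False):
        t = grp[tcol].to_numpy(dtype=float) * tscale
        c = grp[ccol].to_numpy(dtype=float)
        try:
            series.append(
                ConcentrationSeries(
                    times=t, concentrations=c, system=system, closure_id=str(cid)
                )
            )
        except InvalidInputError as exc:
            raise ParseError(f"{path}: closure {cid!r}: {exc}") from exc
    if not series:
        raise ParseError(f"{path}: no closures found")
    return series


def _write_frame(df: pd.DataFrame, path: Union[str, Path], header_note: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_note.strip().splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_series_table(
    series_list: Sequence[ConcentrationSeries],
    path: Union[str, Path],
    note: str = "",
) -> None:
    """Write closures back to the delimited on-disk format (time in seconds)."""
    if len(series_list) == 0:
        raise InvalidInputError("nothing to write")
    rows = []
    for k, s in enumerate(series_list):
        cid = s.closure_id if s.closure_id is not None else f"closure{k:05d}"
        for t, c in zip(s.times, s.concentrations):
            rows.append({"closure": cid, "time_s": t, "conc_ppb": c})
    _write_frame(pd.DataFrame(rows), path, note or "chamberflux closure table")


def decisions_to_frame(decisions: Sequence[FluxDecision]) -> pd.DataFrame:
    rows = []
    for k, d in enumerate(decisions):
        rows.append(
            {
                "closure": d.closure_id if d.closure_id is not None else f"closure{k:05d}",
                "scheme": d.scheme,
                "flux_nmol_s_m2": d.flux,
                "chosen": d.chosen,
                "reason": d.reason,
                "flux_linear_nmol_s_m2": (
                    d.linear_fit.flux if d.linear_fit is not None else math.nan
                ),
                "kappa_per_s": d.kappa if d.kappa is not None else math.nan,
                "kappa_max_per_s": (
                    d.kappa_max_value if d.kappa_max_value is not None else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def write_decisions(
    decisions: Sequence[FluxDecision], path: Union[str, Path], note: str = ""
) -> None:
    """Write per-closure flux decisions as a long-format delimited table."""
    if len(decisions) == 0:
        raise InvalidInputError("nothing to write")
    _write_frame(
        decisions_to_frame(decisions), path, note or "chamberflux flux decisions"
    )


def read_decisions(path: Union[str, Path]) -> pd.DataFrame:
    """Read a decisions table written by :func:`write_decisions`."""
    return _read_table(path, None)


def write_grid_result(
    result: SimGridResult, path: Union[str, Path], note: str = ""
) -> None:
    """Write a grid result as a long-format table (one row per scheme x cell)."""
    _write_frame(result.to_frame(), path, note or "chamberflux simulation grid")
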