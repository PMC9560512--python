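"""Table readers/writers, FCS input, run configuration and logging helpers.

CSV is the canonical interchange format.  The colony table is long-format
(plate_id, condition, day, row, col, strain, size_px, optional status /
replicate / zero_flag), with coordinates accepted either 0-based numeric or
as A1-style well labels.  Flow input is FCS 3.0/3.1 (list mode, float or
integer data) through a small built-in reader, or a CSV fallback carrying
the same channel names.  Run configs are flat YAML key-value files with
fail-fast validation of unknown keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import ZERO_FLAGS
from .plate import parse_well

__all__ = [
    "read_colony_table",
    "write_colony_table",
    "read_growth_curves",
    "read_flow_csv",
    "read_fcs",
    "RunConfig",
    "read_config",
]

COLONY_REQUIRED = ["plate_id", "condition", "day", "row", "col", "strain", "size_px"]

#: Default mapping from instrument channel names ($PnN) to package names.
DEFAULT_CHANNEL_MAP = {
    "FSC-A": "fsc_a",
    "SSC-A": "ssc_a",
    "FSC-H": "fsc_h",
    "Width": "width",
    "FL1-A": "yfp_a",
    "YFP-A": "yfp_a",
}


class TableFormatError(ValueError):
    """Malformed input table; message carries the offending row where known."""


def _coerce_coords(df: pd.DataFrame) -> pd.DataFrame:
    """Accept numeric 0-based row/col or a 'well' column with A1 labels."""
    if "well" in df.columns and not {"row", "col"} <= set(df.columns):
        coords = df["well"].map(parse_well)
        df = df.assign(row=[r for r, _ in coords], col=[c for _, c in coords])
    for colname in ("row", "col"):
        if df[colname].dtype == object:
            parsed = []
            for i, v in enumerate(df[colname]):
                try:
                    parsed.append(int(v))
                except (TypeError, ValueError):
                    raise TableFormatError(
                        f"row {i}: non-numeric coordinate {v!r} "
                        "(use 0-based integers or a 'well' column)"
                    ) from None
            df[colname] = parsed
    return df


def read_colony_table(path) -> pd.DataFrame:
    """Read and validate a long-format colony CSV.

    Rejects missing columns, duplicate (plate_id, condition, day, row, col)
    records and invalid zero flags, naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLONY_REQUIRED
               if c not in df.columns and not (c in ("row", "col") and "well" in df)]
    if missing:
        raise TableFormatError(f"missing required column(s): {missing}")
    df = _coerce_coords(df)
    df["day"] = df["day"].astype(int)
    df["size_px"] = df["size_px"].astype(float)
    if (df["size_px"] < 0).any():
        i = int(df.index[df["size_px"] < 0][0])
        raise TableFormatError(f"row {i}: negative colony size")
    if "status" not in df:
        df["status"] = "OK"
    if "zero_flag" not in df:
        df["zero_flag"] = None
    bad_flag = df["zero_flag"].notna() & ~df["zero_flag"].isin(ZERO_FLAGS)
    if bad_flag.any():
        i = int(df.index[bad_flag][0])
        raise TableFormatError(
            f"row {i}: zero_flag {df.loc[i, 'zero_flag']!r} not in {sorted(ZERO_FLAGS)}"
        )
    key = ["plate_id", "condition", "day", "row", "col"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise TableFormatError(f"duplicate colony record: {first}")
    return df


def write_colony_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_growth_curves(path, layout: str = "wide") -> dict:
    """Plate-reader OD input -> {well: GrowthCurve}.

    ``layout='wide'``: first column is time (hours), one column per well.
    ``layout='long'``: columns time, well, od.
    """
    from .liquid_growth import GrowthCurve

    df = pd.read_csv(path)
    curves: dict[str, GrowthCurve] = {}
    if layout == "wide":
        tcol = df.columns[0]
        for well in df.columns[1:]:
            curves[str(well)] = GrowthCurve(df[tcol].to_numpy(float),
                                            df[well].to_numpy(float))
    elif layout == "long":
        need = {"time", "well", "od"}
        if not need <= set(df.columns):
            raise TableFormatError(f"long growth CSV needs columns {sorted(need)}")
        for well, g in df.groupby("well"):
            g = g.sort_values("time")
            curves[str(well)] = GrowthCurve(g["time"].to_numpy(float),
                                            g["od"].to_numpy(float))
    else:
        raise ValueError("layout must be 'wide' or 'long'")
    return curves


def read_flow_csv(path, channel_map: "dict | None" = None) -> pd.DataFrame:
    """CSV fallback for flow events; maps instrument channel names if needed."""
    from .flow import FLOW_CHANNELS

    df = pd.read_csv(path)
    cmap = dict(DEFAULT_CHANNEL_MAP)
    if channel_map:
        cmap.update(channel_map)
    df = df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})
    missing = [c for c in FLOW_CHANNELS if c not in df.columns]
    if missing:
        raise TableFormatError(f"flow CSV missing channel(s): {missing}")
    return df[FLOW_CHANNELS].astype(float)


# ---------------------------------------------------------------------------
# Minimal FCS 3.0 / 3.1 list-mode reader (header offsets + TEXT keywords +
# uncompensated DATA segment, $DATATYPE F, D or I, list mode).
# ---------------------------------------------------------------------------

def _read_fcs_text(raw: bytes, start: int, end: int) -> dict[str, str]:
    seg = raw[start:end + 1]
    delim = seg[0:1]
    parts = seg[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    kv = {}
    for i in range(0, len(parts) - 1, 2):
        kv[parts[i].decode("latin-1").strip().upper()] = parts[i + 1].decode(
            "latin-1").strip()
    return kv


def read_fcs(path, channel_map: "dict | None" = None) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 list-mode file into an event DataFrame.

    Supports float ($DATATYPE F/D) and fixed-width integer ($DATATYPE I)
    data in either byte order.  Channels are renamed through the channel
    map; channels that stay unmapped keep their $PnN names.
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS3"):
        raise TableFormatError(f"unsupported FCS version {version!r}")
    text_start, text_end = int(raw[10:18]), int(raw[18:26])
    kv = _read_fcs_text(raw, text_start, text_end)
    data_start = int(kv.get("$BEGINDATA", raw[26:34] or 0) or int(raw[26:34]))
    data_end = int(kv.get("$ENDDATA", raw[34:42] or 0) or int(raw[34:42]))
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    if kv.get("$MODE", "L").upper() != "L":
        raise TableFormatError("only list-mode FCS data is supported")
    dtype_code = kv.get("$DATATYPE", "F").upper()
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    data = raw[data_start:data_end + 1]
    if dtype_code == "F":
        arr = np.frombuffer(data[: 4 * n_par * n_tot], dtype=f"{order}f4")
    elif dtype_code == "D":
        arr = np.frombuffer(data[: 8 * n_par * n_tot], dtype=f"{order}f8")
    elif dtype_code == "I":
        bits = {int(kv.get(f"$P{i}B", 16)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise TableFormatError("only uniform 16/32-bit integer FCS supported")
        width = int(kv.get("$P1B", 16)) // 8
        arr = np.frombuffer(data[: width * n_par * n_tot],
                            dtype=f"{order}u{width}")
    else:
        raise TableFormatError(f"unsupported $DATATYPE {dtype_code!r}")
    events = arr.astype(float).reshape(n_tot, n_par)
    df = pd.DataFrame(events, columns=names)
    cmap = dict(DEFAULT_CHANNEL_MAP)
    if channel_map:
        cmap.update(channel_map)
    return df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated flat key-value run configuration."""

    input: "str | None" = None
    calibration: str = "published-default"
    normalization: str = "rowcol-mean"
    log_base: str = "ln"
    exclude_corners: bool = True
    alpha: float = 0.05
    fdr_scope: str = "per-assay"
    seed: int = 0
    output_dir: str = "."
    extras: dict = field(default_factory=dict)

    KNOWN = {
        "input", "calibration", "normalization", "log_base", "exclude_corners",
        "alpha", "fdr_scope", "seed", "output_dir",
    }


def read_config(path) -> RunConfig:
    """Load a flat YAML config; unknown keys are rejected fail-fast."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise TableFormatError("config must be a flat key-value mapping")
    unknown = set(raw) - RunConfig.KNOWN
    if unknown:
        raise TableFormatError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if not 0 < cfg.alpha < 1:
        raise TableFormatError("alpha must lie in (0, 1)")
    if cfg.log_base not in ("ln", "log2"):
        raise TableFormatError("log_base must be 'ln' or 'log2'")
    return cfg
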