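"""Trace files, binned-FEC tables, JSON reports and TOML run configuration.

Trajectory dialect: UTF-8 tab-separated values with a header line,
columns ``time_s  trap_sep_nm  force_pN  extension_nm`` for pulling data
and ``time_s  extension_nm`` for clamp data ('.' decimal; gzip accepted).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clamp import ClampTrace
from .fec import BinnedFEC, ForceExtensionTrace

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_binned_fec",
    "write_binned_fec",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = "1"

_PULL_COLS = ["time_s", "trap_sep_nm", "force_pN", "extension_nm"]
_CLAMP_COLS = ["time_s", "extension_nm"]


@dataclass
class RunConfig:
    """Centralized pipeline defaults; TOML round-trips read→write→read identically."""

    kBT: float = 4.1
    aa_rise: float = 0.365
    bp_rise: float = 0.338
    boxcar_window_s: float = 0.1
    bin_width_pN: float = 0.2
    force_range_pN: tuple = (0.5, 20.0)
    stiffness_fit_range_pN: tuple = (1.0, 7.0)
    rip_threshold_nm: float = 3.0
    rip_max_dwell_s: float = 0.02
    refold_tol_nm: float = 2.0
    refold_range_pN: tuple = (2.0, 6.0)
    n_disordered: float = 123.0
    nanodisc_nm: float = 5.0
    chain_P_nm: float = 0.6
    dna_P_nm: float = 40.0
    dna_bp: float = 4520.0
    seed: int = 0

    def to_toml(self) -> str:
        lines = ["[gatingspring]"]
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                lines.append(f"{key} = [{', '.join(repr(float(v)) for v in value)}]")
            elif isinstance(value, str):
                lines.append(f"{key} = {value!r}")
            else:
                lines.append(f"{key} = {value!r}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_toml(), encoding="utf-8")

    @classmethod
    def read(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        table = data.get("gatingspring", data)
        kwargs = {}
        for key, default in asdict(cls()).items():
            if key in table:
                value = table[key]
                if isinstance(default, tuple):
                    value = tuple(value)
                kwargs[key] = value
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# traces


def read_trace(path, mean_force: float | None = None, label: str = "",
               phase: str = "pull"):
    """Read a trajectory TSV; returns a ForceExtensionTrace or ClampTrace.

    The dialect is chosen from the header: pull files carry force and
    extension columns, clamp files only time and extension (then
    ``mean_force`` must be given).  Malformed rows are rejected with their
    line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"time_s", "force_pN", "extension_nm"} <= cols:
        kind = "pull"
        required = [c for c in _PULL_COLS if c in cols]
    elif set(_CLAMP_COLS) <= cols:
        kind = "clamp"
        required = _CLAMP_COLS
    else:
        raise ValueError(
            f"{path}: header must contain columns {_PULL_COLS} (pull) or "
            f"{_CLAMP_COLS} (clamp); found {sorted(cols)}"
        )
    bad = df[required].isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {rows}")
    if kind == "pull":
        return ForceExtensionTrace(
            df["time_s"].to_numpy(),
            df["force_pN"].to_numpy(),
            df["extension_nm"].to_numpy(),
            trap_sep=df["trap_sep_nm"].to_numpy() if "trap_sep_nm" in cols else None,
            label=label or str(path),
            phase=phase,
        )
    if mean_force is None:
        raise ValueError(f"{path}: clamp trace requires mean_force")
    return ClampTrace(df["time_s"].to_numpy(), df["extension_nm"].to_numpy(),
                      mean_force=mean_force)


def write_trace(trace, path) -> None:
    """Write a trace in the canonical TSV dialect (gzip if path ends in .gz)."""
    if isinstance(trace, ForceExtensionTrace):
        data = {
            "time_s": trace.time,
            "trap_sep_nm": trace.trap_sep
            if trace.trap_sep is not None
            else np.full(len(trace), np.nan),
            "force_pN": trace.force,
            "extension_nm": trace.extension,
        }
        if trace.trap_sep is None:
            del data["trap_sep_nm"]
    elif isinstance(trace, ClampTrace):
        data = {"time_s": trace.time, "extension_nm": trace.extension}
    else:
        raise TypeError(f"cannot write {type(trace).__name__}")
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_binned_fec(path) -> BinnedFEC:
    df = pd.read_csv(path, sep="\t")
    widths = np.diff(df["force_pN"].to_numpy())
    return BinnedFEC(
        df["force_pN"].to_numpy(),
        df["mean_ext_nm"].to_numpy(),
        df["sd_nm"].to_numpy(),
        df["n"].to_numpy(),
        bin_width=float(np.median(widths)) if widths.size else np.nan,
    )


def write_binned_fec(fec: BinnedFEC, path) -> None:
    pd.DataFrame(
        {
            "force_pN": fec.force_center,
            "mean_ext_nm": fec.mean_ext,
            "sd_nm": fec.sd,
            "n": fec.n,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_report(results, path, config: RunConfig | None = None, inputs=None,
                 seed: int | None = None) -> None:
    """Write an analysis report as structured JSON with provenance."""
    report = {
        "schema_version": SCHEMA_VERSION,
        "config": None if config is None else _jsonable(asdict(config)),
        "seed": seed,
        "inputs": {str(p): _checksum(p) for p in (inputs or [])},
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_report(path) -> dict:
    report = json.loads(Path(path).read_text(encoding="utf-8"))
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {report.get('schema_version')!r} != "
            f"{SCHEMA_VERSION!r}"
        )
    return report
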