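"""File formats, configuration, seeding and run manifests.

CSV dialect: UTF-8, comma separator, '.' decimal, LF line endings, shortest
round-trip float representation.  Every writer has a matching reader and
round trips preserve values exactly; re-runs with the same seed are
byte-identical.
"""
from __future__ import annotations

import csv
import hashlib
import json
import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, ParameterError
from .trace import BilateralTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_correlation_csv",
    "write_correlation_csv",
    "load_config",
    "derive_seed",
    "write_manifest",
]

#: Maximum tolerated time-grid jitter (s) when inferring the rate from a file.
CSV_GRID_TOL_S = 1e-6

_TRACE_HEADER = ["time_s", "left", "right"]


def write_trace_csv(trace: BilateralTrace, path, params=None) -> None:
    """Write a trace as ``time_s,left,right`` CSV (full float precision).

    If ``params`` is given (e.g. a CPGParams), a sidecar JSON
    ``<path>.params.json`` records it together with the trace's seed and
    condition.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_TRACE_HEADER) + "\n")
        for t, l, r in zip(trace.t, trace.left, trace.right):
            fh.write(f"{float(t)!r},{float(l)!r},{float(r)!r}\n")
    if params is not None:
        meta = dataclasses.asdict(params) if dataclasses.is_dataclass(params) \
            else dict(params)
        meta["condition"] = trace.condition
        meta["trace_seed"] = trace.seed
        sidecar = path.with_suffix(path.suffix + ".params.json")
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_trace_csv(path) -> BilateralTrace:
    """Read a ``time_s,left,right`` CSV back into a validated trace.

    The sampling rate is inferred from the median time step; rows deviating
    from that grid by more than 1e-6 s are rejected with their row number, as
    are missing columns and non-numeric cells.
    """
    path = Path(path)
    rows = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _TRACE_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(_TRACE_HEADER)!r}, "
                f"got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                rows.append(tuple(float(v) for v in row))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell in {row!r}") from None
    if len(rows) < 2:
        raise FormatError(f"{path}: need at least 2 data rows, got {len(rows)}")
    data = np.asarray(rows, dtype=float)
    t = data[:, 0]
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.nonzero(dt <= 0)[0][0]) + 3   # header + 1-based + next row
        raise FormatError(f"{path}:{bad}: time not strictly increasing")
    step = float(np.median(dt))
    dev = np.abs(dt - step)
    if np.any(dev > CSV_GRID_TOL_S):
        bad = int(np.argmax(dev)) + 3
        raise FormatError(
            f"{path}:{bad}: non-uniform sampling (dt deviates "
            f"{dev.max():.3g} s from the median step {step:.6g} s)"
        )
    rate_hz = 1.0 / step
    # snap to an exact uniform grid so trace validation (1e-9 s) passes
    t_uniform = t[0] + np.arange(len(t)) / rate_hz
    try:
        return BilateralTrace(t=t_uniform, left=data[:, 1], right=data[:, 2],
                              rate_hz=rate_hz)
    except ParameterError as err:
        raise FormatError(f"{path}: {err}") from None


def write_correlation_csv(corr, path) -> None:
    """Write a CorrelationFunction as two-column ``lag_s,value`` CSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("lag_s,value\n")
        for lag, v in zip(corr.lags, corr.values):
            fh.write(f"{float(lag)!r},{float(v)!r}\n")


def read_correlation_csv(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns lag_s,value")
    return data[:, 0], data[:, 1]


# ---------------------------------------------------------------------------
# config, seeding, manifest
# ---------------------------------------------------------------------------
def load_config(path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return out


def derive_seed(global_seed: int, component: str, index: int = 0) -> int:
    """Stable per-component seed below 2**31.

    One global seed feeds every random stage; each (component, index) pair
    maps to a distinct, platform-independent child seed via SHA-256.
    """
    digest = hashlib.sha256(
        f"{int(global_seed)}:{component}:{int(index)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int, artifacts) -> Path:
    """Write ``manifest.json``: config echo, seed, artifact checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config": config,
        "artifacts": {
            str(Path(p).name): _sha256(Path(p)) for p in artifacts
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
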