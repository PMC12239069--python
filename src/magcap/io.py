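"""File I/O: atomic writes, headered CSV tables, field samples, fit JSON.

Every table the package writes carries ``#``-prefixed header lines recording
provenance (coordinate convention, seed, config hash) and is re-readable by
the package's own readers, which skip comment lines. All writes go through a
write-temp-then-rename step so a failed run never leaves partial output.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .field import FieldSample

__all__ = [
    "atomic_write_text",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "read_field_samples",
    "write_field_samples",
]

CONVENTION_NOTE = "x=0 at magnet face, increasing away; speeds are positive approach speed"


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | os.PathLike, header: Mapping | None = None) -> None:
    """Write a DataFrame as CSV with ``#`` provenance header lines, atomically."""
    lines = [f"# {CONVENTION_NOTE}"]
    for k, v in (header or {}).items():
        lines.append(f"# {k}={v}")
    text = "\n".join(lines) + "\n" + df.to_csv(index=False)
    atomic_write_text(path, text)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_json(obj, path: str | os.PathLike, header: Mapping | None = None) -> None:
    """Write a JSON document atomically; provenance goes under ``_meta``."""
    doc = dict(obj)
    if header:
        doc["_meta"] = {**dict(header), "convention": CONVENTION_NOTE}
    atomic_write_text(path, json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_json(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_field_samples(path: str | os.PathLike) -> list[FieldSample]:
    """Read field samples from a CSV with columns ``position_m, flux_T``."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = {"position_m", "flux_T"} - set(df.columns)
    if missing:
        raise ValueError(f"field sample CSV is missing columns: {sorted(missing)}")
    return [FieldSample(float(p), float(b)) for p, b in zip(df["position_m"], df["flux_T"])]


def write_field_samples(samples: Iterable[FieldSample], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {"position_m": [s.position for s in samples], "flux_T": [s.flux_density for s in samples]}
    )
    write_table(df, path)
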