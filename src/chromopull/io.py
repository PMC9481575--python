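"""Trace container and the tab-separated trace-file dialect.

A trace is one tether's magnetic-tweezers time series: time (s), force
(pN), extension (nm) and, when bead tracking is available, lateral bead
position X/Y (µm).  Files carry a small ``# key: value`` header with the
template metadata (template length in bp, nucleosome repeat length, HO:DNA
ratio, trace id) followed by tab-separated numeric columns.  Values round
trip losslessly (floats are written with shortest-exact ``repr``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

_MAGIC = "# chromopull-trace v1"
_COLUMNS_XY = ("time_s", "force_pN", "extension_nm", "x_um", "y_um")
_COLUMNS_NOXY = ("time_s", "force_pN", "extension_nm")


class TraceParseError(ValueError):
    """Malformed trace file; the message names the offending line."""


@dataclass
class Trace:
    """One tether's force-extension time series plus template metadata.

    ``x_um``/``y_um`` are ``None`` when bead XY tracking is absent (the
    rupture unsticking filter then passes events through flagged).
    ``metadata`` holds template length (bp), NRL (bp), HO:DNA ratio, a
    trace id, and — for synthetic traces — the embedded ground-truth
    record under ``"truth"``.
    """

    time_s: np.ndarray
    force_pN: np.ndarray
    extension_nm: np.ndarray
    x_um: Optional[np.ndarray] = None
    y_um: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        n = self.time_s.size
        if self.force_pN.size != n or self.extension_nm.size != n:
            raise ValueError("time, force and extension must have equal length")
        if (self.x_um is None) != (self.y_um is None):
            raise ValueError("x_um and y_um must be supplied together")
        if self.x_um is not None:
            self.x_um = np.asarray(self.x_um, dtype=float)
            self.y_um = np.asarray(self.y_um, dtype=float)
            if self.x_um.size != n or self.y_um.size != n:
                raise ValueError("XY channels must match the time base")
        if n > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    @property
    def has_xy(self) -> bool:
        return self.x_um is not None

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)


_HEADER_KEYS = ("trace_id", "template_bp", "nrl_bp", "ho_dna_ratio", "manifest")


def write_trace(trace: Trace, path) -> None:
    """Write a trace in the TSV dialect (header block, then columns)."""
    path = Path(path)
    lines = [_MAGIC]
    meta = trace.metadata
    for key in _HEADER_KEYS:
        if key in meta and meta[key] is not None:
            lines.append(f"# {key}: {meta[key]!r}" if isinstance(meta[key], str)
                         else f"# {key}: {meta[key]}")
    cols = _COLUMNS_XY if trace.has_xy else _COLUMNS_NOXY
    lines.append("\t".join(cols))
    channels = [trace.time_s, trace.force_pN, trace.extension_nm]
    if trace.has_xy:
        channels += [trace.x_um, trace.y_um]
    for row in zip(*channels):
        lines.append("\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_header_value(key: str, raw: str):
    raw = raw.strip()
    if key in ("template_bp", "nrl_bp"):
        return int(raw)
    if key == "ho_dna_ratio":
        return float(raw)
    return raw.strip("'\"")


def read_trace(path) -> Trace:
    """Parse a trace file written by :func:`write_trace`.

    Raises
    ------
    TraceParseError
        Naming the line on any malformed header or data row.
    """
    path = Path(path)
    meta: dict = {}
    data_lines = []
    columns = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if lineno == 1:
                    if line != _MAGIC:
                        raise TraceParseError(
                            f"{path}:1: not a chromopull trace file"
                        )
                    continue
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise TraceParseError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, raw = body.split(":", 1)
                key = key.strip()
                try:
                    meta[key] = _parse_header_value(key, raw)
                except ValueError as exc:
                    raise TraceParseError(
                        f"{path}:{lineno}: bad value for {key!r}: {exc}"
                    ) from exc
            elif columns is None:
                columns = tuple(line.split("\t"))
                if columns not in (_COLUMNS_XY, _COLUMNS_NOXY):
                    raise TraceParseError(
                        f"{path}:{lineno}: unexpected column header {columns}"
                    )
            else:
                data_lines.append((lineno, line))
    if columns is None:
        raise TraceParseError(f"{path}: no column header found")
    rows = []
    for lineno, line in data_lines:
        parts = line.split("\t")
        if len(parts) != len(columns):
            raise TraceParseError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise TraceParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
    data = np.asarray(rows, dtype=float)
    if data.size == 0:
        raise TraceParseError(f"{path}: no data rows")
    kwargs = dict(
        time_s=data[:, 0], force_pN=data[:, 1], extension_nm=data[:, 2],
        metadata=meta,
    )
    if columns == _COLUMNS_XY:
        kwargs.update(x_um=data[:, 3], y_um=data[:, 4])
    try:
        return Trace(**kwargs)
    except ValueError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def write_manifest(manifest: list, path) -> None:
    """Write the per-trace ground-truth manifest as JSON."""
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True),
                          encoding="utf-8")


def read_manifest(path) -> list:
    return json.loads(Path(path).read_text(encoding="utf-8"))
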