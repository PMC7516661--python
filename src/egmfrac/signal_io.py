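"""Reading and writing electrogram signals and analysis results.

Signal format: plain delimited text, one sample per line, preceded by a
comment header carrying the sampling frequency and optional AF-type label::

    # fs=1000 label=II
    0.0123
    -0.4521
    ...

Results are serialized as JSON with sorted keys (deterministic byte output)
and carry the full configuration used, so any results file documents its
own provenance.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Any, Optional

import numpy as np

from .errors import FormatError, ParameterError
from .synthgen import AF_TYPES, EGMRecord

__all__ = ["read_egm", "write_egm", "write_results", "read_results"]


def write_egm(record: EGMRecord, path: str) -> dict:
    """Write a record as header + one full-precision float per line.

    Returns a small descriptor of the written file.  A JSON metadata
    sidecar ``<path>.meta.json`` is written when the record carries
    non-empty ``meta`` (e.g. Type IV ground-truth segment tags).
    """
    if not np.all(np.isfinite(record.samples)):
        raise ParameterError("refusing to write non-finite samples")
    header = f"# fs={record.fs:g}"
    if record.label is not None:
        header += f" label={record.label}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for v in record.samples:
            fh.write(repr(float(v)) + "\n")
    if record.meta:
        with open(path + ".meta.json", "w") as fh:
            json.dump(_jsonable(record.meta), fh, sort_keys=True, indent=1)
    return {
        "path": path,
        "format": "delimited-text",
        "fs": record.fs,
        "n_samples": len(record.samples),
    }


def read_egm(path: str) -> EGMRecord:
    """Read a delimited-text electrogram written by :func:`write_egm`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].lstrip().startswith("#"):
        raise FormatError(f"{path}: missing '# fs=...' header line")
    fields = dict(
        tok.split("=", 1) for tok in lines[0].lstrip("# ").split() if "=" in tok
    )
    if "fs" not in fields:
        raise FormatError(f"{path}: header does not specify fs")
    try:
        fs = float(fields["fs"])
    except ValueError:
        raise FormatError(f"{path}: non-numeric fs {fields['fs']!r}") from None
    label = fields.get("label")
    if label is not None and label not in AF_TYPES:
        raise FormatError(f"{path}: unknown label {label!r}")

    samples = []
    for ln, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            samples.append(float(line))
        except ValueError:
            raise FormatError(f"{path}:{ln}: non-numeric sample {line!r}") from None
    if not samples:
        raise FormatError(f"{path}: empty sample body")

    meta: dict = {}
    sidecar = path + ".meta.json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
    return EGMRecord(np.asarray(samples), fs=fs, label=label, source="file", meta=meta)


def write_results(results: Any, path: str) -> str:
    """Serialize an analysis results bundle to deterministic JSON."""
    try:
        payload = json.dumps(_jsonable(results), sort_keys=True, indent=1)
    except (TypeError, ValueError) as exc:
        raise OSError(f"cannot serialize results: {exc}") from exc
    with open(path, "w") as fh:
        fh.write(payload + "\n")
    return path


def read_results(path: str) -> Any:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy scalars and arrays to plain
    JSON-compatible Python objects."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
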