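"""Delimited-text input/output for trial matrices and result tables.

Trial matrices are plain whitespace-delimited text, one row per trial, with a
single header line ``# fs=<Hz> t0=<s>``.  Result tables are CSV with a comment
line recording the package version, a hash of the run configuration and the
master seed, so any output file identifies the run that produced it;
timestamps are deliberately omitted so identical runs produce identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .spectral import TrialWindowSet

__all__ = [
    "read_trial_matrix",
    "write_trial_matrix",
    "read_accuracy",
    "write_accuracy",
    "config_hash",
    "write_results",
    "read_results",
]


def write_trial_matrix(w: TrialWindowSet, path: str | Path) -> None:
    """Write a trial matrix with its ``# fs=<Hz> t0=<s>`` header."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# fs={w.fs!r} t0={w.t0!r}\n")
        np.savetxt(fh, w.data, fmt="%.17g")


def read_trial_matrix(path: str | Path) -> TrialWindowSet:
    """Read a trial matrix written by :func:`write_trial_matrix`.

    Accepts Unix and Windows line endings.  Raises with the file name and
    line number on a missing header, ragged rows or non-numeric cells.
    """
    path = Path(path)
    with path.open("r", newline=None) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}, line 1: missing '# fs=<Hz> t0=<s>' header")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("#").split() if "=" in item
        )
        if "fs" not in fields:
            raise ValueError(f"{path}, line 1: header does not define fs")
        fs = float(fields["fs"])
        t0 = float(fields.get("t0", 0.0))
        rows: list[list[float]] = []
        width: int | None = None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-numeric cell") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}, line {lineno}: ragged row ({len(row)} vs {width} columns)"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return TrialWindowSet(data=np.array(rows), fs=fs, t0=t0)


def write_accuracy(accuracy: np.ndarray, path: str | Path) -> None:
    """Write a one-column 0/1 accuracy file."""
    np.savetxt(Path(path), np.asarray(accuracy, dtype=int), fmt="%d")


def read_accuracy(path: str | Path) -> np.ndarray:
    a = np.loadtxt(Path(path), dtype=int, ndmin=1)
    if a.ndim != 1:
        raise ValueError(f"{path}: accuracy file must have one column")
    return a


def config_hash(config: dict) -> str:
    """Deterministic short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a tidy CSV with a provenance comment line (no timestamps)."""
    path = Path(path)
    buf = _io.StringIO()
    table.to_csv(buf, index=False)
    with path.open("w", newline="\n") as fh:
        fh.write(
            f"# mifreq={__version__} config_hash={config_hash(config or {})} seed={seed}\n"
        )
        fh.write(buf.getvalue())


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results`."""
    return pd.read_csv(Path(path), comment="#")
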