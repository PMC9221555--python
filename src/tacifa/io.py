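"""Data ingestion, run manifests and result export.

CSV conventions: one file per series, comma separated, header row of
feature names, rows = time points, with an optional leading time column.
Internally series are stored features-as-rows (p x T) with the time grid
rescaled to [0, 1].
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PairedSeries

__all__ = ["load_paired_csv", "write_paired_csv", "RunManifest"]


def _read_table(path: str | Path, time_column: str | None):
    df = pd.read_csv(path)
    t = None
    if time_column is not None:
        if time_column not in df.columns:
            raise ValueError(f"{path}: no column named {time_column!r}")
        t = df.pop(time_column).to_numpy(dtype=float)
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric columns {bad}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cells are not supported")
    return df.to_numpy(dtype=float).T, t, list(df.columns)  # p x T


def rescale_time(t: np.ndarray) -> np.ndarray:
    """Affinely map a time grid onto [0, 1]."""
    t = np.asarray(t, dtype=float)
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("time column must be strictly increasing")
    return (t - t[0]) / span


def load_paired_csv(path_x: str | Path, path_y: str | Path,
                    time_column: str | None = None) -> PairedSeries:
    """Load two CSV feature tables into a :class:`PairedSeries`.

    Both files must have the same number of rows (time points) and
    feature columns.  Without a time column a uniform grid on [0, 1] is
    assumed; with one, the grid is rescaled to [0, 1].
    """
    X, tx, _ = _read_table(path_x, time_column)
    Y, ty, _ = _read_table(path_y, time_column)
    if X.shape != Y.shape:
        raise ValueError(
            f"shape mismatch: {path_x} has (features, times) {X.shape} "
            f"but {path_y} has {Y.shape}"
        )
    if tx is not None and ty is not None and not np.allclose(tx, ty):
        raise ValueError("the two files carry different time grids")
    t = rescale_time(tx) if tx is not None else np.linspace(0.0, 1.0, X.shape[1])
    return PairedSeries(X, Y, t)


def write_paired_csv(data: PairedSeries, path_x: str | Path, path_y: str | Path,
                     time_column: str = "time") -> None:
    """Write a PairedSeries back to two CSV files (lossless round trip)."""
    names = [f"f{i}" for i in range(data.p)]
    for mat, path in ((data.X, path_x), (data.Y, path_y)):
        df = pd.DataFrame(mat.T, columns=names)
        df.insert(0, time_column, data.t)
        df.to_csv(path, index=False, float_format="%.17g")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record attached to every set of outputs."""

    config: dict
    seed: int
    version: str
    input_digests: dict[str, str]
    started: float = 0.0
    elapsed_s: float = 0.0

    @staticmethod
    def from_config(config, input_paths: dict[str, str | Path] | None = None) -> "RunManifest":
        from . import __version__

        digests = {k: file_digest(v) for k, v in (input_paths or {}).items()}
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
        return RunManifest(config=cfg, seed=cfg.get("seed", 0), version=__version__,
                           input_digests=digests, started=time.time())

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps([self.config, self.seed, self.input_digests], sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["manifest_hash"] = self.hash
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    @staticmethod
    def from_json(path: str | Path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        payload.pop("manifest_hash", None)
        return RunManifest(**payload)
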