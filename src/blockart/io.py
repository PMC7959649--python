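"""File formats and run configuration.

The canonical artifacts are plain text: MatrixMarket (coordinate, real,
general) for the sparse system matrix, two-column CSV (index, value) for
density and projection vectors, ASCII PGM for quick visual inspection of a
reconstruction, and a flat ``key = value`` file for run configurations.
Reconstruction vectors are the primary output; images are derived views.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ParseError
from .geometry import PixelGrid, SystemMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_vector",
    "read_vector",
    "write_history",
    "render_pgm",
    "render_png",
    "RunConfig",
]


def write_matrix(matrix: SystemMatrix, path) -> None:
    """Write as MatrixMarket coordinate/real/general with 17 significant digits."""
    csr = matrix.csr if isinstance(matrix, SystemMatrix) else sp.csr_matrix(matrix)
    scipy.io.mmwrite(str(path), csr, field="real", symmetry="general", precision=17)


def read_matrix(path) -> SystemMatrix:
    """Read a MatrixMarket file back into a :class:`SystemMatrix`."""
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:  # the backend reports its own line context
        raise ParseError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
    csr = sp.csr_matrix(mat)
    if csr.shape[0] == 0 or csr.shape[1] == 0:
        raise ParseError(f"matrix in {path} has an empty dimension {csr.shape}")
    return SystemMatrix(csr)


def write_vector(values: np.ndarray, path) -> None:
    """Write a density/projection vector as CSV with columns index,value."""
    values = np.asarray(values, dtype=float).ravel()
    frame = pd.DataFrame({"index": np.arange(values.shape[0]), "value": values})
    frame.to_csv(path, index=False, float_format="%.17g")


def read_vector(path) -> np.ndarray:
    """Read an index,value CSV; indices must be exactly 0..len-1."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse vector file {path}: {exc}") from exc
    if list(frame.columns) != ["index", "value"]:
        raise ParseError(f"{path}: expected header 'index,value', got {list(frame.columns)}")
    if frame.empty:
        raise ParseError(f"{path}: vector file holds no entries")
    idx = frame["index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        bad = int(np.argmax(idx != np.arange(len(idx))))
        raise ParseError(f"indices must be contiguous from 0; first problem at row {bad}",
                         line=bad + 2)
    return frame["value"].to_numpy(dtype=float)


def write_history(history: pd.DataFrame, path) -> None:
    """Write a solver's per-iteration history as CSV."""
    history.to_csv(path, index=False)


def _to_image(values: np.ndarray, grid: PixelGrid) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.shape[0] != grid.N:
        raise ValueError(f"vector length {values.shape[0]} != grid pixels {grid.N}")
    img = values.reshape(grid.n, grid.n)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        scaled = np.round((img - lo) / (hi - lo) * 255.0)
    else:
        scaled = np.full_like(img, 128.0)  # constant image -> mid-gray
    return scaled.astype(np.uint8)


def render_pgm(values: np.ndarray, grid: PixelGrid, path) -> None:
    """8-bit min-max scaled ASCII PGM (P2) view of a density vector."""
    img = _to_image(values, grid)
    lines = ["P2", f"{grid.n} {grid.n}", "255"]
    lines.extend(" ".join(str(v) for v in row) for row in img)
    Path(path).write_text("\n".join(lines) + "\n")


def render_png(values: np.ndarray, grid: PixelGrid, path) -> None:
    """PNG view via Pillow (optional; same scaling as the PGM renderer)."""
    from PIL import Image

    Image.fromarray(_to_image(values, grid), mode="L").save(str(path))


_MISSING = ("", "none", "None")


@dataclass
class RunConfig:
    """Every CLI-settable parameter of a reconstruction run.

    Serializes to a flat ``key = value`` text file and re-parses losslessly,
    so a run can be replayed bit-identically from its config echo.
    """

    n: int = 40
    geometry: str = "one_by_one"
    pkt: int = 50
    angles: int = 100
    rays: int = 121
    phantom: str = "f1"
    algorithm: str = "art"
    lam: float = 1.0
    blocks: int = 1
    workers: int = 1
    constraint: str = "nonneg"
    constraint_timing: str = "per_step"
    max_iterations: int = 1000
    stop_delta: float | None = None
    stop_residual: float | None = None
    noise_sigma: float = 0.0
    noise_seed: int = 0
    out: str = "recon.csv"
    log_level: str = "info"

    def save(self, path) -> None:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            lines.append(f"{f.name} = {'' if value is None else value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"expected 'key = value', got {line!r}", line=lineno)
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            text = raw.pop(f.name)
            if f.name in ("stop_delta", "stop_residual"):
                kwargs[f.name] = None if text in _MISSING else float(text)
            elif f.type == "int":
                kwargs[f.name] = int(text)
            elif f.type == "float":
                kwargs[f.name] = float(text)
            else:
                kwargs[f.name] = text
        if raw:
            raise ParseError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)
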