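"""Centerline point sets and the ASCII interchange format.

The skeletonization stage reduces the vessel mask to centerline points, each
annotated with a local average vessel diameter.  The on-disk format is one
whitespace-separated record per line::

    x y z D

with coordinates and diameter in micrometres, and ``#`` comment lines
allowed anywhere.  This is the deposited-data format used by the original
morphometry studies this package follows, and is the interchange format
between the segmentation and graph-reconstruction stages.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["CenterlineSet", "read_centerline", "write_centerline"]


@dataclass
class CenterlineSet:
    """Ordered collection of centerline points with diameters.

    Attributes
    ----------
    coords
        ``(n, 3)`` float array of physical point coordinates (um).
    diameters
        ``(n,)`` float array of local average vessel diameters (um), all > 0.
    meta
        Free-form source metadata (sample id, voxel spacing, ...).
    """

    coords: np.ndarray
    diameters: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        if self.coords.shape[1] != 3:
            raise DataError(f"coords must be (n, 3), got {self.coords.shape}")
        if len(self.diameters) != len(self.coords):
            raise DataError("coords and diameters length mismatch")
        if len(self.diameters) and self.diameters.min() <= 0:
            raise DataError("all diameters must be > 0")
        if len(self.coords) > 1:
            uniq = np.unique(self.coords, axis=0)
            if len(uniq) != len(self.coords):
                raise DataError("duplicate centerline coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def spacing(self) -> float | None:
        return self.meta.get("spacing")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"x": self.coords[:, 0], "y": self.coords[:, 1],
             "z": self.coords[:, 2], "D": self.diameters}
        )


def write_centerline(cs: CenterlineSet, path: str | Path, precision: int = 6) -> Path:
    """Write the ASCII ``x y z D`` format; gzip if the path ends in ``.gz``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    fmt = f"%.{precision}g %.{precision}g %.{precision}g %.{precision}g\n"
    with opener(path, "wt") as fh:
        for key, value in sorted(cs.meta.items()):
            fh.write(f"# {key}: {value}\n")
        for (x, y, z), d in zip(cs.coords, cs.diameters):
            fh.write(fmt % (x, y, z, d))
    return path


def read_centerline(path: str | Path) -> CenterlineSet:
    """Parse an ASCII centerline file.

    Comment lines starting with ``#`` are skipped (``# key: value`` headers
    are collected into ``meta``).  A malformed record or a non-positive
    diameter raises :class:`DataError` naming the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"centerline file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    coords: list[tuple[float, float, float]] = []
    diameters: list[float] = []
    meta: dict = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = stripped.split()
            if len(parts) != 4:
                raise DataError(
                    f"{path}:{lineno}: expected 4 fields 'x y z D', got {len(parts)}"
                )
            try:
                x, y, z, d = (float(p) for p in parts)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if d <= 0:
                raise DataError(f"{path}:{lineno}: diameter must be > 0, got {d}")
            coords.append((x, y, z))
            diameters.append(d)
    if not coords:
        raise DataError(f"{path}: no centerline points found")
    if "spacing" in meta:
        try:
            meta["spacing"] = float(meta["spacing"])
        except ValueError:
            pass
    logger.info("read %d centerline points from %s", len(coords), path.name)
    return CenterlineSet(np.asarray(coords), np.asarray(diameters), meta=meta)
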