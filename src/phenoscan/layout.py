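"""Multi-well plate geometry.

A plate is a regular grid of circular wells (the physical assay uses a
24-well plate: 6 rows x 4 columns, 15.5 mm well diameter). Treatments are
assigned row-wise, two consecutive rows per treatment, so each treatment
has 2 x n_cols replicate wells (8 on the standard plate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SizingError, ConfigurationError

#: fraction of each image dimension occupied by the well grid
_USABLE_FRACTION = 0.92
#: well radius as a fraction of the grid pitch
_RADIUS_FRACTION = 0.42
#: smallest usable well radius in pixels
_MIN_RADIUS_PX = 8.0

WELL_DIAMETER_MM = 15.5


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a multi-well plate image plus row-wise treatment map."""

    n_rows: int
    n_cols: int
    image_shape: tuple[int, int]
    well_centers: np.ndarray  # (n_wells, 2) float, (y, x) pixel coordinates
    well_radius_px: float
    row_treatments: tuple[str, ...]
    well_diameter_mm: float = WELL_DIAMETER_MM

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def treatments(self) -> tuple[str, ...]:
        """Distinct treatments in row order."""
        seen: dict[str, None] = {}
        for t in self.row_treatments:
            seen.setdefault(t, None)
        return tuple(seen)

    def well_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def well_rowcol(self, index: int) -> tuple[int, int]:
        return divmod(index, self.n_cols)

    def well_treatment(self, index: int) -> str:
        row, _ = self.well_rowcol(index)
        return self.row_treatments[row]

    def wells_of_treatment(self, treatment: str) -> list[int]:
        return [i for i in range(self.n_wells)
                if self.well_treatment(i) == treatment]

    def label_image(self) -> np.ndarray:
        """Integer image: 0 = outside all wells, i+1 = inside well i."""
        h, w = self.image_shape
        labels = np.zeros((h, w), dtype=np.int32)
        r = self.well_radius_px
        for i, (cy, cx) in enumerate(self.well_centers):
            y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
            x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
            yy, xx = np.ogrid[y0:y1, x0:x1]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            labels[y0:y1, x0:x1][disk] = i + 1
        return labels

    def well_disk_mask(self) -> np.ndarray:
        """Boolean image: True inside any well disk."""
        return self.label_image() > 0


def make_layout(
    n_rows: int,
    n_cols: int,
    image_shape: tuple[int, int],
    treatments: Sequence[str],
    seed: int = 0,
    center_jitter_px: float = 1.0,
) -> PlateLayout:
    """Build a plate layout with wells on a regular grid.

    ``treatments`` are assigned to consecutive row pairs: treatments[k]
    covers rows 2k and 2k+1. ``seed`` drives a small (<= ``center_jitter_px``)
    jitter of well centers emulating plate placement tolerance; the result
    is deterministic for fixed inputs.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ConfigurationError("n_rows and n_cols must be positive")
    if n_rows % 2 != 0:
        raise ConfigurationError("n_rows must be even (two rows per treatment)")
    if len(treatments) != n_rows // 2:
        raise ConfigurationError(
            f"expected {n_rows // 2} treatments for {n_rows} rows, "
            f"got {len(treatments)}")

    h, w = int(image_shape[0]), int(image_shape[1])
    pitch_y = h * _USABLE_FRACTION / n_rows
    pitch_x = w * _USABLE_FRACTION / n_cols
    radius = _RADIUS_FRACTION * min(pitch_y, pitch_x)
    if radius < _MIN_RADIUS_PX:
        raise SizingError(
            f"image {h}x{w} too small for {n_rows}x{n_cols} non-overlapping "
            f"wells (radius {radius:.1f} px < {_MIN_RADIUS_PX} px)")

    rng = np.random.default_rng(seed)
    y0 = (h - pitch_y * n_rows) / 2.0
    x0 = (w - pitch_x * n_cols) / 2.0
    centers = np.empty((n_rows * n_cols, 2), dtype=float)
    for i in range(n_rows):
        for j in range(n_cols):
            jitter = rng.uniform(-center_jitter_px, center_jitter_px, size=2)
            centers[i * n_cols + j] = (
                y0 + (i + 0.5) * pitch_y + jitter[0],
                x0 + (j + 0.5) * pitch_x + jitter[1],
            )

    row_treatments = tuple(treatments[i // 2] for i in range(n_rows))
    return PlateLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        image_shape=(h, w),
        well_centers=centers,
        well_radius_px=float(radius),
        row_treatments=row_treatments,
    )
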