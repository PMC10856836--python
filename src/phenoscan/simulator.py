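"""Synthetic multi-well plate image sets with known ground truth.

The raw plate images behind the assay are not publicly deposited, so the
simulator is the test substrate for every downstream stage: it renders
RGB, chlorophyll-fluorescence (F0/Fm/Fs) and thermal frames for one plate
at one timepoint, with per-well ground-truth masks and the realized
spectral-parameter values recorded alongside.

Rendering model (deliberately minimal -- just rich enough that the index,
CF and thermal computations round-trip):

* plants are random-walk-grown blobs centred in each well;
* plant pixel chromaticity is solved in closed form against the well's
  injected mNDI and ExG targets;
* CF plant pixels are the control reference triple scaled by the ratios
  (F0/Fm, Fs/Fm) that realize the injected Fv/Fm and PhiPSII targets --
  a common per-pixel brightness factor multiplies all three frames so the
  ratios survive pixel texture exactly;
* the thermal frame places leaves at (ambient - 2 C) + dT and is shifted
  by a known integer translation relative to the RGB frame;
* the plate rim is neutral grey (the white-balance reference) while the
  in-well growth medium is rendered warm (a* around +9) so the a* channel
  separates plants from background across the whole senescence range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleTargetError
from .layout import PlateLayout
from .presets import (
    CF_SCALE,
    CF_FS_FRACTION,
    CONTROL_FDFM,
    CONTROL_FVFM,
    CONTROL_PHIPSII,
    CONTROL_TREATMENT,
    ResponsePreset,
    cf_ratios_from_percents,
)

# -- appearance constants ---------------------------------------------------

#: chromaticity (r, g, b) of healthy control foliage; NDI = 0.2857, ExG = 0.35
CONTROL_CHROMATICITY = (0.25, 0.45, 0.30)
CONTROL_NDI = (CONTROL_CHROMATICITY[1] - CONTROL_CHROMATICITY[0]) / (
    CONTROL_CHROMATICITY[1] + CONTROL_CHROMATICITY[0])
CONTROL_EXG = (2 * CONTROL_CHROMATICITY[1] - CONTROL_CHROMATICITY[0]
               - CONTROL_CHROMATICITY[2])

#: warm chromaticity of the in-well growth medium (agar); a* ~ +9
AGAR_CHROMATICITY = (0.38, 0.32, 0.30)
#: neutral plate rim used as the white-balance reference
RIM_CHROMATICITY = (1 / 3, 1 / 3, 1 / 3)

PLANT_LUMINANCE = 1.10   # sum R+G+B of plant pixels before texture
AGAR_LUMINANCE = 1.45
RIM_LUMINANCE = 1.65

#: default illumination colour cast (undone by white balancing)
DEFAULT_CAST = (1.04, 1.00, 0.96)

AMBIENT_C = 33.0          # growth chamber air temperature
LEAF_OFFSET_C = -2.0      # transpiring control leaves vs ambient

CF_BACKGROUND = 0.01      # background fluorescence, fraction of CF_SCALE

_BLOB_MIN_PX = 250
_BLOB_MAX_PX = 550


@dataclass
class PlateImageSet:
    """One plate x one timepoint: co-registered frames plus ground truth."""

    layout: PlateLayout
    hat: int
    rgb: np.ndarray | None = None              # (H, W, 3) float in [0, 1]
    cf_stack: np.ndarray | None = None         # (3, H, W): F0, Fm, Fs
    thermal: np.ndarray | None = None          # (H, W) degrees C
    thermal_offset: tuple[int, int] = (0, 0)   # (dy, dx) thermal vs RGB
    ambient: float = AMBIENT_C
    truth_labels: np.ndarray | None = None     # (H, W) int, 0 = background
    truth_values: pd.DataFrame = field(default_factory=pd.DataFrame)

    def truth_mask(self, well_index: int) -> np.ndarray:
        if self.truth_labels is None:
            raise ValueError("scene not rendered")
        return self.truth_labels == well_index + 1


# -- scene construction -----------------------------------------------------


def _grow_blob(rng: np.random.Generator, center: tuple[float, float],
               max_radius: float, n_target: int,
               shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk region growth; returns (rows, cols) of blob pixels."""
    h, w = shape
    cy, cx = int(round(center[0])), int(round(center[1]))
    taken = {(cy, cx)}
    frontier = [(cy, cx)]
    max_r2 = max_radius * max_radius
    budget = 80 * n_target
    while len(taken) < n_target and frontier and budget > 0:
        budget -= 1
        idx = rng.integers(len(frontier))
        py, px = frontier[idx]
        dy, dx = ((0, 1), (0, -1), (1, 0), (-1, 0))[rng.integers(4)]
        q = (py + dy, px + dx)
        if q in taken:
            # densify: occasionally retire exhausted frontier points
            if rng.random() < 0.02:
                frontier.pop(idx)
            continue
        if not (0 <= q[0] < h and 0 <= q[1] < w):
            continue
        if (q[0] - center[0]) ** 2 + (q[1] - center[1]) ** 2 > max_r2:
            continue
        taken.add(q)
        frontier.append(q)
    rows, cols = np.array(sorted(taken)).T
    return rows, cols


def _check_coverage(layout: PlateLayout,
                    presets: Mapping[tuple[str, str], ResponsePreset],
                    parameters: Sequence[str]) -> None:
    missing = [(t, p) for t in set(layout.row_treatments) for p in parameters
               if (t, p) not in presets]
    if missing:
        raise ConfigurationError(
            f"presets missing for treatment/parameter pairs: {missing}")


def _scene(layout: PlateLayout,
           presets: Mapping[tuple[str, str], ResponsePreset],
           hat: int, rng: np.random.Generator,
           noise_scale: float) -> tuple[np.ndarray, pd.DataFrame]:
    """Grow blobs and sample per-well realized parameter values.

    Returns the ground-truth label image and a tidy table of the injected
    per-well values (the value actually rendered, well effect included).
    """
    _check_coverage(layout, presets,
                    ("mNDI", "ExG", "FvFm", "PhiPSII", "dT"))
    h, w = layout.image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    records: list[dict] = []
    for i, (cy, cx) in enumerate(layout.well_centers):
        n_px = int(rng.integers(_BLOB_MIN_PX, _BLOB_MAX_PX))
        max_r = 0.80 * layout.well_radius_px
        n_px = min(n_px, int(2.0 * max_r * max_r))  # cap for tiny wells
        rows, cols = _grow_blob(rng, (cy, cx), max_r, n_px, (h, w))
        labels[rows, cols] = i + 1

        treatment = layout.well_treatment(i)
        row, col = layout.well_rowcol(i)
        realized: dict[str, float] = {}
        for param in ("mNDI", "ExG", "FvFm", "PhiPSII"):
            p = presets[(treatment, param)]
            target = p.value(hat)
            sd = noise_scale * p.noise_sd * target / 100.0
            realized[param] = float(np.clip(rng.normal(target, sd), 0.0, 120.0))
        # keep the CF pair feasible (Fs <= Fm) after noise
        try:
            x, y = cf_ratios_from_percents(realized["FvFm"],
                                           realized["PhiPSII"])
        except InfeasibleTargetError:
            y = 1.0
            x = 1.0 - realized["FvFm"] / 100.0 * CONTROL_FVFM
            ratio = x  # F0/Fs with Fs = Fm
            realized["PhiPSII"] = 100.0 * (1.0 - ratio) / CONTROL_PHIPSII
        realized["FdFm"] = 100.0 * (1.0 - y) / CONTROL_FDFM
        realized["_x"] = x
        realized["_y"] = y

        p_dt = presets[(treatment, "dT")]
        realized["dT"] = float(rng.normal(p_dt.value(hat),
                                          noise_scale * p_dt.noise_sd))

        for param in ("mNDI", "ExG", "FvFm", "PhiPSII", "FdFm", "dT"):
            records.append({
                "well_row": row, "well_col": col, "well_index": i,
                "treatment": treatment, "hat": hat, "parameter": param,
                "value": realized[param],
            })
        # stash the fluorescence ratios for the CF renderer
        records.append({
            "well_row": row, "well_col": col, "well_index": i,
            "treatment": treatment, "hat": hat, "parameter": "_cf_x",
            "value": realized["_x"],
        })
        records.append({
            "well_row": row, "well_col": col, "well_index": i,
            "treatment": treatment, "hat": hat, "parameter": "_cf_y",
            "value": realized["_y"],
        })
    return labels, pd.DataFrame.from_records(records)


def _truth_lookup(truth: pd.DataFrame, well_index: int,
                  parameter: str) -> float:
    sel = truth[(truth.well_index == well_index)
                & (truth.parameter == parameter)]
    return float(sel["value"].iloc[0])


# -- modality renderers -----------------------------------------------------


def _chromaticity_for(mndi_pct: float, exg_pct: float
                      ) -> tuple[float, float, float]:
    """Solve (r, g, b), r+g+b = 1, hitting the well's NDI and ExG targets."""
    n = mndi_pct / 100.0 * CONTROL_NDI
    e = exg_pct / 100.0 * CONTROL_EXG
    g = (e + 1.0) / 3.0                       # ExG = 2g - r - b = 3g - 1
    r = g * (1.0 - n) / (1.0 + n)
    b = 1.0 - r - g
    if min(r, g, b) < 0.0 or max(r, g, b) > 1.0:
        raise InfeasibleTargetError(
            f"no valid chromaticity for mNDI={mndi_pct}%, ExG={exg_pct}%")
    return r, g, b


def _render_rgb(layout: PlateLayout, labels: np.ndarray, truth: pd.DataFrame,
                rng: np.random.Generator, noise_scale: float,
                cast: tuple[float, float, float]) -> np.ndarray:
    h, w = layout.image_shape
    img = np.empty((h, w, 3), dtype=np.float64)

    rim_l = RIM_LUMINANCE * (1.0 + noise_scale * rng.normal(0, 0.03, (h, w)))
    for c in range(3):
        img[..., c] = RIM_CHROMATICITY[c] * rim_l

    well_disks = layout.label_image()
    agar = (well_disks > 0) & (labels == 0)
    agar_l = AGAR_LUMINANCE * (1.0 + noise_scale
                               * rng.normal(0, 0.03, agar.sum()))
    for c in range(3):
        img[..., c][agar] = AGAR_CHROMATICITY[c] * agar_l

    for i in range(layout.n_wells):
        m = labels == i + 1
        n = int(m.sum())
        if n == 0:
            continue
        r0, g0, b0 = _chromaticity_for(_truth_lookup(truth, i, "mNDI"),
                                       _truth_lookup(truth, i, "ExG"))
        jr = noise_scale * rng.normal(0, 0.003, n)
        jg = noise_scale * rng.normal(0, 0.003, n)
        lum = PLANT_LUMINANCE * (1.0 + noise_scale * rng.normal(0, 0.06, n))
        img[..., 0][m] = (r0 + jr) * lum
        img[..., 1][m] = (g0 + jg) * lum
        img[..., 2][m] = (b0 - jr - jg) * lum

    img *= np.asarray(cast)[None, None, :]
    return np.clip(img, 0.0, 1.0)


def _render_cf(layout: PlateLayout, labels: np.ndarray, truth: pd.DataFrame,
               rng: np.random.Generator, noise_scale: float) -> np.ndarray:
    h, w = layout.image_shape
    stack = np.empty((3, h, w), dtype=np.float64)
    bg = CF_BACKGROUND * CF_SCALE
    for k in range(3):
        stack[k] = bg + np.abs(noise_scale
                               * rng.normal(0, 0.002 * CF_SCALE, (h, w)))
    for i in range(layout.n_wells):
        m = labels == i + 1
        n = int(m.sum())
        if n == 0:
            continue
        x = _truth_lookup(truth, i, "_cf_x")
        y = _truth_lookup(truth, i, "_cf_y")
        fm_well = CF_SCALE * (1.0 + noise_scale * rng.normal(0, 0.05))
        brightness = np.clip(
            1.0 + noise_scale * rng.normal(0, 0.08, n), 0.2, None)
        base = fm_well * brightness
        sensor = noise_scale * rng.normal(0, 0.002 * CF_SCALE, (3, n))
        f0 = x * base + sensor[0]
        fm = base + sensor[1]
        fs = y * base + sensor[2]
        f0 = np.minimum(f0, fm)       # sensor noise must not break F0 <= Fm
        fs = np.clip(fs, f0, fm)
        stack[0][m] = f0
        stack[1][m] = fm
        stack[2][m] = fs
    return stack


def _render_thermal(layout: PlateLayout, labels: np.ndarray,
                    truth: pd.DataFrame, rng: np.random.Generator,
                    noise_scale: float, ambient: float,
                    offset: tuple[int, int]) -> np.ndarray:
    h, w = layout.image_shape
    if abs(offset[0]) > 0.1 * h or abs(offset[1]) > 0.1 * w:
        raise ConfigurationError(
            f"thermal offset {offset} exceeds 10% of image size")
    frame = ambient + noise_scale * rng.normal(0, 0.08, (h, w))
    for i in range(layout.n_wells):
        m = labels == i + 1
        if not m.any():
            continue
        dt = _truth_lookup(truth, i, "dT")
        frame[m] = (ambient + LEAF_OFFSET_C + dt
                    + noise_scale * rng.normal(0, 0.08, int(m.sum())))
    # integer translation of the whole thermal frame vs the RGB frame
    frame = np.roll(frame, shift=offset, axis=(0, 1))
    return frame


# -- public API -------------------------------------------------------------


def simulate_plate(
    layout: PlateLayout,
    presets: Mapping[tuple[str, str], ResponsePreset],
    hat: int,
    seed: int,
    *,
    noise_scale: float = 1.0,
    ambient: float = AMBIENT_C,
    thermal_offset: tuple[int, int] = (0, 0),
    cast: tuple[float, float, float] = DEFAULT_CAST,
) -> PlateImageSet:
    """Render a full co-registered plate image set (RGB + CF + thermal).

    Identical arguments produce bit-identical output. ``noise_scale``
    multiplies every stochastic texture/noise amplitude (0 gives
    noise-free plates with randomly shaped but exactly rendered plants).
    """
    rng = np.random.default_rng(seed)
    labels, truth = _scene(layout, presets, hat, rng, noise_scale)
    rgb = _render_rgb(layout, labels, truth, rng, noise_scale, cast)
    cf = _render_cf(layout, labels, truth, rng, noise_scale)
    thermal = _render_thermal(layout, labels, truth, rng, noise_scale,
                              ambient, thermal_offset)
    public = truth[~truth.parameter.str.startswith("_")].reset_index(drop=True)
    return PlateImageSet(
        layout=layout, hat=hat, rgb=rgb, cf_stack=cf, thermal=thermal,
        thermal_offset=tuple(int(v) for v in thermal_offset),
        ambient=ambient, truth_labels=labels, truth_values=public,
    )


def render_rgb_plate(layout, presets, hat, seed, *,
                     noise_scale=1.0, cast=DEFAULT_CAST) -> PlateImageSet:
    """RGB frame plus ground truth (no CF/thermal frames)."""
    rng = np.random.default_rng(seed)
    labels, truth = _scene(layout, presets, hat, rng, noise_scale)
    rgb = _render_rgb(layout, labels, truth, rng, noise_scale, cast)
    public = truth[~truth.parameter.str.startswith("_")].reset_index(drop=True)
    return PlateImageSet(layout=layout, hat=hat, rgb=rgb,
                         truth_labels=labels, truth_values=public)


def render_cf_stack(layout, presets, hat, seed, *,
                    noise_scale=1.0) -> PlateImageSet:
    """F0/Fm/Fs stack plus ground truth (no RGB/thermal frames)."""
    rng = np.random.default_rng(seed)
    labels, truth = _scene(layout, presets, hat, rng, noise_scale)
    _render_rgb(layout, labels, truth, rng, noise_scale, DEFAULT_CAST)
    cf = _render_cf(layout, labels, truth, rng, noise_scale)
    public = truth[~truth.parameter.str.startswith("_")].reset_index(drop=True)
    return PlateImageSet(layout=layout, hat=hat, cf_stack=cf,
                         truth_labels=labels, truth_values=public)


def render_thermal(layout, presets, hat, seed, *, ambient=AMBIENT_C,
                   offset=(0, 0), noise_scale=1.0) -> PlateImageSet:
    """Thermal frame plus ground truth (no RGB/CF frames)."""
    rng = np.random.default_rng(seed)
    labels, truth = _scene(layout, presets, hat, rng, noise_scale)
    _render_rgb(layout, labels, truth, rng, noise_scale, DEFAULT_CAST)
    _render_cf(layout, labels, truth, rng, noise_scale)
    thermal = _render_thermal(layout, labels, truth, rng, noise_scale,
                              ambient, offset)
    public = truth[~truth.parameter.str.startswith("_")].reset_index(drop=True)
    return PlateImageSet(layout=layout, hat=hat, thermal=thermal,
                         thermal_offset=tuple(int(v) for v in offset),
                         ambient=ambient, truth_labels=labels,
                         truth_values=public)
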