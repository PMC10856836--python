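"""Vegetation indices from RGB plate images.

Chromaticities r, g, b are the channel fractions of R+G+B. The greenness
indices are

    NDI = (g - r) / (g + r)
    ExG = 2g - r - b

and mNDI expresses a treated well's NDI as percent of the untreated
control's NDI at the same plate and timepoint. Indices are computed per
pixel and averaged per well; ExG is additionally reported as percent of
the control mean, which is the form used for mode-of-action statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError, NormalizationError
from .layout import PlateLayout
from .presets import CONTROL_TREATMENT
from .segmentation import PlantMask

#: canonical tidy measurement-table columns
MEASUREMENT_COLUMNS = (
    "plate_id", "well_row", "well_col", "treatment", "hat",
    "parameter", "raw_value", "normalized_value", "n_pixels",
)


def chromaticity(R, G, B):
    """Channel fractions (r, g, b) of the total intensity R+G+B."""
    R, G, B = (np.asarray(v, dtype=float) for v in (R, G, B))
    total = R + G + B
    if np.any(total <= 0):
        raise DegenerateInputError(
            "chromaticity undefined for zero-intensity pixel(s)")
    return R / total, G / total, B / total


def ndi(r, g):
    """Normalized difference index (g - r)/(g + r) on chromaticities."""
    r, g = np.asarray(r, dtype=float), np.asarray(g, dtype=float)
    denom = g + r
    if np.any(denom <= 0):
        raise DegenerateInputError("NDI undefined where g + r = 0")
    return (g - r) / denom

def mndi(ndi_h, ndi_0):
    """Treated NDI as percent of the untreated-control NDI."""
    ndi_0 = np.asarray(ndi_0, dtype=float)
    if np.any(ndi_0 == 0):
        raise NormalizationError("control NDI is zero; mNDI undefined")
    return 100.0 * np.asarray(ndi_h, dtype=float) / ndi_0


def exg(r, g, b):
    """Excess green index 2g - r - b on chromaticities."""
    r, g, b = (np.asarray(v, dtype=float) for v in (r, g, b))
    return 2.0 * g - r - b


def well_rgb_summary(
    rgb: np.ndarray,
    mask: PlantMask,
    layout: PlateLayout,
    hat: int,
    plate_id: str = "plate",
    control_treatment: str = CONTROL_TREATMENT,
) -> pd.DataFrame:
    """Per-well mean NDI and ExG, raw and as percent of the control mean.

    Pixels with zero total intensity are excluded (with a warning when any
    occur). The control reference is the mean of control-well means on the
    same plate at the same timepoint; if the plate carries no usable
    control wells the normalized columns are left NaN with a warning.
    """
    rgb = np.asarray(rgb, dtype=float)
    labels = mask.well_labels.copy()
    total = rgb.sum(axis=2)
    bad = (labels > 0) & (total <= 0)
    if bad.any():
        warnings.warn(f"excluded {int(bad.sum())} zero-intensity pixels",
                      stacklevel=2)
        labels = np.where(bad, 0, labels)

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total > 0, rgb[..., 0] / total, 0.0)
        g = np.where(total > 0, rgb[..., 1] / total, 0.0)
        b = np.where(total > 0, rgb[..., 2] / total, 0.0)
        ndi_px = np.where(g + r > 0, (g - r) / (g + r), 0.0)
    exg_px = 2.0 * g - r - b

    present_ids = np.unique(labels[labels > 0])
    present = np.zeros(layout.n_wells, dtype=bool)
    present[present_ids - 1] = True
    ndi_w = np.full(layout.n_wells, np.nan)
    exg_w = np.full(layout.n_wells, np.nan)
    n_w = np.zeros(layout.n_wells)
    ndi_w[present_ids - 1] = ndimage.mean(ndi_px, labels=labels,
                                          index=present_ids)
    exg_w[present_ids - 1] = ndimage.mean(exg_px, labels=labels,
                                          index=present_ids)
    n_w[present_ids - 1] = ndimage.sum_labels(np.ones_like(ndi_px),
                                              labels=labels,
                                              index=present_ids)

    is_control = np.array([layout.well_treatment(i) == control_treatment
                           for i in range(layout.n_wells)])
    ctrl_ok = is_control & present
    if ctrl_ok.any():
        ndi_0 = float(np.mean(ndi_w[ctrl_ok]))
        exg_0 = float(np.mean(exg_w[ctrl_ok]))
    else:
        warnings.warn("no control wells measurable; normalization skipped",
                      stacklevel=2)
        ndi_0 = exg_0 = np.nan

    rows = []
    for i in range(layout.n_wells):
        if not present[i]:
            continue
        wr, wc = layout.well_rowcol(i)
        common = dict(plate_id=plate_id, well_row=wr, well_col=wc,
                      treatment=layout.well_treatment(i), hat=hat,
                      n_pixels=int(n_w[i]))
        m = (mndi(ndi_w[i], ndi_0)
             if np.isfinite(ndi_0) and ndi_0 != 0 else np.nan)
        rows.append(dict(common, parameter="mNDI",
                         raw_value=float(ndi_w[i]),
                         normalized_value=float(m)))
        e = (100.0 * exg_w[i] / exg_0
             if np.isfinite(exg_0) and exg_0 != 0 else np.nan)
        rows.append(dict(common, parameter="ExG",
                         raw_value=float(exg_w[i]),
                         normalized_value=float(e)))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
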