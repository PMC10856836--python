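"""Leaf temperature extraction from IR thermal plate images.

The thermal frame is registered to the RGB frame by an exhaustive
integer-translation search maximizing the cross-correlation between the
thermal "leaf map" (pixels departing from ambient) and the RGB-derived
plant mask. Leaf temperature is then averaged per well through the mask
and the treated-vs-control difference dT = T_h - T_0 computed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import RegistrationError, NormalizationError
from .layout import PlateLayout
from .presets import CONTROL_TREATMENT
from .rgb_indices import MEASUREMENT_COLUMNS
from .segmentation import PlantMask

#: leaf pixels are taken as those at least this far below ambient, or --
#: for heat-stressed leaves -- any departure larger than this (degrees C)
LEAF_CONTRAST_C = 1.0
#: search bound for the translation, as a fraction of each image dimension
SEARCH_FRACTION = 0.10


def register_thermal_to_rgb(
    thermal: np.ndarray,
    mask: PlantMask,
    ambient: float,
    search_fraction: float = SEARCH_FRACTION,
) -> tuple[int, int]:
    """Estimate the (dy, dx) translation of the thermal frame vs the RGB.

    Cross-correlates the binarized leaf map of the thermal image with the
    plant mask over all integer shifts within ``search_fraction`` of the
    image size (FFT accelerated) and returns the argmax. Raises
    :class:`RegistrationError` when the thermal frame carries no leaf
    contrast.
    """
    t = np.asarray(thermal, dtype=float)
    fg = mask.foreground
    if t.shape != fg.shape:
        raise ValueError("thermal frame and mask shapes differ")
    if not fg.any():
        raise RegistrationError("plant mask is empty")
    leaf_map = np.abs(t - ambient) > LEAF_CONTRAST_C
    if leaf_map.sum() < mask.min_pixels:
        raise RegistrationError(
            "thermal frame shows no leaf contrast; registration impossible")

    a = leaf_map.astype(float) - leaf_map.mean()
    b = fg.astype(float) - fg.mean()
    # c[s] = sum_p a(p) b(p - s): peak at the applied translation
    corr = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real

    h, w = t.shape
    by, bx = int(h * search_fraction), int(w * search_fraction)
    shifts_y = np.r_[0:by + 1, h - by:h]
    shifts_x = np.r_[0:bx + 1, w - bx:w]
    window = corr[np.ix_(shifts_y, shifts_x)]
    if np.ptp(window) < 1e-9:
        raise RegistrationError("flat correlation surface")
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy, dx = int(shifts_y[iy]), int(shifts_x[ix])
    if dy > h // 2:
        dy -= h
    if dx > w // 2:
        dx -= w
    return dy, dx


def apply_registration(thermal: np.ndarray,
                       offset: tuple[int, int]) -> np.ndarray:
    """Bring the thermal frame into RGB coordinates (undo the translation)."""
    return np.roll(np.asarray(thermal, dtype=float),
                   shift=(-offset[0], -offset[1]), axis=(0, 1))


def leaf_temperature(thermal: np.ndarray, mask: PlantMask) -> pd.DataFrame:
    """Mean temperature over foreground pixels per well (registered frame)."""
    t = np.asarray(thermal, dtype=float)
    labels = mask.well_labels
    if t.shape != labels.shape:
        raise ValueError("thermal frame and mask shapes differ")
    present_ids = np.unique(labels[labels > 0])
    means = ndimage.mean(t, labels=labels, index=present_ids)
    n_w = ndimage.sum_labels(np.ones_like(t), labels=labels,
                             index=present_ids)
    return pd.DataFrame({
        "well_index": present_ids - 1,
        "temperature_c": means,
        "n_pixels": n_w.astype(int),
    })


def temperature_difference(t_h, t_0):
    """Signed leaf temperature difference T_h - T_0 (degrees C)."""
    return np.asarray(t_h, dtype=float) - np.asarray(t_0, dtype=float)


def well_thermal_summary(
    thermal: np.ndarray,
    mask: PlantMask,
    layout: PlateLayout,
    hat: int,
    ambient: float,
    plate_id: str = "plate",
    control_treatment: str = CONTROL_TREATMENT,
) -> pd.DataFrame:
    """Register, extract leaf temperatures, and emit tidy dT rows.

    ``raw_value`` is the well's mean leaf temperature in degrees C;
    ``normalized_value`` is dT versus the control-well mean.
    """
    offset = register_thermal_to_rgb(thermal, mask, ambient)
    registered = apply_registration(thermal, offset)
    temps = leaf_temperature(registered, mask)
    if temps.empty:
        return pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))
    treatments = np.array([layout.well_treatment(int(i))
                           for i in temps.well_index])
    is_control = treatments == control_treatment
    if is_control.any():
        t0 = float(temps.temperature_c[is_control].mean())
    else:
        warnings.warn("no control wells measurable; dT left undefined",
                      stacklevel=2)
        t0 = np.nan
    rows = []
    for k, i in enumerate(temps.well_index):
        wr, wc = layout.well_rowcol(int(i))
        t_h = float(temps.temperature_c[k])
        rows.append(dict(
            plate_id=plate_id, well_row=wr, well_col=wc,
            treatment=treatments[k], hat=hat, parameter="dT",
            raw_value=t_h,
            normalized_value=(float(temperature_difference(t_h, t0))
                              if np.isfinite(t0) else np.nan),
            n_pixels=int(temps.n_pixels[k]),
        ))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
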