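"""Chlorophyll-fluorescence parameters from F0/Fm/Fs frame stacks.

F0 is the dark-adapted ground fluorescence, Fm the maximum at 1 s, Fs the
steady state at 60 s. Parameters follow the study's formulas:

    Fv/Fm  = (Fm - F0) / Fm
    PhiPSII = (Fs - F0) / Fs      (as printed; see the methods note --
                                   this differs from the conventional
                                   light-adapted (Fm' - Fs)/Fm')
    Fd/Fm  = (Fm - Fs) / Fm

Pixel intensities are averaged per well first and the parameters computed
from the well means; each parameter is then normalized as percent of the
untreated-control mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError, NormalizationError
from .layout import PlateLayout
from .presets import CONTROL_TREATMENT
from .rgb_indices import MEASUREMENT_COLUMNS
from .segmentation import PlantMask

#: acquisition times of the three frames (s); F0 is dark-adapted (t = 0)
ACQUISITION_TIMES_S = (0.0, 1.0, 60.0)


def fv_fm(F0, Fm):
    """Maximum PSII quantum efficiency (Fm - F0)/Fm."""
    F0, Fm = np.asarray(F0, dtype=float), np.asarray(Fm, dtype=float)
    if np.any(Fm <= 0):
        raise DegenerateInputError("Fv/Fm undefined for Fm <= 0")
    return (Fm - F0) / Fm


def phi_psii(F0, Fs):
    """Steady-state quantum-yield parameter (Fs - F0)/Fs, as defined here."""
    F0, Fs = np.asarray(F0, dtype=float), np.asarray(Fs, dtype=float)
    if np.any(Fs <= 0):
        raise DegenerateInputError("PhiPSII undefined for Fs <= 0")
    return (Fs - F0) / Fs


def fd_fm(Fm, Fs):
    """Fluorescence-decline ratio (Fm - Fs)/Fm."""
    Fm, Fs = np.asarray(Fm, dtype=float), np.asarray(Fs, dtype=float)
    if np.any(Fm <= 0):
        raise DegenerateInputError("Fd/Fm undefined for Fm <= 0")
    return (Fm - Fs) / Fm


def normalize_cf(treated, control_mean):
    """Percent of the untreated-control mean."""
    control_mean = np.asarray(control_mean, dtype=float)
    if np.any(control_mean <= 0):
        raise NormalizationError("control mean must be positive")
    return 100.0 * np.asarray(treated, dtype=float) / control_mean


def cf_well_means(stack: np.ndarray, mask: PlantMask) -> pd.DataFrame:
    """Mean F0, Fm, Fs over foreground pixels, per well.

    ``stack`` is a (3, H, W) array in frame order F0, Fm, Fs. Empty wells
    produce no row. Wells whose means violate the expected ordering
    F0 <= Fs <= Fm are flagged (``qc_ordering_violation``), not clipped.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError("expected a (3, H, W) stack ordered F0, Fm, Fs")
    labels = mask.well_labels
    present_ids = np.unique(labels[labels > 0])
    means = [ndimage.mean(stack[k], labels=labels, index=present_ids)
             for k in range(3)]
    n_w = ndimage.sum_labels(np.ones(stack.shape[1:]), labels=labels,
                             index=present_ids)
    rows = []
    for j, lab in enumerate(present_ids):
        f0, fm, fs = (float(means[k][j]) for k in range(3))
        rows.append({
            "well_index": int(lab - 1), "F0": f0, "Fm": fm, "Fs": fs,
            "n_pixels": int(n_w[j]),
            "qc_ordering_violation": not (f0 <= fs + 1e-9 <= fm + 2e-9),
        })
    return pd.DataFrame(rows)


def well_cf_summary(
    stack: np.ndarray,
    mask: PlantMask,
    layout: PlateLayout,
    hat: int,
    plate_id: str = "plate",
    control_treatment: str = CONTROL_TREATMENT,
) -> pd.DataFrame:
    """Tidy per-well CF parameter table, raw and percent-of-control."""
    means = cf_well_means(stack, mask)
    if means.empty:
        return pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))
    vals = {
        "FvFm": fv_fm(means.F0, means.Fm),
        "PhiPSII": phi_psii(means.F0, means.Fs),
        "FdFm": fd_fm(means.Fm, means.Fs),
    }
    treatments = np.array([layout.well_treatment(i)
                           for i in means.well_index])
    is_control = treatments == control_treatment
    rows = []
    for param, v in vals.items():
        v = np.asarray(v, dtype=float)
        if is_control.any():
            ref = float(np.mean(v[is_control]))
        else:
            warnings.warn(
                "no control wells measurable; CF normalization skipped",
                stacklevel=2)
            ref = np.nan
        for k, i in enumerate(means.well_index):
            wr, wc = layout.well_rowcol(int(i))
            norm = (float(normalize_cf(v[k], ref))
                    if np.isfinite(ref) and ref > 0 else np.nan)
            rows.append(dict(
                plate_id=plate_id, well_row=wr, well_col=wc,
                treatment=treatments[k], hat=hat, parameter=param,
                raw_value=float(v[k]), normalized_value=norm,
                n_pixels=int(means.n_pixels[k]),
            ))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
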