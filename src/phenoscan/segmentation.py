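"""Plant segmentation from RGB plate images.

Procedure: white balance (grey-world on the plate rim), RGB -> CIE L*a*b*,
Otsu threshold on the a* values inside the well disks (vegetation sits on
the negative, green side of the a* axis; the growth medium is warmer), and
per-well partition of the foreground with small-component suppression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color, morphology

from .errors import DegenerateInputError
from .layout import PlateLayout

#: connected components smaller than this are discarded as noise
MIN_COMPONENT_PX = 5
#: wells with fewer foreground pixels than this are flagged empty
DEFAULT_MIN_PIXELS = 50

OTSU_NBINS = 256


#: minimum Otsu effectiveness (between-class / total variance) for a well's
#: a* sample to count as genuinely bimodal (plant + background) rather than
#: unimodal background noise
MIN_OTSU_EFFECTIVENESS = 0.8


@dataclass
class PlantMask:
    """Per-pixel foreground labelling with per-well partition."""

    foreground: np.ndarray          # (H, W) bool
    well_labels: np.ndarray         # (H, W) int, 0 = background, i+1 = well i
    n_pixels_per_well: np.ndarray   # (n_wells,) int
    empty_wells: np.ndarray         # (n_wells,) bool
    thresholds_a: np.ndarray        # (n_wells,) Otsu thresholds on a* (NaN
                                    # where no bimodal signal was found)
    min_pixels: int

    @property
    def n_wells(self) -> int:
        return len(self.n_pixels_per_well)

    def well_mask(self, well_index: int) -> np.ndarray:
        return self.well_labels == well_index + 1


def white_balance(rgb: np.ndarray,
                  background: np.ndarray | None = None) -> np.ndarray:
    """Grey-world white balance computed on background pixels.

    Each channel is scaled so the background channel means become equal
    (to their common grey mean); output is clipped to [0, 1]. ``background``
    is a boolean mask of reference pixels (e.g. the plate rim outside the
    well disks); when omitted the whole image is used.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    if background is None:
        ref = rgb.reshape(-1, 3)
    else:
        ref = rgb[np.asarray(background, bool)]
    if ref.size == 0:
        raise DegenerateInputError("empty background reference")
    means = ref.mean(axis=0)
    if np.any(means <= 0):
        raise DegenerateInputError(
            "background has a zero-mean channel; cannot white balance")
    grey = means.mean()
    return np.clip(rgb * (grey / means)[None, None, :], 0.0, 1.0)


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB (values in [0, 1]) to CIE L*a*b* under D65."""
    return color.rgb2lab(np.asarray(rgb, dtype=float))


def _bin_index(values: np.ndarray, lo: float, width: float,
               nbins: int) -> np.ndarray:
    idx = np.floor((values - lo) / width).astype(np.intp)
    return np.clip(idx, 0, nbins - 1)


def otsu_threshold(values: np.ndarray, nbins: int = OTSU_NBINS) -> float:
    """Otsu threshold of a 1-D sample, maximizing between-class variance.

    Candidate thresholds are the interior edges of ``nbins`` equal-width
    bins spanning the sample range; class statistics use the exact sample
    values. Ties break toward the smallest maximizing bin. The returned
    threshold separates class 0 (values strictly below it, up to binning)
    from class 1.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise DegenerateInputError("need at least 2 values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateInputError("constant sample has no Otsu threshold")
    width = (hi - lo) / nbins
    idx = _bin_index(v, lo, width, nbins)
    counts = np.bincount(idx, minlength=nbins).astype(float)
    sums = np.bincount(idx, weights=v, minlength=nbins)

    n0 = np.cumsum(counts)[:-1]            # class sizes for split after bin k
    s0 = np.cumsum(sums)[:-1]
    n1 = v.size - n0
    s1 = v.sum() - s0
    valid = (n0 > 0) & (n1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / n0
        mu1 = s1 / n1
        sigma_b = (n0 / v.size) * (n1 / v.size) * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    k = int(np.argmax(sigma_b))            # argmax returns the smallest tie
    return lo + (k + 1) * width


def _otsu_effectiveness(values: np.ndarray, threshold: float) -> float:
    """Between-class variance at ``threshold`` over total variance.

    Near 1 for a cleanly bimodal sample; ~0.64 when Otsu merely bisects
    unimodal Gaussian noise.
    """
    total = values.var()
    if total == 0:
        return 0.0
    lo = values[values < threshold]
    hi = values[values >= threshold]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0 = lo.size / values.size
    return float(w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2 / total)


def segment_plants(rgb: np.ndarray, layout: PlateLayout,
                   min_pixels: int = DEFAULT_MIN_PIXELS,
                   threshold_scope: str = "well") -> PlantMask:
    """Segment plants from a white-balanced RGB plate image.

    Foreground = pixels inside well disks whose a* value falls below the
    Otsu threshold of the in-well a* sample (plants are the green, low-a*
    class; the growth medium sits on the warm side). With the default
    ``threshold_scope="well"`` each well gets its own threshold, which
    keeps senescent (near-neutral a*) plants segmentable on plates that
    also carry healthy green wells; ``"plate"`` uses a single threshold
    over all well disks. Wells whose a* sample is not convincingly bimodal
    (Otsu effectiveness < ``MIN_OTSU_EFFECTIVENESS``) are treated as
    plant-free. Components below ``MIN_COMPONENT_PX`` pixels are removed;
    wells with fewer than ``min_pixels`` foreground pixels are flagged
    empty.
    """
    if threshold_scope not in ("well", "plate"):
        raise ValueError("threshold_scope must be 'well' or 'plate'")
    lab = rgb_to_lab(rgb)
    a_star = lab[..., 1]
    disk_labels = layout.label_image()
    in_well = disk_labels > 0

    thresholds = np.full(layout.n_wells, np.nan)
    fg = np.zeros(a_star.shape, dtype=bool)
    if threshold_scope == "plate":
        thr = otsu_threshold(a_star[in_well])
        thresholds[:] = thr
        fg = in_well & (a_star < thr)
    else:
        for i in range(layout.n_wells):
            disk = disk_labels == i + 1
            sample = a_star[disk]
            try:
                thr = otsu_threshold(sample)
            except DegenerateInputError:
                continue
            if _otsu_effectiveness(sample, thr) < MIN_OTSU_EFFECTIVENESS:
                continue  # unimodal background; no plant signal
            thresholds[i] = thr
            fg |= disk & (a_star < thr)

    fg = morphology.remove_small_objects(fg, max_size=MIN_COMPONENT_PX - 1)

    well_labels = np.where(fg, disk_labels, 0).astype(np.int32)
    n_px = np.bincount(well_labels.ravel(),
                       minlength=layout.n_wells + 1)[1:]
    empty = n_px < min_pixels
    for i in np.nonzero(empty)[0]:
        well_labels[well_labels == i + 1] = 0
    fg = well_labels > 0

    if empty.all():
        warnings.warn("no well reached min_pixels foreground; empty plate?",
                      stacklevel=2)
    return PlantMask(
        foreground=fg,
        well_labels=well_labels,
        n_pixels_per_well=n_px,
        empty_wells=empty,
        thresholds_a=thresholds,
        min_pixels=int(min_pixels),
    )
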