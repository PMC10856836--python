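"""End-to-end orchestration: simulate -> segment -> measure -> diagnose.

A run renders synthetic plates for every configured timepoint, measures
all six spectral parameters through the same code paths a real image set
would take, and produces the tidy measurement table, per-parameter ANOVA,
per-timepoint and pooled PCA, the cluster-separation report and a manifest
with checksums. Fixed config + seed gives identical measurement CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .errors import ConfigurationError
from .layout import make_layout
from .moa_stats import (
    DEFAULT_N_COMPONENTS,
    DEFAULT_SEPARATION_THRESHOLD,
    run_pooled_pca,
    separation_report,
    separation_timeline,
    two_way_anova,
)
from .presets import (
    CONTROL_TREATMENT,
    HATS,
    HERBICIDES,
    PARAMETERS,
    default_presets,
    load_presets,
)
from .cf_analysis import well_cf_summary
from .rgb_indices import well_rgb_summary
from .segmentation import DEFAULT_MIN_PIXELS, segment_plants, white_balance
from .simulator import AMBIENT_C, simulate_plate
from .thermal_analysis import well_thermal_summary

logger = logging.getLogger("phenoscan")

#: label dose in g a.i./ha for each herbicide (recommended field dose)
RECOMMENDED_DOSES: Mapping[str, float] = {
    "paraquat": 500.0,
    "tiafenacil": 160.0,
    "penoxsulam": 120.0,
    "isoxaflutole": 200.0,
    "glufosinate": 1440.0,
    "glyphosate": 3690.0,
}

#: the assay sprays a quarter of the recommended dose
TESTED_DOSE_FRACTION = 0.25

#: default plate composition: three treatments per 6-row plate, each plate
#: carrying its own untreated control pair for normalization
DEFAULT_PLATES: tuple[tuple[str, str, str], ...] = (
    ("paraquat", "tiafenacil", CONTROL_TREATMENT),
    ("glufosinate", "glyphosate", CONTROL_TREATMENT),
    ("isoxaflutole", "penoxsulam", CONTROL_TREATMENT),
)


def derive_tested_doses(recommended: Mapping[str, float]
                        ) -> dict[str, float]:
    """Tested dose = recommended / 4 (metadata only)."""
    out = {}
    for herb, dose in recommended.items():
        if not np.isfinite(dose) or dose <= 0:
            raise ConfigurationError(
                f"recommended dose for {herb!r} must be positive, got {dose}")
        out[herb] = dose * TESTED_DOSE_FRACTION
    return out


@dataclass
class RunConfig:
    """Everything a pipeline run needs, seeds included."""

    hats: tuple[int, ...] = HATS
    plates: tuple[tuple[str, ...], ...] = DEFAULT_PLATES
    image_shape: tuple[int, int] = (720, 480)
    n_rows: int = 6
    n_cols: int = 4
    seed: int = 0
    noise_scale: float = 1.0
    min_pixels: int = DEFAULT_MIN_PIXELS
    separation_threshold: float = DEFAULT_SEPARATION_THRESHOLD
    n_components: int = DEFAULT_N_COMPONENTS
    ambient: float = AMBIENT_C
    max_thermal_offset: int = 12
    preset_path: str | None = None
    recommended_doses: Mapping[str, float] = field(
        default_factory=lambda: dict(RECOMMENDED_DOSES))

    def __post_init__(self) -> None:
        if not self.hats:
            raise ConfigurationError("HAT list must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = pio.load_yaml(path) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "hats" in raw:
            raw["hats"] = tuple(int(h) for h in raw["hats"])
        if "plates" in raw:
            raw["plates"] = tuple(tuple(p) for p in raw["plates"])
        if "image_shape" in raw:
            raw["image_shape"] = tuple(int(v) for v in raw["image_shape"])
        return cls(**raw)


def _stage_seed(base_seed: int, plate_idx: int, hat: int, stage: int) -> int:
    """Deterministic per-stage seed fan-out (documented counter scheme)."""
    ss = np.random.SeedSequence(
        entropy=base_seed, spawn_key=(plate_idx, int(hat), stage))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def measure_plate_set(image_set, min_pixels: int = DEFAULT_MIN_PIXELS,
                      plate_id: str = "plate") -> pd.DataFrame:
    """Segment one rendered plate set and measure all six parameters."""
    layout = image_set.layout
    wb = white_balance(image_set.rgb, background=~layout.well_disk_mask())
    mask = segment_plants(wb, layout, min_pixels=min_pixels)
    frames = [
        well_rgb_summary(wb, mask, layout, image_set.hat, plate_id=plate_id),
        well_cf_summary(image_set.cf_stack, mask, layout, image_set.hat,
                        plate_id=plate_id),
        well_thermal_summary(image_set.thermal, mask, layout, image_set.hat,
                             ambient=image_set.ambient, plate_id=plate_id),
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_and_measure(config: RunConfig) -> pd.DataFrame:
    """Render and measure every (plate, HAT) of the configured experiment."""
    presets = (load_presets(config.preset_path) if config.preset_path
               else default_presets())
    tables = []
    for p_idx, plate_treatments in enumerate(config.plates):
        layout = make_layout(config.n_rows, config.n_cols,
                             config.image_shape, plate_treatments,
                             seed=_stage_seed(config.seed, p_idx, 0, 0))
        for hat in config.hats:
            rng = np.random.default_rng(
                _stage_seed(config.seed, p_idx, hat, 1))
            off = (int(rng.integers(-config.max_thermal_offset,
                                    config.max_thermal_offset + 1)),
                   int(rng.integers(-config.max_thermal_offset,
                                    config.max_thermal_offset + 1)))
            image_set = simulate_plate(
                layout, presets, hat,
                seed=_stage_seed(config.seed, p_idx, hat, 2),
                noise_scale=config.noise_scale, ambient=config.ambient,
                thermal_offset=off)
            t0 = time.perf_counter()
            table = measure_plate_set(image_set, config.min_pixels,
                                      plate_id=f"plate{p_idx}")
            logger.info("plate%d hat=%d measured in %.2fs",
                        p_idx, hat, time.perf_counter() - t0)
            tables.append(table)
    return pd.concat(tables, ignore_index=True)


def balanced_analysis_subset(measurements: pd.DataFrame,
                             control_plate: str = "plate0") -> pd.DataFrame:
    """Restrict control samples to one plate so the factorial is balanced.

    Every plate carries control wells for normalization; for ANOVA/PCA the
    control group's replicates are taken from ``control_plate`` only, so
    all treatment x time cells have equal replication.
    """
    keep = (measurements.treatment != CONTROL_TREATMENT) | (
        measurements.plate_id == control_plate)
    return measurements[keep].reset_index(drop=True)


def diagnose(measurements: pd.DataFrame,
             threshold: float = DEFAULT_SEPARATION_THRESHOLD,
             n_components: int = DEFAULT_N_COMPONENTS,
             pooled: bool | None = None) -> dict:
    """ANOVA per parameter + per-HAT and pooled PCA separation reports."""
    data = balanced_analysis_subset(measurements)
    n_hats = data.hat.nunique()
    anova = {}
    if n_hats >= 2:
        for param in PARAMETERS:
            anova[param] = two_way_anova(data, param)
    timeline = separation_timeline(data, threshold=threshold,
                                   n_components=n_components)
    out = {"anova": anova, "separation_timeline": timeline}
    if pooled is None:
        pooled = n_hats >= 2
    if pooled:
        if n_hats < 2:
            raise ConfigurationError(
                "pooled PCA needs >= 2 timepoints; run per-HAT mode only")
        pooled_pca = run_pooled_pca(data)
        out["pooled_pca"] = pooled_pca
        out["pooled_separation"] = separation_report(
            pooled_pca, threshold=threshold, n_components=n_components)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Full run; writes artifacts and a checksummed manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    measurements = simulate_and_measure(config)
    pio.save_table(out / "measurements.csv", measurements)

    results = diagnose(measurements, threshold=config.separation_threshold,
                       n_components=config.n_components)
    if results["anova"]:
        anova_table = pd.concat(
            [r.to_frame() for r in results["anova"].values()],
            ignore_index=True)
        pio.save_table(out / "anova.csv", anova_table)
    pio.save_table(out / "separation_per_hat.csv",
                   results["separation_timeline"])
    if "pooled_pca" in results:
        pca = results["pooled_pca"]
        scores = pca.sample_annotations.copy()
        for j in range(pca.scores.shape[1]):
            scores[f"PC{j + 1}"] = pca.scores[:, j]
        pio.save_table(out / "pca_pooled_scores.csv", scores)
        loadings = pd.DataFrame(
            pca.loadings,
            index=list(pca.feature_names),
            columns=[f"PC{j + 1}" for j in range(pca.loadings.shape[1])])
        pio.save_table(out / "pca_pooled_loadings.csv",
                       loadings.reset_index(names="parameter"))
        pio.save_table(out / "pooled_separation.csv",
                       results["pooled_separation"])

    doses = derive_tested_doses(config.recommended_doses)
    manifest = {
        "seed": config.seed,
        "hats": list(config.hats),
        "noise_scale": config.noise_scale,
        "separation_threshold": config.separation_threshold,
        "tested_doses_g_ai_ha": doses,
        "files": {},
    }
    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
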