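"""Response presets: per-herbicide spectral-parameter trajectories.

The simulator injects these trajectories as ground truth. The five RGB/CF
percent parameters are expressed as percent of the untreated control; the
thermal parameter ``dT`` is the leaf-minus-control temperature difference
in degrees C.

CF reference kinetics
---------------------
Plant pixels in the fluorescence stack are generated from a control
reference triple ``(F0, Fm, Fs) = (0.2, 1.0, FS0) * S``. ``F0 = 0.2 Fm``
gives the canonical healthy-leaf Fv/Fm of 0.8. The steady-state level
``FS0 = 0.2969 Fm`` is the solution that makes the three study formulas

    Fv/Fm = (Fm - F0)/Fm,  PhiPSII = (Fs - F0)/Fs,  Fd/Fm = (Fm - Fs)/Fm

mutually consistent with the anchored early-paraquat response pattern:
because the three parameters are functions of just two ratios
(x = F0/Fm, y = Fs/Fm), only two of them are free. Presets therefore
author Fv/Fm and PhiPSII; Fd/Fm is derived here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, InfeasibleTargetError

HATS: tuple[int, ...] = (3, 6, 24, 48, 72, 120)

PARAMETERS: tuple[str, ...] = ("mNDI", "ExG", "FvFm", "PhiPSII", "FdFm", "dT")
PERCENT_PARAMETERS: tuple[str, ...] = ("mNDI", "ExG", "FvFm", "PhiPSII", "FdFm")

CONTROL_TREATMENT = "control"
HERBICIDES: tuple[str, ...] = (
    "paraquat", "tiafenacil", "penoxsulam",
    "isoxaflutole", "glufosinate", "glyphosate",
)

#: herbicide -> biochemical target (mode of action)
MODES_OF_ACTION: Mapping[str, str] = {
    "paraquat": "PSI",
    "tiafenacil": "PPO",
    "penoxsulam": "ALS",
    "isoxaflutole": "HPPD",
    "glufosinate": "GS",
    "glyphosate": "EPSPS",
}

# Control reference fluorescence kinetics (fractions of Fm).
CF_F0_FRACTION = 0.2
CF_FM_FRACTION = 1.0
CF_FS_FRACTION = 0.2969
CF_SCALE = 1000.0

#: control (untreated) values of the three CF parameters
CONTROL_FVFM = (CF_FM_FRACTION - CF_F0_FRACTION) / CF_FM_FRACTION
CONTROL_PHIPSII = (CF_FS_FRACTION - CF_F0_FRACTION) / CF_FS_FRACTION
CONTROL_FDFM = (CF_FM_FRACTION - CF_FS_FRACTION) / CF_FM_FRACTION


@dataclass(frozen=True)
class ResponsePreset:
    """One (treatment, parameter) trajectory over hours after treatment."""

    treatment: str
    parameter: str
    trajectory: Mapping[int, float]
    noise_sd: float

    def value(self, hat: int) -> float:
        try:
            return float(self.trajectory[hat])
        except KeyError:
            raise ConfigurationError(
                f"no preset value for {self.treatment}/{self.parameter} "
                f"at {hat} HAT") from None

    def __post_init__(self) -> None:
        vals = np.array(list(self.trajectory.values()), dtype=float)
        if self.parameter in PERCENT_PARAMETERS:
            if np.any(vals < 0) or np.any(vals > 120):
                raise ConfigurationError(
                    f"{self.treatment}/{self.parameter}: percent values must "
                    f"lie in [0, 120]")


def cf_ratios_from_percents(fvfm_pct: float, phipsii_pct: float
                            ) -> tuple[float, float]:
    """Map percent-of-control (Fv/Fm, PhiPSII) to the ratios (F0/Fm, Fs/Fm).

    Raises :class:`InfeasibleTargetError` when the targets would require
    F0 > Fm (Fv/Fm percent above 125 with the 0.8 reference) or Fs outside
    [F0, Fm].
    """
    x = 1.0 - (fvfm_pct / 100.0) * CONTROL_FVFM          # F0/Fm
    ratio = 1.0 - (phipsii_pct / 100.0) * CONTROL_PHIPSII  # F0/Fs
    if x < 0.0 or x > 1.0:
        raise InfeasibleTargetError(
            f"Fv/Fm target {fvfm_pct}% incompatible with control reference "
            f"(would need F0/Fm = {x:.3f})")
    if ratio <= 0.0:
        raise InfeasibleTargetError(
            f"PhiPSII target {phipsii_pct}% incompatible with control "
            f"reference")
    y = 1.0 if ratio == 0 else x / ratio                  # Fs/Fm
    if x == 0.0 and ratio > 0.0:
        # fully open centers: Fs free; pin it at the reference level
        y = CF_FS_FRACTION
    if y > 1.0 + 1e-9:
        raise InfeasibleTargetError(
            f"targets Fv/Fm={fvfm_pct}%, PhiPSII={phipsii_pct}% would need "
            f"Fs > Fm (Fs/Fm = {y:.3f})")
    return x, min(y, 1.0)


def derived_fdfm_pct(fvfm_pct: float, phipsii_pct: float) -> float:
    """Fd/Fm percent-of-control implied by Fv/Fm and PhiPSII targets."""
    _, y = cf_ratios_from_percents(fvfm_pct, phipsii_pct)
    return 100.0 * (1.0 - y) / CONTROL_FDFM


def _default_config_path() -> Path:
    return Path(resources.files("phenoscan") / "data" / "presets.yaml")


def load_presets(path: str | Path | None = None
                 ) -> dict[tuple[str, str], ResponsePreset]:
    """Load a preset table from YAML, deriving the Fd/Fm trajectories.

    Returns a mapping keyed by ``(treatment, parameter)`` covering all six
    spectral parameters for every treatment in the file.
    """
    path = Path(path) if path is not None else _default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    hats = [int(h) for h in raw["hats"]]
    noise = raw["noise_sd"]
    presets: dict[tuple[str, str], ResponsePreset] = {}
    for treatment, table in raw["trajectories"].items():
        for param in ("mNDI", "ExG", "FvFm", "PhiPSII", "dT"):
            values = table[param]
            if len(values) != len(hats):
                raise ConfigurationError(
                    f"{treatment}/{param}: expected {len(hats)} values")
            presets[(treatment, param)] = ResponsePreset(
                treatment=treatment,
                parameter=param,
                trajectory=dict(zip(hats, map(float, values))),
                noise_sd=float(noise[param]),
            )
        fdfm = {
            h: derived_fdfm_pct(table["FvFm"][k], table["PhiPSII"][k])
            for k, h in enumerate(hats)
        }
        presets[(treatment, "FdFm")] = ResponsePreset(
            treatment=treatment,
            parameter="FdFm",
            trajectory=fdfm,
            noise_sd=float(noise["FvFm"]),
        )
    return presets


def default_presets() -> dict[tuple[str, str], ResponsePreset]:
    """Presets for the six herbicides plus the untreated control."""
    return load_presets(None)


def preset_value(presets: Mapping[tuple[str, str], ResponsePreset],
                 treatment: str, parameter: str, hat: int) -> float:
    try:
        return presets[(treatment, parameter)].value(hat)
    except KeyError:
        raise ConfigurationError(
            f"no preset for treatment={treatment!r} "
            f"parameter={parameter!r}") from None
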