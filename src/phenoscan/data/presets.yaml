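# Per-herbicide response trajectories injected by the plate simulator.
#
# Units: mNDI, ExG, FvFm, PhiPSII are percent of the untreated control;
# dT is the leaf temperature difference vs the control in degrees C.
# Keys are hours after treatment (HAT).
#
# Anchor cells are the values printed in the source study (paraquat:
# mNDI 53.9 / ExG 73.5 at 6 HAT; FvFm 45.9, PhiPSII 56.7 at 3 HAT, all CF
# parameters 0 at 6 HAT). All other cells are authored to honor the
# qualitative response ordering reported there: paraquat fastest;
# tiafenacil clearly changed by 24 HAT; glufosinate and glyphosate moving
# together at 24 HAT and diverging by 48 HAT; isoxaflutole unchanged until
# a late PhiPSII collapse at 120 HAT; penoxsulam indistinguishable from
# the control throughout.
#
# FdFm is NOT listed: with the study's formulas the three CF parameters
# carry only two degrees of freedom, so FdFm is derived from FvFm and
# PhiPSII through the control reference kinetics (see phenoscan.presets).

hats: [3, 6, 24, 48, 72, 120]

noise_sd:
  mNDI: 2.0      # percent points at control level; scales with the target
  ExG: 2.0
  FvFm: 2.0
  PhiPSII: 2.0
  dT: 0.3        # degrees C, additive

trajectories:
  control:
    mNDI:    [100, 100, 100, 100, 100, 100]
    ExG:     [100, 100, 100, 100, 100, 100]
    FvFm:    [100, 100, 100, 100, 100, 100]
    PhiPSII: [100, 100, 100, 100, 100, 100]
    dT:      [0, 0, 0, 0, 0, 0]
  paraquat:
    mNDI:    [97, 53.9, 15, 8, 5, 3]
    ExG:     [98, 73.5, 20, 10, 6, 4]
    FvFm:    [45.9, 0, 0, 0, 0, 0]
    PhiPSII: [56.7, 0, 0, 0, 0, 0]
    dT:      [1.0, 2.0, -1.5, -2.5, -3.0, -3.0]
  tiafenacil:
    mNDI:    [100, 97, 60, 20, 10, 8]
    ExG:     [100, 98, 65, 25, 12, 10]
    FvFm:    [100, 98, 55, 20, 3, 2]
    PhiPSII: [100, 96, 50, 12, 2, 2]
    dT:      [0.2, 0.5, 1.2, 1.8, 0.5, -1.0]
  penoxsulam:
    mNDI:    [100, 100, 99, 99, 98, 99]
    ExG:     [100, 100, 99, 99, 98, 98]
    FvFm:    [100, 100, 100, 99, 99, 99]
    PhiPSII: [100, 100, 99, 99, 99, 99]
    dT:      [0.0, 0.0, 0.1, 0.1, 0.1, 0.1]
  isoxaflutole:
    mNDI:    [100, 100, 99, 99, 98, 92]
    ExG:     [100, 100, 99, 98, 97, 93]
    FvFm:    [100, 100, 99, 98, 98, 75]
    PhiPSII: [100, 100, 98, 97, 97, 35]
    dT:      [0.0, 0.0, 0.1, 0.2, 0.3, 1.5]
  glufosinate:
    mNDI:    [100, 99, 95, 70, 45, 30]
    ExG:     [100, 99, 94, 75, 50, 35]
    FvFm:    [100, 98, 89, 70, 55, 45]
    PhiPSII: [100, 97, 48, 30, 25, 20]
    dT:      [0.3, 0.6, 1.4, 1.0, 0.5, 0.1]
  glyphosate:
    mNDI:    [100, 99, 96, 90, 70, 50]
    ExG:     [100, 99, 95, 92, 75, 55]
    FvFm:    [100, 99, 89, 80, 65, 55]
    PhiPSII: [100, 98, 50, 40, 32, 28]
    dT:      [0.2, 0.5, 1.2, 1.6, 0.8, 0.2]
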