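# Methods

## The assay and what the package models

A multi-well plate bioassay reads herbicide activity off living seedlings
with three imaging modalities. Mode of action (MoA) shows up as *when* and
*where* the spectral parameters move: a photosystem-I inhibitor
(paraquat) collapses chlorophyll fluorescence within hours, long before
visible wilting; a PPO inhibitor (tiafenacil) follows within a day;
glutamine-synthase and EPSPS inhibitors (glufosinate, glyphosate) act over
two days; an HPPD bleacher (isoxaflutole) shows almost nothing until a
late fluorescence collapse; and an ALS inhibitor with no activity on this
grass (penoxsulam) never departs from the untreated control.

The package implements the full analysis path -- segmentation, per-well
parameter extraction, control normalization, ANOVA, correlation PCA and
cluster-separation scoring -- plus a synthetic plate simulator that stands
in for the (undeposited) raw images.

## Simulator

**What it emulates.** One plate x one timepoint yields a co-registered
set: an RGB frame, a three-frame CF stack (F0, Fm, Fs at 0 s / 1 s /
60 s), and a thermal frame, with per-well ground-truth masks and the
realized parameter values. Plants are random-walk-grown blobs (250-550 px)
centred in each 15.5 mm well; the default frame is 720 x 480 px for the
6 x 4 plate (500 x 480 for a 4 x 4 sub-plate), chosen so a well disk spans
~90 px -- small enough that a full six-timepoint, three-plate experiment
renders and measures in well under a minute, large enough that per-well
means average over hundreds of pixels.

**Injected trajectories.** `data/presets.yaml` holds per-herbicide
trajectories over 3-120 HAT for mNDI, ExG, Fv/Fm and PhiPSII (percent of
control) and dT (degrees C). Cells printed in the reference study are
anchored exactly (paraquat: mNDI 53.9 / ExG 73.5 at 6 HAT; Fv/Fm 45.9 and
PhiPSII 56.7 at 3 HAT; all CF parameters 0 from 6 HAT). Unprinted cells
are authored once, as smooth monotone-in-time curves honouring the
qualitative ordering above, and are deliberately *not* free knobs: they
define the study conditions every test runs under. Two herbicides with
reportedly similar early kinetics (glufosinate, glyphosate) are kept
near-identical at 24 HAT and diverge by 48 HAT, matching the reported
clustering sequence.

**CF reference kinetics and the derived Fd/Fm.** The three CF formulas
depend only on two ratios x = F0/Fm and y = Fs/Fm, so only two of the
three parameters can be prescribed independently; the presets author
Fv/Fm and PhiPSII and derive Fd/Fm. Control plants are rendered with
(F0, Fm, Fs) = (0.2, 1.0, 0.2969) x S (S = 1000): F0 = 0.2 Fm gives the
canonical healthy-leaf Fv/Fm of 0.8, and the steady-state fraction 0.2969
is the root of the consistency condition that makes the three printed
early-paraquat percentages (45.9 / 56.7 / 31.8) simultaneously
realizable -- with the more usual Fs = 0.5 Fm they are mutually
infeasible under these formulas. A side effect worth knowing: PhiPSII as
defined here is *hypersensitive* -- small Fv/Fm or Fd/Fm changes imply
large PhiPSII swings -- which is also why the simulator samples replicate
noise on (Fv/Fm, PhiPSII) and lets Fd/Fm inherit it, not the reverse.

**Pixel model.** Plant chromaticity is solved in closed form from the
well's injected (mNDI, ExG) pair (two constraints, two degrees of freedom
on the simplex), then multiplied by a textured luminance; CF pixels scale
the (x, 1, y) triple by one common per-pixel brightness factor so the
well-mean ratios equal the injected values exactly; thermal leaves sit at
ambient - 2 C + dT (33 C chamber; the -2 C transpiration offset is a fixed
documented constant). An illumination cast (1.04, 1.00, 0.96) multiplies
the RGB channels and is what the white-balance stage must undo. The
thermal frame is translated by a known integer offset (pure translation,
no rotation/scale -- keeps ground truth exact).

**Replicate noise.** Each well draws one random effect per parameter with
sd = noise_sd x target/100 (noise_sd = 2 percent points, so exactly 2 at
the control level), plus small per-pixel chromaticity/brightness jitter.
The proportional form means dead tissue (target 0) shows no replicate
variance -- a truncated additive Gaussian would instead bias "0%" wells
upward by ~1.6 points, contradicting the anchored zero. dT noise stays
additive (sd 0.3 C).

**Background palette.** The plate rim is neutral grey (the white-balance
reference); the in-well medium is rendered warm (a* ~ +9). A fully
achromatic background would make the a* channel blind to senescent plants
(a* ~ -1): the working assumption is that any assay for which a*-Otsu
segmentation succeeds must have had warm-vs-green contrast in the wells.

**What the simulator does not model,** and hence what passing tests do not
show about real data: leaf architecture and self-shadowing, illumination
gradients, optical blur, sensor-resolution mismatch between modalities,
rotation/scale in the thermal registration, germination variability, and
well-to-well spray non-uniformity. Round-trip recovery here demonstrates
the *analysis* is correct and unbiased, not that the segmentation would
survive arbitrary field imagery.

## Segmentation

White balance is grey-world restricted to background (non-well) pixels.
The a* channel of CIE L\*a\*b\* (D65) is thresholded by Otsu's criterion
computed over a 256-bin histogram of the sample range with exact
class means and smallest-bin tie-break; plants are the low-a* class.
The threshold is computed **per well** rather than per plate: on plates
mixing healthy (a* ~ -28) and necrotic (a* ~ -6) wells against the warm
medium (~ +9) the pooled sample is trimodal and a single plate-level Otsu
splits green-vs-rest, silently losing dead wells (verified on simulated
late-timepoint plates; `threshold_scope="plate"` remains available). A
well whose a* sample is not convincingly bimodal -- Otsu effectiveness
(between-class over total variance) below 0.8, against ~0.64 for pure
Gaussian noise -- is declared plant-free instead of thresholding noise.
Components under 5 px are dropped; wells under `min_pixels` (default 50)
are flagged empty rather than measured.

## Measurement conventions

- RGB indices are computed per pixel and averaged per well (on the
  simulator's homogeneous blobs this agrees with index-of-mean within 1%,
  asserted as a regression property). CF parameters are computed from
  well-mean F values, matching the assay's average-then-ratio description.
- The control reference (NDI_0, CF means, T_0) is the mean over control
  wells on the same plate at the same timepoint. Plates without control
  wells get raw values plus a warning, no normalization.
- CF means violating F0 <= Fs <= Fm are flagged (`qc_ordering_violation`),
  never clipped.
- Thermal registration is an exhaustive integer-translation search (FFT
  cross-correlation of the binarized leaf map against the plant mask)
  within +-10% of the image size; it recovers simulator offsets exactly
  and fails loudly on frames without leaf contrast.

## Statistics

- **ANOVA**: fixed-effects two-way (herbicide x time) with interaction on
  a balanced complete design, fitted by OLS; on balanced data type-2 sums
  of squares coincide with the classical cell-means decomposition, which
  the tests verify against a hand-computed oracle to 1e-8. Unbalanced
  input is an error by design (the assay is balanced); the pipeline keeps
  the factorial balanced by taking the control group's replicates from
  the first plate only (the other plates' controls serve as their own
  plates' normalization references).
- **PCA** is correlation-based: columns standardized (ddof = 1), scores
  and loadings from SVD, eigenvalues equal to those of the sample
  correlation matrix (tested against an explicit eigendecomposition).
  Constant columns are dropped with a warning. Sign convention: each
  component's largest-magnitude loading is positive.
- **Separation score** (the quantitative stand-in for "visibly separate
  cluster"): for groups g, h with centroids c_g, c_h in the first two
  component dimensions, score(g) = min over h of ||c_g - c_h|| divided by
  the pair's pooled within-group RMS distance; a group is *separated*
  when its score exceeds 2.0. Identically distributed groups stay below
  the threshold in >= 95% of null simulations; the threshold and the
  number of retained components (2, optionally 3) are exposed in config.
- p-values are reported to machine precision; "< 0.0001" is a display
  convention of the reference tables, not a computed quantity.

## Determinism

Every stochastic step takes an explicit seed; one run seed fans out to
per-(plate, timepoint, stage) seeds through `numpy.random.SeedSequence`
spawn keys, so identical config + seed reproduces measurement CSVs
byte-for-byte while any single stage can be re-run in isolation.

## Known limitations

- The per-well Otsu scope, the warm-medium palette, the -2 C leaf offset
  and the CF reference triple are modelling commitments documented above;
  real plates may need recalibration of all four.
- PhiPSII is implemented exactly as the assay defines it, (Fs - F0)/Fs.
  It is not the light-adapted PSII operating efficiency, and its
  algebraic dependence on the other two parameters (given two fluorescence
  ratios) means the three CF parameters carry two, not three, independent
  dimensions in the PCA.
- Thermal/RGB resolution mismatch and non-translational misalignment are
  out of scope; the registration model matches the simulator's.
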