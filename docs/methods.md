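# Methods

This note documents the models implemented in `stdifftcv`, the numerical
choices behind them, the synthetic data they are validated on, and the
limits of what that validation shows.

## Intensity standardization

PDE-based stages are sensitive to intensity-range drift between frames, and
the delineation stage needs one intensity threshold that is meaningful for
the whole sequence. The standardization stage therefore matches each
three-frame window's histogram to a global reference:

* **Training.** All frames are pooled into a 256-bin histogram over
  [G_Min, G_Max] (the global extrema). The reference intensity `I_ref`
  marks the tail of the background distribution; its pooled cumulative
  probability `F_ref = F_AF(I_ref)` is stored. The package defaults to the
  intensity at the 0.8 quantile of the pooled histogram (`iref_quantile`),
  with an explicit `iref_value` override — a reproducible stand-in for a
  manually chosen background threshold.
* **Testing.** Per window, `I_test = argmin_I |F_3F(I) - F_ref|` over bin
  centers (ties to the smallest intensity). The CDF is evaluated at mid-bin
  mass so a point-mass bin where the CDF crosses `F_ref` is matched exactly
  instead of tying with every other bin. The window is then mapped by
  `T1(I) = (I_ref - G_Min)/(I_test - L_Min) * (I - G_Min) + G_Min` followed
  by the fixed rescale `T2` onto [0, 255], and clipped. Output stays
  floating point; downstream PDEs need fractional intensities.

`L_Min` is the window minimum by default (`lmin_mode: window`), or `G_Min`
(`lmin_mode: global`). With `L_Min = G_Min`, `T1` maps `I_test` exactly onto
`I_ref`, so the standardized fraction of window pixels at or below
`T2(I_ref)` reproduces `F_ref` to within one histogram bin of probability
mass; in the general window mode the mapping is approximate in the same way
the defining transform is. The window-independent value `T2(I_ref)`
(`StandardizationModel.threshold_255`) is the "standardized reference value"
used by the delineation threshold rule.

Degenerate windows (constant intensity, or `I_test = L_Min`) are rejected
with an error rather than producing an unbounded slope.

## Spatio-temporal diffusion

Given a standardized window {t-1, t, t+1}, three coupled nonlinear
diffusion equations are advanced jointly with explicit finite differences.
Per iteration, each frame receives a 4-neighbor spatial flux in which the
difference toward each neighbor is weighted by the diffusivity of the
gradient magnitude at the paired shifted position (N with (i+1,j), S with
(i-1,j), E with (i,j+1), W with (i,j-1)); the center frame additionally
receives `lambda_t * (w_PF*PF + w_NF*NF)` with `PF = I(t-1) - I(t)`,
`NF = I(t+1) - I(t)`, and the neighbor frames receive `-2*lambda_t*w*PF`
(resp. `NF`). Gradient magnitudes are central differences with replicate
padding; spatial boundaries are replicate-padded (zero normal gradient); at
the sequence ends the missing temporal neighbor is the center frame itself,
the temporal analogue of the zero-gradient condition.

The temporal weights `w_PF, w_NF` default to `g(|PF|), g(|NF|)`
(`temporal_term: diffusivity_weighted`): the temporal flux is throttled at
large frame differences exactly as the spatial flux is throttled at edges,
which is the only reading under which temporal discontinuities (moving
cells) are *preserved* rather than erased. The alternate literal reading —
weighting by the neighbor frame's spatial gradient magnitude — is available
as `temporal_term: literal_gradmag`.

Parameters (config keys in `diffusion:`):

| key | default | meaning |
|---|---|---|
| `lambda_s` | 0.2 | spatial step; the explicit 4-neighbor scheme needs <= 0.25 |
| `ts_ratio` | 1.0 | temporal-to-spatial ratio; `lambda_t = ts_ratio*lambda_s` |
| `k` | 15 | conductance on the standardized 0-255 scale: gradients below ~k are treated as noise and diffused, above ~k as edges and preserved |
| `n_iters` | 10 | scale steps |
| `g_form` | rational | `1/(1+x^2/k^2)`, the region-favoring diffusivity; `exponential` available |

Properties verified by the test suite: constant windows are exact fixed
points; per-iteration max/min obey a discrete extremum principle on random
data; with `g ~ 1` and `ts_ratio = 0` the scheme reproduces a Gaussian blur
of total scale `sqrt(2*n_iters*lambda_s)` (correlation > 0.999 on a
structured frame — on pure white noise the discrete and continuum heat
kernels genuinely differ at unresolvable frequencies, so that comparison is
made on a frame with spatial structure); a one-step literal transcription
of the update equations matches to 1e-12.

Negative undershoots (possible at machine precision) are clamped to zero,
since frames are intensities.

## Parzen edge-occurrence map

Region interiors have unimodal local intensity distributions; windows
straddling an edge are bimodal, and their mean falls into the density
valley. For every pixel, the Gaussian-kernel Parzen estimate
`f_h` of the surrounding `parzen_window` x `parzen_window` intensities
(replicate-padded; default 7) is evaluated at the window mean, and the edge
index is `1 - f_h(mean)/max_frame(f_h(mean))`. The bandwidth `parzen_h`
(default 8 on the 0-255 scale) controls bimodality resolution: too small is
noise-ragged, too large merges the modes — the test suite asserts both
regimes on a two-cluster sample. The index is computed on the diffused
center frame (one edge map per frame). It is invariant to adding a constant
to the frame and lies in [0, 1] by construction.

## Watershed delineation and classification

The edge map is a topographic relief (homogeneous areas = valleys, edges =
ridges) and is flooded from its regional minima with 8-connectivity. The
delineation operation itself floods all regional minima (`h_minima = 0`);
the pipeline defaults to suppressing minima shallower than `h_minima = 0.2`
first, because on noisy sequences the raw map has hundreds of noise-depth
minima that over-segment the background into cell-sized fragments whose
means are biased by blob halos — depth suppression is the standard watershed
practice for this.

Each basin is classified by one of two rules:

* **Threshold rule** (`use_likelihoods: false`): cell iff mean standardized
  intensity > `T(I_ref)`. Fully determined by the standardization model,
  but blind to cells darker than the background.
* **Gaussian MAP rule** (default): the basin's (area, mean intensity) is
  scored under Gaussian class models `p(area|c)*p(I|c)*prior(c)`. The cell
  class uses configurable Gaussians (defaults: area 350±250 px, intensity
  170±80 — nucleus-sized objects on 128x128 standardized frames). The
  background class models a *fragment of the background partition*: its
  area Gaussian is anchored at zero with a broad sd (fragments come in all
  sizes), and its intensity model is the sampling distribution of a
  fragment mean — pixel sd shrunk by sqrt(area), floored at a quarter of
  the pixel sd to absorb systematic variation. Priors default to
  (0.9, 0.1): most basins are background. Background pixel statistics are
  estimated per frame from the dominant (largest) basin
  (`estimate_background`, default on), since standardization rescales each
  sequence's background differently.

The MAP rule recognizes cells whose mean deviates from the background in
*either* direction, which is what makes absorption (darker-than-background)
cells detectable once the motion path has delineated them; the published
description states both a threshold rule and a Gaussian-likelihood
classification without reconciling them, and only the MAP reading supports
that capability, so the MAP rule decides when likelihoods are enabled
rather than acting as an extra filter on top of the threshold.

Adjacent cell basins (8-connectivity) merge into one instance; "coherent
motion" between adjacent regions is not formalized beyond adjacency plus
both-cell classification. Merging can only reduce the instance count.

## Chan-Vese level sets with temporal linking

The two-phase piecewise-constant energy is minimized with the regularized
Heaviside `H_eps(z) = (1 + (2/pi)arctan(z/eps))/2` and
`delta_eps(z) = eps/(pi(eps^2+z^2))` (`eps = 1`). Numerical scheme:

* the curvature term `div(grad phi/|grad phi|)` is discretized with
  half-point fluxes and treated semi-implicitly in the center value (the
  original Chan-Vese scheme), which is unconditionally stable — an explicit
  curvature step proved prone to both instability and noise-splitting local
  minima;
* `c1, c2` in the descent are the mean intensities inside/outside the
  contour ({phi >= 0} / {phi < 0}), recomputed every iteration;
* `cv_energy` reports the fully H_eps-regularized functional (H-weighted
  memberships and means). Its trace along the descent is nonincreasing on
  the clean fixtures; on a perfectly matched two-valued image the fitting
  terms vanish in the |phi| -> infinity limit;
* intensities are internally rescaled to unit range (and `mu`, `nu` by the
  square); the energy and weights are homogeneous in intensity^2, so this
  is an exact reparameterization. Weights are expressed on the 0-255
  standardized scale: defaults `mu = 0.2*255^2`, `nu = 0`,
  `lambda1 = lambda2 = 1`, `dt = 0.5`.

Convergence (`i_final`) is declared when the relative energy change stays
below `tol = 1e-6` for 5 consecutive iterations *or* the zero level set has
not moved for 50 consecutive iterations, capped at `max_iter = 800`. The
energy decays like a slow power law while phi saturates away from the
contour, so an energy-only rule either fires too early (loose tol) or never
(tight tol); contour stability is the segmentation-relevant notion. A
sustained rise of more than 1e-3 relative per step for over 20 iterations
raises a divergence error (transient ~1e-4 rises occur legitimately while
contours merge).

Temporal linking passes frame n's converged field to frame n+1 bit-exactly
in `tcv_sequence`. The pipeline methods additionally redistance the carried
field (clipped signed distance, +-1 band) at each handoff
(`reinit_on_handoff`, default on): the zero level set — the substance of
the temporal link — is preserved exactly, while undoing phi's saturation so
the warm-started contour can track moving cells; without it the carried
contour progressively lags a cell moving ~2 px/frame. Mask-to-phi handoffs
(from ST-Diff seeds) use the same clipped signed distance: smooth across
the contour (keeping the descent's energy trace monotone) yet mobile far
from it, so new objects can still nucleate.

Cold starts (plain CV, first TCV frame) use the checkerboard-of-circles
field `sin(pi*y/5)*sin(pi*x/5)`. Because the energy is symmetric under
phase exchange when `lambda1 = lambda2`, cold-started runs orient the
*brighter* phase as cell afterwards (the fluorescence convention); the
ST-Diff-TCV refinement deliberately does not re-orient, since the ST-Diff
seed already fixes which phase is cell — required for absorption cells.

## Pipeline

`STDIFF` runs standardize -> diffuse -> edge map -> watershed -> classify
per frame. `STDIFF_TCV` re-initializes phi from the ST-Diff mask on every
frame index divisible by `k_modulo` (default 5 — small enough to catch
mitoses and entering cells within a few frames, large enough to keep the
motion stage off most frames) and refines every frame with the Chan-Vese
descent on the standardized center frame (so the fixed weight scale
applies). Identical input and configuration give bit-identical masks; all
stages are deterministic.

## Synthetic sequences

The simulator emulates fluorescently labeled nuclei migrating on a 2D
surface. Cells are smoothed flat-top ellipses — an ellipse indicator
convolved with a Gaussian PSF (`psf_sigma`, default 2 px) — rather than
pure Gaussian intensity profiles: real nuclei have finite extent with a
blurred boundary, and for this profile the half-maximum contour (the
ground-truth mask) coincides with the steepest-gradient contour that
gradient-localizing stages (watershed, Chan-Vese at the intensity midpoint)
find. For a pure Gaussian profile those two contours disagree by a fixed
geometric factor (~0.85), which would put a ~0.84 ceiling on achievable
Dice for *any* correct edge-localizing method — a property of the profile,
not of the segmentation.

Ground-truth masks label each pixel by the cell whose noiseless
contribution exceeds half its own amplitude (in magnitude, so absorption
cells with negative amplitude work identically). Mitosis events replace a
cell by two diverging daughters from the event frame; entries/exits are
expressed through initial centers and velocities. Noise is additive
Gaussian by default (Poisson available); frames are clipped at zero.

`target_snr_db` rescales the *signal amplitude* so the measured
`SNR = 20 log10(mean_cell/mean_background)` hits the target: zero-mean
noise does not move a ratio of means, so SNR targeting cannot work through
the noise level; the noise sd remains the separate knob that drives CNR.

Standard fixtures (the study conditions used throughout the tests and the
acceptance script):

* `clean_two_blob` — two well-separated bright nuclei (amplitudes 180/170
  over background 20, radii 10-13 px, ~2 px/frame, noise sd 3, seed 42),
  measured SNR ~18 dB. The "easy" condition: all four methods should be
  accurate, with the joint method on top.
* `dim_mover` — a single absorption cell (amplitude -30 on background 40,
  ~4 px/frame, seed 7): mean intensity *below* the background level.
  Bright-phase region competition structurally assigns it to background
  (plain CV recall 0); the motion path detects it and the
  {dark cell}-vs-{background} two-phase refinement is stable.
* `crowded` — 12 touching nuclei (seed 11); exercises instance merging.
* `mitosis` — one division at frame 5 (seed 5); the ground-truth instance
  count rises from 2 to 3.

What passing on these fixtures does *not* show: performance on real
microscopy (uneven illumination, structured noise, photobleaching, PSF
anisotropy, densely packed tissue are not simulated), robustness of the
"experimentally determined" parameters across imaging conditions, or
instance-level separation of touching cells (binary Dice is the reported
measure; the crowded fixture's touching cells merge into one instance).

## Validation measures

Binary per-frame Dice `2|A∩B|/(|A|+|B|)` (both-empty defined as 1),
`SNR = 20 log10(mean_cell/mean_bg)` in dB, and
`CNR = |mean_cell - mean_bg|/sd_bg` with the population (divide-by-N)
standard deviation. Sequence summaries are mean ± sd over frames.

## Known limitations

* Two-phase model: a frame containing *both* bright and
  darker-than-background cells cannot be represented by one Chan-Vese
  foreground; such cells survive only as long as the ST-Diff re-seeding
  outweighs region-competition eviction. Multiphase formulations are out of
  scope.
* The watershed merge criterion is adjacency only; genuinely touching cells
  of similar intensity merge into one instance.
* Parameters (`k`, `parzen_h`, `mu`, `h_minima`, `k_modulo`) are
  per-dataset choices, as in any diffusion/level-set pipeline; the defaults
  are tuned to the standard fixtures' scale (128x128, nucleus radii ~10 px,
  standardized 0-255 intensities).
* No cell tracking or identity linking across frames; masks are
  per-frame instances.
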