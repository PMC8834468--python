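# Methods

## The problem

During a fruit-wine fermentation, ethanol rises as yeast consumes sugars
(total soluble solids, TSS), while the organic acids — total acidity (TA, as
citric acid) and total volatile acids (TVA, as acetic acid) — creep upward
at two to four orders of magnitude lower concentration.  FT-NIR spectroscopy
with a liquid probe can monitor all four simultaneously, but the NIR
overtone/combination bands of ethanol, sugars and acids overlap heavily, and
much of the 11,536–3,952 cm⁻¹ axis carries no analyte information at all.
Multivariate calibration on the whole axis therefore drags hundreds of noise
channels into the model.  This package implements the two-stage
wavelength-selection workflow that addresses this, plus everything needed to
run and validate it at desk scale.

## Pipeline

1. **Axis handling.** Spectra live on a uniform descending wavenumber grid
   (default 11,536–3,952 cm⁻¹ at 8 cm⁻¹, 949 channels).  The saturated water
   combination band at 5,248–4,984 cm⁻¹ — beyond the detector's linear range
   — is excluded first, splitting the axis into contiguous segments of 786
   and 129 channels.  All later windowed operations are confined to one
   segment; nothing ever bridges the gap.

2. **Pretreatment.** Savitzky–Golay second derivative (polynomial order 2,
   window 7 points) per segment, which removes baseline offset and slope
   from light scattering and sharpens overlapping bands.  The edge policy is
   *trim*: each segment loses (7−1)/2 = 3 channels per end rather than
   carrying extrapolated edge values, leaving 780 + 123 = 903 channels.
   The derivative is taken with respect to channel index (no 1/Δν² factor):
   after mean-centering, PLS predictions are invariant to one global
   positive rescaling of X, so the convention cannot change any result.

3. **PLS-1 engine.** Deterministic NIPALS for a single response.  Each
   factor's weight vector has the closed form w = Xᵀr/‖Xᵀr‖, so there is no
   iterative inner loop and no random initialization; X is deflated after
   each factor, and fits are reproducible bit-for-bit.  Centering is
   recomputed inside *every* fit — every moving-window fit and every
   cross-validation fold — and no variance scaling is applied anywhere.
   A batched variant runs thousands of window fits as stacked matrix
   operations; it is numerically identical to the per-window path (tested
   against it) and exists purely for speed.

4. **MWPLSR (step 1).** A 20-channel window slides across every segment; at
   each position PLS-1 models with 1..10 latent variables (LVs) are fitted
   and log₁₀ of the sum of squared calibration residues (SSR) is recorded.
   Log base 10 is used so typical SSR values of a few hundred read as ≈2.3
   on the residue plot.  Valleys of these residue lines mark informative
   regions.  Detection is automated: window positions whose log₁₀(SSR) at
   the 3-LV line falls below the 15% quantile of that line, in runs of at
   least 3 positions, are unioned (window extent included) into candidate
   regions; runs never cross a segment gap.  A manual mode accepts
   user-specified regions verbatim for reproducing hand-read residue plots.

5. **SCMWPLS (step 2).** Inside the first informative region every
   sub-interval (all widths w = 1..p, all positions) is fitted and the one
   with the smallest RMSEC becomes the *base region*.  Each further region
   then offers all its sub-intervals plus the empty interval; the best
   combination (base ∪ candidate) becomes the new base.  Key numerical
   choices:
   * **LV cap.** The dimensionality of every candidate fit is
     min(cap, width, n−1), where the cap is the smallest k at which one more
     LV improves RMSEC by less than 2% relative ("decreases
     insignificantly").  In the combination step the cap is estimated from
     the *current base region*: estimating it on base+candidate would let a
     fresh LV justify itself purely by fitting appended noise.
   * **Meaningful improvement.** A candidate is adopted only if it lowers
     RMSEC by at least 2% relative (configurable, default equal to the LV
     rule's threshold).  Appending channels to a base almost always shaves a
     chance-level sliver off the in-sample error — roughly w/2n relative,
     amplified by best-of-many selection — and accepting such slivers would
     make it impossible for the procedure ever to discard a region, which it
     demonstrably must be able to do (a selection run can end with a single
     region out of four proposed).
   * **Tie-break** (RMSEC equal within 10⁻¹²): fewer channels first, then
     higher starting wavenumber — parsimonious and deterministic.
   * **Order.** Regions are processed high-to-low wavenumber by default; an
     alternative policy processes them by ascending individual RMSEC, which
     is preferable when region quality varies wildly.
   * **Search-cost controls** (w_min, w_max, stride) default to the
     exhaustive enumeration; restricting them logs a warning that the result
     is an approximation.

6. **Final calibration and validation.** The final model's LV count is
   re-selected by full (leave-one-out) cross-validation: the chosen k is the
   one minimizing RMSECV among those where the curve rises at k+1, falling
   back to the global argmin (with a warning) when the curve is still
   falling at k_max.  Ties go to the smallest k.  Validation on the
   independent test batch reports R², RMSEC/RMSEP, SEP, bias, RPD and the
   ISO-12099-style confidence limits:
   * T_b = t₁₋α/₂,ₙ₋₁ · SEP/√n (two-sided, α = 0.05),
   * T_UE = SEC · √F_α(ν, M) with ν = n_p − 1 and M = n_c − LVs − 1
     (one-sided, α = 0.05).
   The square root on the F quantile follows ISO 12099 practice; renderings
   that drop the radical produce limits in the wrong units (error²·scale).
   A model is accepted when SEP < T_UE and |bias| < T_b (strict; the
   degenerate perfect fit with error and limit both exactly zero is
   accepted).  **n for the confidence limits is caller-supplied**: when
   triplicate subsamples share one sampling event, the defensible count is
   the number of independent events (33 for the default test batch of 99
   spectra), and that is the pipeline default when sample metadata is
   present; otherwise the number of test predictions is used.

## Synthetic fermentation generator

No public spectra exist for this kind of study, so the generator produces
the full two-batch-calibration / one-batch-test design (11 days × 3
samplings × 3 subsamples = 99 spectra per batch; 198 calibration + 99 test)
with known ground truth.

* **Kinetics.** A daily table of mean concentrations (ethanol 0.06→10.76%,
  TSS 23.70→10.25 °Brix, TA 0.29→0.46%, TVA 1.30→1.80·10⁻³%) interpolated
  linearly in time; a logistic parametric mode is available.  Sampling
  events sit at day·24 + {0, 3, 6} h (three samplings, then an 18 h
  overnight gap); the final-day value is held constant for events up to 24 h
  past the last tabulated day, since the fermentation has plateaued.
  Batch-to-batch variation is a per-analyte multiplicative factor
  (σ = 2%).  Per-sample reference-method noise (GC / refractometer /
  titration) has σ 0.30%, 0.15 °Brix, 0.012%, 8·10⁻⁵% for
  ethanol/TSS/TA/TVA — chosen so each analyte's attainable prediction
  quality is on the scale such reference methods actually deliver: ethanol
  and TSS well determined, the trace acids near their measurement floor.
* **Spectra.** Beer–Lambert mixture of per-component Gaussian bands, with
  widths set so each band group's ±2σ support tiles its assignment window:
  ethanol at 8,404 (C–H 2nd overtone), 6,800 (O–H 1st overtone),
  5,900/5,750/5,600 (C–H 1st overtones) and 4,450/4,340 cm⁻¹
  (combinations); sugars at 7,000, 6,400, 5,610, 4,400/4,300; the acids as
  weak features overlapping the majors (which is exactly what makes the
  acid calibrations hard at <0.5% and <0.002%); water with its strong 6,900
  band and the saturating ≈5,150 combination band.  On top: baseline offset
  (σ 0.01) and slope (σ 2·10⁻⁵/channel), multiplicative scatter (σ 1%),
  additive detector noise (σ 3·10⁻⁴ absorbance), and hard clipping at 2.5
  absorbance inside 5,248–4,984 cm⁻¹.
* **Detector roll-off.** The additive noise σ rises smoothly tenfold above
  ≈9,800 cm⁻¹, emulating the third-overtone region where detector response
  fades — the region that shows uniformly high residue lines and is
  discarded by selection in practice.  Without this heteroscedasticity a
  whole-region model ties the selected-region model and wavelength
  selection has nothing to buy.
* **Ground truth.** Per analyte, the union of its component's band supports
  (center ± 2σ, snapped to the grid) — the reference answer for
  planted-region recovery checks.

What the generator does *not* emulate: CO₂ bubble artifacts and particle
scattering at the probe slit, instrument drift between batches, nonlinear
detector response outside the clipped band, and the two-directional sugar
chemistry (invertase splitting sucrose while glucose is consumed).  Passing
recovery tests on this generator therefore shows the selection machinery
works when bands are where the assignment table says they are — not that it
would survive every artifact of a real probe in a fermenting tank.

## Problem sizes and determinism

Default study size is the full design (198 calibration spectra × 903
pretreated channels); the exhaustive sub-window searches run in seconds
because window fits are batched.  Recovery properties are asserted over 20
independent study replicates.  All randomness flows from one integer seed
through a splittable generator (one child stream per batch); identical seeds
give bit-identical datasets, and the PLS engine itself has no stochastic
component.

## Known limitations

* The greedy combination is order-dependent; neither processing order is
  guaranteed globally optimal (the exhaustive joint search over all region
  combinations is exponential).
* The 2% thresholds (LV cap, meaningful improvement) are heuristics for
  "insignificant"; both are exposed in configuration.
* With realistic fermentation kinetics, ethanol and TSS are almost
  perfectly anti-correlated within a batch, so either analyte's model may
  legitimately borrow the other's bands; recovery metrics for one analyte
  count shared windows as correct only where band supports overlap.
* T_UE's degrees of freedom follow the definitions above; published tables
  elsewhere are not always reproducible from their own printed SEC/SEP
  values, so small discrepancies against external sources are expected.
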