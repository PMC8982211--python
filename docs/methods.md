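# Methods

## Acquisition geometry and masking

The scan model is parameterized by the excitation range/step, the emission
grid (floor, stop, step) and two scatter-avoidance rules: for excitations
at or above `ex_cutoff` (290 nm) emission starts at λex + `scatter_offset`
(20 nm); below the cutoff it starts at the emission floor (300 nm).  All
wavelengths are integer nm and every bound must sit on its grid; geometry
construction validates this eagerly so downstream code never sees a
half-valid scan.  The default geometry yields 26 excitation wavelengths,
71 emission grid points and 1340 valid cells (506 scatter-masked).

Masked cells are stored as NaN, never as zero: an accidental read of a
masked cell fails loudly (unfolding raises a data-integrity error naming
the offending λex/λem) instead of silently biasing a model.  The canonical
unfolding order is ascending λex then ascending λem.  Instruments often
scan in descending excitation order; the vector permutation is immaterial
to any bilinear model, so the reproducible order wins.  `refold` inverts
`unfold` exactly on valid cells.

Difference spectra subtract the *mean* control EEM (not an arbitrary
replicate) — the stable choice when the control itself is replicated —
and are flagged so that negative intensities are accepted only there.
Region summaries use inclusive rectangle bounds on the 5/10 nm grids;
the three default regions are the UV-responsive windows of the difference
landscapes: λex 250–300/λem 300–420 nm (aromatic amino acids + DNA,
decreasing), λex 300–340/λem 360–460 nm and λex 340–430/λem 420–480 nm
(coenzymes/vitamins, increasing).

## Synthetic data generator

The generator emulates a UV-stress experiment on adherent melanoma cells
in a 96-well plate, not a specific instrument.  Its defaults *are* the
study conditions: doses {0, 10, 20, 40, 50, 60} min, 12 EEM replicates
per dose (72 spectra), 6 MTT replicates per dose (the plate design allows
3–9; a uniform 6 is used because the actual per-dose allocation is not
recoverable), MTT replicate SD 5% viability.

**Dose–response.** v(t) = v_min + (100 − v_min)/(1 + (t/t50)^h) with
v_min = 15%, t50 = 20 min, h = 4: viability ≈ 50–60% at 20 min and below
25% from 40 min on, matching the qualitative kill curve the design
assumes.  The Hill form is a modelling choice; only the monotone shape
and those anchor points are constrained.

**Spectra.** Six separable Gaussian bands at the control-cell fluorescence
maxima (290/340, 360/440, 390/500, 390/590, 430/520, 430/590 nm;
σ_ex = 20 nm, σ_em = 25 nm — wide enough to span the named regions,
narrow enough to keep them distinct).  Band amplitude responds linearly
to lost viability, A(v) = A₁₀₀·(1 + κ·(100 − v)/100) floored at 0, with
κ = −0.4 for the amino-acid band, +0.6 for the 360/440 and 430/520 bands
and 0 for the rest — encoding "region 1 decreases, regions 2–3 increase,
some channels are uninformative".  Linear amplitude response is the
simplest mechanism consistent with monotone difference spectra and makes
successful PLS recovery an analytic expectation rather than luck.

**Replicate structure.** Two noise levels are deliberately separated:

* *well-to-well biology* (`bio_sd`, default 5% viability, clipped to
  [0, 100]): each EEM well draws its own viability around the dose value.
  Without this term the within-dose spread of soft-sensor predictions
  would be set by instrument noise alone — orders of magnitude below the
  MTT replicate spread — and no per-dose precision (F-test) comparison
  between the methods could ever be meaningful.  Real plates show
  comparable SDs for both methods, which is exactly what this term
  produces.  It equals the MTT SD by default because both assays observe
  wells with the same biology.
* *instrument noise*: multiplicative (σ_rel = 1%) plus additive
  (σ_add = 0.5 AU ≈ 0.5% of the strongest band), Gaussian per cell,
  intensities clipped at 0.

The clipping of well viabilities at 100% produces a ceiling effect at
dose 0: control-well EEM predictions scatter less than MTT replicates,
which the per-dose F-test can detect.  This is a property of the modelled
biology (controls saturate), not an artifact.

**Medium modes.** `off` (default) models the medium-exchange protocol: the
fresh-medium contribution is constant across samples and is omitted
(a constant background is removed by autoscaling anyway).  `confound`
adds a medium-photodegradation signal scaling linearly with dose — one
photobleached band (280/350 nm, −15 AU at the reference dose) and two
photoproduct bands (320/410 and 385/450 nm, +25 AU) sitting in the same
three windows as the cellular response.  The magnitudes are free
parameters chosen so the confound rivals the cellular signal; the mode is
phenomenological (no photochemical kinetics) and exists to demonstrate
the mis-correlation hazard: with all κ = 0 the pipeline still reaches
apparent train R² ≥ 0.99 against dose-correlated targets, and the run
report carries a `confounded` label.

What the generator does **not** emulate: inner-filter effects, day/plate
batch effects, spatial well gradients, non-Gaussian band shapes, drift.
Passing tests therefore demonstrate correctness of the calibration and
statistics machinery under the assumed signal model, not robustness to
every artifact of real plate data.

## Calibration

* **Response**: each EEM sample's y is the *dose-level mean* MTT viability
  (the reference assay only yields dose-level means ± SD); a per-replicate
  pairing is available but heuristic, since MTT and EEM wells are
  physically distinct.
* **Split**: uniformly random, |train| = round(0.75·n) (54/18 for n = 72),
  from a named seeded generator recorded in the model artifact.
* **Autoscaling**: per-column mean/SD (n−1), fitted on training rows only.
  Zero-variance columns are kept but scaled to 0 (with a warning) so
  column indices stay aligned with the wavelength map.
* **NIPALS PLS1**: w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt,
  deflation of both X and y; regression vector W(PᵀW)⁻¹q.  If the residual
  covariance norm falls below 1e−12 the loop stops early with a warning
  and returns the components found.  With n_lv = rank(X) the coefficient
  equals the normal-equations least-squares solution — used as an oracle
  test, with scikit-learn's PLSRegression as a second, independent
  cross-check.
* **Cross-validation**: venetian blinds, fold k = {rows i : i mod s = k},
  default s = 10 splits of thickness 1 (the de-facto default of common
  chemometrics software; the number is configurable).  Scaling and
  response centering are refit inside every fold — leakage-free is the
  defensible default.  RMSECV is reported for LV counts 0..max_lv (0 =
  mean-only model, whose RMSECV is the pooled retained-mean error);
  max_lv defaults to min(15, n_train − s).  The chosen count is the
  argmin, smallest count on ties (parsimony).
* **Diagnostics**: OLS of predicted on reference; R² = 1 − SSres/SStot;
  SEs from residual variance; 95% CIs via t(0.975, n−2).  Because the
  ambiguity cannot be resolved from the design alone, test-set
  diagnostics are emitted both per-sample and per-dose-mean.

## Accordance statistics

* t-test: pooled (Student's) two-sided by default — consistent with
  running a separate F-test for variance equality — with Welch selectable;
  the report records the variant.
* F-test: F = s₁²/s₂², two-sided p = 2·min(P(F ≤ f), P(F ≥ f)) capped
  at 1.
* α = 0.05 by default, configurable.
* Discrimination matrices report raw per-pair p-values by default
  (mirroring standard practice for these tables); Holm/Bonferroni
  adjustments are available but off.
* "Indistinguishable groups" are reported as connected components of the
  non-significant-pair graph and labeled heuristic: statistical
  indistinguishability is not transitive.
* Identity-line correlation uses the per-dose means of each method
  (6 points under the default design) and flags whether the 95% CIs of
  slope and intercept contain 1 and 0.

Under the default synthetic conditions (seed 1) the dose–response tail is
nearly flat beyond 40 min (20.0 → 17.1 → 16.0% viability), so the
least-discriminated adjacent dose pair always falls among the high doses
— the same qualitative behavior as reference assays at saturating stress.

## Numerical and I/O choices

* Zero-variance tolerance 1e−12; NIPALS stop tolerance 1e−12; orthogonality
  and oracle assertions at 1e−8.
* All artifacts are plain text (CSV/JSON/YAML), UTF-8, period decimals,
  integer nm wavelengths.  Long-CSV intensities are written via `repr` and
  read with round-trip float parsing so a dataset survives a disk
  round-trip bit-exactly.
* Config files are flat key–value YAML with units in key names
  (`ex_step_nm`, `mtt_sd_pct`).  YAML 1.1 parses bare `off` as a boolean;
  the loader maps `false` back to `"off"` for `medium_mode`.
* The run manifest stores the config echo, package version, SHA-256 of
  every data artifact, and timestamps; identical (config, seed) reproduce
  identical artifact hashes (timestamps live only in the manifest).

## Problem sizes

The default end-to-end experiment (72 spectra × 1340 variables, 10-fold
venetian-blinds CV over up to 15 latent variables) runs in well under a
second; the oracle and closed-form test batteries use 100 random problems
each.  These sizes were chosen so the full suite exercises the complete
design of the emulated study rather than a scaled-down version.

## Known limitations

* The soft-sensor is validated only within the signal model of the
  generator; no claim is made about transfer across cell lines, stress
  factors or instruments.
* No scatter-correction algorithms are provided: the geometry avoids
  scatter at acquisition, so EEMs that *contain* scatter must be masked
  upstream.
* No N-PLS/PARAFAC decompositions; the method is unfold-then-PLS1 by
  construction.
* The blank-subtraction hook for medium-only wells defaults to raw
  spectra; whether reference data were blank-subtracted is generally
  protocol-specific.
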