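# Methods

This note states, precisely, what each stage of the qplexflow cascade
computes, which constants it uses, and where its assumptions end.

## Data model

A run consists of a plate template (well → role, compound, concentration,
cell count, timepoint, cell line; roles are `background`, `negative_control`
and `sample`) and a raw table of per-well, per-gene median fluorescence
intensity (MFI) and bead count. Wells are canonicalized to `A01`–`H12`. All
processing operates on the wells × genes MFI matrix; every removal is
recorded with its reason and emitted in a QC table, never silently.

## Bead-count filter

A per-well, per-gene MFI is the median over that bead region's individual
beads; with few beads the median is noisy. Entries with bead count strictly
below the threshold (default **37**) are set to missing and listed in
`qc_discarded.csv`. A missing HKG entry later removes the whole well (see
LOQ stage), a missing target-gene entry just drops that dose point.

The default of 37 comes from a bead-subsampling stability analysis, which the
package can reproduce on bead-level exports:

* For subsample sizes n ∈ {10, 20, 30, 40, 50} (defaults), draw 100
  subsamples without replacement per (gene, well) and compute the percent
  deviation of the subsample median from the full-set median,
  %dev = (median(sub) − median(full)) / median(full) · 100.
* Average |%dev| per gene and size, then fit a continuous hockey-stick
  (sloped segment meeting a flat plateau) per gene by exhaustive search of
  the breakpoint on a 0.1-bead grid with a linear least-squares solve at each
  candidate; ties take the smallest breakpoint. Curves with no measurable
  slope or spread are marked degenerate and excluded.
* The recommended threshold is the 95th percentile (linear interpolation) of
  the per-gene breakpoints.

Subsampling results are invariant to the stored order of the bead array
(arrays are sorted before seeded drawing).

## Background and LOQ

Per gene, background mean and sample SD (ddof = 1) are estimated from the
dedicated background wells (≥ 2 required; < 6 warns). The mean is subtracted
from every non-background well and negatives are clamped to 0. Background
values more than 3 SD from their mean are flagged in `qc_background.csv` but
not removed.

The limit of quantification is LOQ_k = mean + k·SD for k ∈ {3, 5, 10}; the
well-removal rule uses **k = 10**: a well is removed when any retained HKG's
*corrected* signal is strictly below k·SD (equivalent to raw < LOQ_k, robust
to the zero-clamp). Only HKGs can remove a well; a target gene below LOQ
keeps its well (its FC is simply near zero and is down-weighted later).

An optional linearity check regresses corrected HKG signal on cell count over
negative-control wells (≥ 3 distinct counts) and reports slope and R² to
reveal saturation of the assay.

## Normalization and fold change

Per well, the geometric mean of the retained HKGs' corrected signals is the
scale factor; relative expression = corrected / geometric mean; fold change
(FC) = relative expression / per-gene median of the negative-control wells.
The median negative-control FC of every gene is therefore exactly 1, and FC
is invariant to any per-well multiplicative effect.

HKG stability is judged on the FC scale: an HKG whose own FC leaves
**[0.8, 1.2]** in any sample well is unstable. Removal is iterative — the
worst offender (largest |log FC| excursion beyond the interval) is removed
and FC recomputed with the reduced set — because one drifting HKG distorts
the geometric mean and can push innocent HKGs outside the interval. A single
remaining HKG normalizes itself to FC ≡ 1, so the filter always terminates
with a nonempty set. In screening mode, wells of cytotoxicity-flagged
conditions are excluded from the stability judgment first, so compound
toxicity is not mistaken for HKG instability.

## Cytotoxicity

Per HKG, the cutoff is (1 − 0.70) × mean corrected negative-control signal.
A compound × dose condition (median over replicate wells) is flagged when at
least one HKG falls strictly below its cutoff; `dose_dependent` records
whether the flagged doses form an upper set of the compound's dose ladder.
The flag intentionally uses pre-normalization signals: HKG normalization
divides uniform suppression away, so the FC view cannot see it.

## Dose-response model and absolute AC50

Mean FC versus dose x is modelled with the three-parameter log-logistic

    E(y) = c + (d − c) / (1 + exp(b (log x − ẽ))),

with d fixed at 1 (the negative-control FC), b ≥ 1e−6, c ≥ 1e−6 (box
bounds), and f(0) = 1 by the limit convention. Model selection per gene ×
compound:

* If every FC lies inside [0.8, 1.2] the response is uninformative — an
  intercept-only (constant) fit is returned without attempting a sigmoid.
* Otherwise constant, 3PL and 1/FC²-weighted 3PL compete on AIC (Gaussian
  likelihood, σ² profiled out; weights treated as fixed variance ratios, so
  AIC values are comparable across the three candidates). Exact ties prefer
  the simpler model.

The 1/FC² weights encode multiplicative (constant-CV) noise, the empirically
sensible regime for fluorescence ratios; under such noise the weighted model
is the modal AIC choice.

Fitting is multi-start bounded Levenberg–Marquardt/TRF least squares: starts
span the log of every tested nonzero dose × b ∈ {0.5, 1, 2} × c at the
observed FC extremes; a coarse pass (ftol 1e−8) is followed by one tight
polish (ftol 1e−13) of the best start.

Potency is reported as the **absolute AC50** — the dose where the fitted
curve crosses FC 0.5 (decreasing, c < 1) or FC 1.5 (increasing, c > 1):

    log AC50 = ẽ + (1/b) · log((d − L) / (L − c)),    L ∈ {0.5, 1.5},

defined iff L lies strictly between the asymptotes (c < 0.5, resp. c > 1.5);
otherwise "level not reached" is reported. Unlike the relative AC50 exp(ẽ),
the absolute AC50 is stable when the far asymptote is poorly pinned down by
an incomplete dose range (verified in the test suite by truncating the top
doses).

SE(log10 AC50) comes from the delta method: gradient of log AC50 in
(b, c, ẽ) against the parameter covariance RSS_w/(n−3) · (JᵀJ)⁻¹. Estimates
with SE > **0.3** (a factor-of-2 uncertainty) or no usable covariance are
marked `~` (uncertain).

**Coverage caveat.** The delta-method SE is a first-order approximation on
top of a small-n nonlinear fit with a box-bounded c. In simulation (6-dose
series, 5 % multiplicative noise), nominal 95 % intervals on log10 AC50 cover
the truth in roughly 70–87 % of replicates depending on the regime (~84 %
typical) — the SE is best read as a ranking/flagging device, not an exact
confidence statement.

## Synthetic ground-truth generator

`make_truth` / `simulate_plate` emulate a 96-well screening run for
validation: deterministic layout (6 background, 6 negative-control wells,
then compounds with ascending doses, row-major), per-gene additive background
plus baseline × planted fold effect, multiplicative log-normal MFI noise
(exp(σ·N(0,1)), σ default 0.05), uniform bead counts, and optional planted
violations — low-bead entries, wells with an HKG pushed below LOQ₁₀, HKG FC
excursions, and cytotoxic compounds scaling every transcript past an onset
dose. Background wells carry a fixed standardized pattern so their sample
mean and SD reproduce the nominal values exactly; in the noise-free limit the
pipeline's FC equals the planted fold effect exactly. Regeneration is
byte-identical per seed.

The default problem shape (20 target genes + 2 HKGs, 10 compounds × 6
half-log doses, 72 annotated wells) is this package's own choice of a typical
screening plate; nothing in the pipeline depends on it.

What the generator does **not** emulate: bead-level fluorescence inside the
MFI wells (bead arrays are simulated separately by `simulate_beads`),
spatial/edge effects, carryover, plate-to-plate batch effects, saturation of
the reader, or correlated noise between genes. Conclusions about those
failure modes cannot be drawn from it.

## Numerical choices

* Sample SD everywhere (ddof = 1).
* Quantiles via linear interpolation (numpy default).
* Breakpoint grid 0.1 bead; AC50 in closed form (no root search); the test
  suite checks the closed form against bisection to 1e−8 relative.
* Raw CSVs are parsed with round-trip float precision, so files written by
  the generator reproduce the in-memory matrices bit for bit.
* σ̂² is floored at 1e−12 so AIC stays finite on noise-free data.

## Known limitations

* The AC50 SE undercovers (see caveat above); bootstrap or profile-likelihood
  intervals would be better but are out of scope.
* AIC with n = 6 points discriminates weakly between the weighted and
  unweighted 3PL; the reported model kind should not be over-interpreted.
* The cytotox flag needs the HKG baseline: compounds that induce HKGs while
  killing cells can mask their own toxicity.
* LOQ removal assumes the HKG panel is expressed well above background in
  healthy wells; panels near the LOQ will discard many wells (by design).
* One plate is processed at a time; cross-plate normalization is not
  implemented.
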