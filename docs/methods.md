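# Methods

This note documents the models, the synthetic study design, and the
numerical and design choices behind `wadem`, in the spirit of a package
vignette: what is assumed, what is tunable, and what passing tests do and do
not demonstrate.

## Hydrologic covariates

All covariates derive from a daily depth stack on a regular cell lattice
(0-based row-major indices, row 0 north; projected centers
`x = (col + 0.5)·cell_size`, `y = (nrows − row − 0.5)·cell_size`). Depth is
cm relative to ground; negative values (water table below ground) are
retained and "wet" means strictly `depth > 0`.

* **DSD** — consecutive wet days ending today, capped at 1095 days (three
  years). Days before the record start contribute nothing (left-censoring at
  zero): the only data-safe choice, but it biases DSD low in the record's
  first years; synthetic experiments that lean on DSD therefore use
  multi-year records.
* **Recession** — `(depth[t−14] − depth[t]) / 14`, positive while drying,
  undefined (NaN) for the first 14 days. The lag is configurable
  (`lag_days`); 14 days is the default throughout.
* **Hydroperiod** — `365 · (wet days) / (record days)` per cell,
  time-invariant over the record.
* **Reversal** — within a dry-season window (default Jan 1–Jun 30, the
  survey season; configurable) a cell is *reversed* once its depth has
  fallen strictly below the species' lower availability bound (the 10%
  depth-use quantile) and later risen back to at least that bound —
  re-entry into the closed availability band is what "rewetted" means here.
  The state resets at each season start, preventing multi-year carryover in
  what is conceptually a dry-season variable. The daily reversal fraction is
  reversed-and-available cells over available cells.

Missing single-cell single-day depths are rejected at read time rather than
imputed: the day-lag logic above must not silently bridge gaps.

## Availability and the daily landscape record

The availability window is the 10–90% quantile pair (linear interpolation)
of depths at a species' observation cell-days, one value per record,
unweighted by flock size — availability is defined by where birds forage,
not by how many forage there. A count-weighted variant exists behind a
flag. Cells are available when valid and inside the closed band.

Each species-day one record summarizes the landscape: availability means
and SDs of depth/recession/DSD over available cells, the available-cell
count ("cells"), the reversal fraction, and use means over
occupied-and-available cells (each occupied cell counted once), plus flock
(occupied cells) and individual (summed birds) counts. Observations outside
the window are excluded from use means but still inform the window
estimate. Use means are undefined on bird-free days; stage-2 models are
therefore fitted on days with at least one flock, which also keeps every
candidate on an identical case set.

## Mixed models

All fits are Gaussian linear mixed models,
`y = Xβ + Σ_b Z_b u_b + ε`, with one variance ratio per random block
(random intercept for month or region; penalized radial smoother). The
likelihood is profiled over β and σ² and maximized over log variance
ratios with L-BFGS-B from three fixed deterministic starts (ratios 10⁻⁴,
0.1, 1), tolerance 1e-12, bounds 10⁻¹⁰–10⁸ — fits are exactly reproducible.
Woodbury identities keep every evaluation O(q³) in the number of
random-effect columns. Design columns are internally rescaled to unit RMS
(an exact reparameterization) so raw-scale polynomial terms (DSD² reaches
10⁶) do not degrade the normal equations; coefficients are reported on the
original scale.

**ML vs REML.** Candidates compared by AICc differ in fixed effects, so
they are fitted by ML; REML likelihoods are not comparable across fixed
structures. REML remains available (and is what the balanced-ANOVA test
exercises) for variance estimation within a fixed mean structure.

**K for AICc** counts fixed coefficients (incl. intercept) + variance
components + the residual variance — the standard mixed-model convention.

**Smoother.** The low-rank thin-plate construction: basis `r² log r` to K
knots chosen by farthest-point traversal (seeded start, discarded),
distances scaled by the median inter-knot distance for conditioning,
columns post-multiplied by the inverse square root (eigenvalue-magnitude
form, since the kernel matrix is only conditionally positive definite) of
the knot-penalty matrix, coefficients treated as one exchangeable random
effect. Default K = min(50, cells/10), at least 3. The claim tested is not
equivalence with any particular black-box smoother but the property that
matters: the fitted surface captures smooth spatial trend and residual
Moran's I (rook adjacency, row-standardized, seeded permutation p)
collapses.

Degenerate variance components hit the ratio floor of 10⁻¹⁰; on null data
the smoother can therefore cost a few 10⁻⁷ of log-likelihood relative to
omitting it, which is the tolerance the monotonicity test uses.

## Candidate sets, retention, averaging

Term grammar: main effects, squares (`x^2`), products (`x*y`); marginality
is enforced (square or interaction requires its mains) with one deliberate
exception, the depth-selection interaction `depth_use*depth`, which the
model families include without a `depth_use` main effect. Ties in AICc
break on smaller K then lexicographic terms. Retention is strict
`ΔAICc < 4`; weights are renormalized over the retained set. A term's
averaged coefficient renormalizes again over its containing models; its
unconditional SE is `sqrt(Σ w̃ (se² + (β − β̄)²))`; its importance is the
summed retained weight of containing models. Reported R² is the squared
Pearson correlation of the response with retained-weight-averaged
predictions (each model predicts; predictions are averaged — coefficients
are never zero-filled into one design). The "N" column in reports is the
number of candidate models containing the term.

Exhaustive marginality-respecting enumeration of the full term universes
runs to thousands of models per response; the enumerator supports it
(`build_candidate_set` with `max_terms`), but the pipeline defaults use
curated explicit families of ~10–25 models per response spanning the same
term structure (mains, SDs, squares, resource interactions, the
depth-selection interaction, reversal). The abundance family deliberately
includes availability-depth terms alongside `dsd_use`: the area of suitable
habitat contracts as the landscape dries, which confounds raw DSD-use
effects on counted birds, and conditioning on availability depth is what
isolates the production signal (the same role the depth-availability terms
play in the published model families).

## The synthetic landscape

The generator is the study's data source, with every parameter recorded in
a ground-truth sidecar.

* **Hydrology.** A landscape-wide stage starts each year at the wet-season
  peak (50 cm over mean ground), declines at `dry_season_recession_mean`
  (0.4 cm/day) through June 30 with Poisson rain jumps (2 events/season,
  10 cm), and refills at twice the recession rate. Depth = stage −
  elevation + correlated daily noise (1 cm SD). Elevation is a Gaussian
  random field (white noise convolved with a Gaussian kernel; e-folding
  correlation distance equals the configured range, 4 cells) scaled to
  30 cm relief. These values give a 40×40 desk-scale landscape whose
  drying curve, depth range (−40 to 65 cm) and reversal behavior resemble
  a managed subtropical wetland's dry season.
* **Birds.** Occupancy, not movement: each wet cell's latent intensity is
  `exp(−(d−opt)²/2τ² + s·recession + g·dsd/(dsd+h))` — a Gaussian depth
  niche (egret 20±14 cm, ibis 13±11, stork 13±13), a log-linear drying
  preference, and a saturating production term (half-saturation 200 days).
  The day's expected occupied-cell count scales with landscape-mean
  production (`abundance_dsd_gain` = 0.6), occupancy is Bernoulli
  proportional to intensity, and counts are 1 + negative-binomial
  (dispersion 1, mean flock size 5) — conspecific clustering enters purely
  as count overdispersion. One whole-grid survey per day, evenly
  subsampled to 200 dry-season days with defined recession.

What the generator does **not** emulate: transect-based detection, gauge
interpolation error, vegetation, prey population dynamics (DSD stands in
for production directly), or movement-based site fidelity. Passing
recovery tests therefore shows the estimation chain is faithful to its own
model class on clustered, seasonally confounded data — not that the fitted
coefficients would match any particular field system. The saturating DSD
form itself is a package choice; field data constrain only its sign and
rough scale.

## Prediction and indices

Stage-1 averaged models predict use from availability; stage-2 consumes
predicted use, availability SDs and reversal; random month effects are set
to their population mean (zero) for new data; count predictions are
back-transformed (inverse-root responses are clipped at a small positive
floor first) and flagged when any predictor leaves its training range.
Stage 2 is fitted on observed use but predicts from stage-1 output; the
asymmetry is intentional — the chain is the deployment path, the fit uses
the best available measurements.

The SFC surface is the averaged-model prediction per valid cell (region
and smoother effects included) on the frequency scale, averaged over the
requested dates; the smoother's own BLUP field is written separately as
the spatial-effect map. The combined daily index is the product of the TFC
individual index and the SFC mean over currently-available cells, each
normalized by its scenario maximum — one plausible combination, chosen for
interpretability (0–1, zero when either component vanishes); the raw
columns are always preserved, and days with zero available cells get a
combined index of exactly 0. Inverse-root transforms would invert
"more birds = higher index"; reports re-invert so the reading is uniform.

## Problem sizes and determinism

Default experiment sizes — 40×40 cells, 4 years, 200 survey days, 20
replicates for recovery checks, 999 permutations for Moran's I — keep the
full suite and the acceptance script in the minutes range on one CPU while
leaving the stochastic checks comfortable margins. All randomness flows
from explicit seeds (simulation streams are derived per-component via seed
sequences); pipeline reruns with the same configuration are byte-identical,
verified by manifest hashes.

## Known limitations

* Availability-side daily statistics are computed over the whole valid
  grid, not a flight-coverage subset; survey-extent masking would be a
  straightforward extension of the availability mask.
* The reversal "rewet" threshold equals the lower availability bound; a
  `depth > 0` variant is arguable and would be a one-line change.
* The "cells" model term is interpreted as the available-cell count.
* Inference after model averaging is approximate (unconditional SEs);
  no post-selection correction is attempted.
* The stork inverse-root transforms are variance-stabilizing tricks, not
  count models; a GLM family would be the principled alternative and is
  out of scope.
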