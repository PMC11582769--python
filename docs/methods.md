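# Methods

## Scope and shape

`estrocycle` is organized as an analysis project: the computation lives in
the installable package under `src/estrocycle/`, and the numbered scripts
under `analysis/` are thin narrative drivers that exercise it and write
tables under `results/`. Everything here runs on synthetic data produced by
the package's own seeded generators; no external measurements ship with the
repository.

## Signaling models

Three nested ODE models describe E2-driven induction of GREB1, PR and TFF1.
All bimolecular steps (binding, stimulation) use the saturating form
`p·X·Y/(1+X+Y)`, which bounds every flux by `p·min(X, Y)` and prevents
unbounded accumulation. Complexes degrade but never dissociate — without
measurements of the complexes themselves, dissociation rates would be
structurally unidentifiable. E2 has no synthesis term: free E2 is consumed
by complex formation only, which is what produces the biphasic E2 decay after
an exposure spike (fast while free ERα is abundant, then limited by ERα
resynthesis).

* **Model I** — E2-ERα binds GREB1; E2-ERα/GREB1 stimulates all three
  targets. Its knockdown predictions are structurally wrong: no target
  depends on PR.
* **Model II** — GREB1 stimulation additionally requires PR and TFF1 is
  driven by E2-ERα·PR. Knocking GREB1 down in this variant routes all
  E2-ERα into the TFF1-stimulating pool and over-expresses TFF1 (visible in
  `analysis/02_knockdown_panel.py`: TFF1 rises to ~2.6× mock).
* **Model III** — PR binds E2-ERα first, GREB1 joins afterwards; the
  quaternary complex stimulates GREB1 and PR, E2-ERα·PR stimulates TFF1.
  This is the only variant whose complete-knockdown pattern matches the
  observed interdependencies (PR↓ ⇒ GREB1↓, TFF1↓; GREB1↓ ⇒ PR↓; TFF1↓ ⇒
  nothing else changes), and it is the default for all coupled simulations.

**Steady-state constraint.** Synthesis rates are never free parameters:
`s_X = d_X·X_init` for ERα and the three targets, so the E2-free system sits
exactly at its initial state (the RHS is identically zero, not merely small).
Every candidate vector evaluated during fitting re-derives synthesis, so the
constraint is structural rather than penalized.

**Printed-equation switch.** In Models I/II the GREB1 balance includes the
flux consuming GREB1 into the E2-ERα/GREB1 complex by default (mass
consistency with the complex equation, mirroring Model III's explicit
consumption terms); `strict_printed=True` drops that term for the variant
without GREB1 consumption.

**Units and dose scale.** Concentrations are arbitrary units on the
effective-dose scale; time is hours. The nominal→effective dose map is a
monotone saturating table anchored at 0.001 (the pinned lowest dose), 0.837
(the 100 nM exposure level) and chosen so that log-log interpolation gives
~0.104 at the 0.055 nM bracket midpoint; the complete-medium E2 equivalent
is 1.5× that value, 0.156. Intermediate anchors (0.032, 0.158, 0.40, 0.65)
were fixed once as a plausible saturating curve through those constraints.

**Default rate constants.** Reference parameter tables for this system are
not available, so the shipped defaults are the package's own calibration,
chosen once to satisfy the qualitative constraints jointly: biphasic
GREB1/TFF1 induction (fast over the first 15 h, much slower afterwards) with
near-linear PR induction at the 100 nM exposure; a monotone drop of all
observables during a 24 h starvation with recovery after exposure; slow
enough E2-ERα turnover that the coupled oscillator keeps cycling through a
100 h exposure, yet fast enough that starvation arrests cells within a day.
Binding and degradation constants respect the [0, 1] fitting bounds.
`analysis/01_signaling_timecourses.py` prints the realized slopes. One known
cosmetic mismatch: with these defaults GREB1 peaks around 30 h and declines
mildly thereafter rather than rising without bound; the early/late slope
asymmetry (the biphasic signature) is preserved.

## Cell cycle model

The cell cycle is the classic two-variable CDK1/APC relaxation oscillator:
CDK1 is activated at a basal rate plus a Cdc25-type positive feedback and
inactivated by active APC; APC is activated by CDK1 and inactivated at a
basal rate. All Hill terms use K = 0.5, n = 8. The base constants
(a1 = 0.05, b1 = a2 = a3 = 1.5, b2 = 0.5 per hour) put the base period at
4.43 h; dividing the five rates by 11 — an exact time rescaling — yields
48.8 h, matching the ~50 h MCF7 division time.

Coupling adds `k_GREB1·GREB1` to CDK1 activation (GREB1 acts through
Akt-mediated p21 inactivation) and multiplies APC inactivation by
`r·E2_ER·PR` (both drive cyclin D1 and hence G1 exit). The coupling
variables are the free-form states of Model III (a literal reading of the
model equations); `couple_totals=True` switches to the observable totals.
With `k_GREB1 = 0` and `r·E2_ER·PR = 1` the base model is recovered exactly.

`k_GREB1 = 5·10⁻⁴` and `r = 41.5` were calibrated once
(`analysis/00_tune_coupling.py`): k_GREB1 contributes ~25 % of the basal
CDK1 activation at culture GREB1 levels — enough that its loss visibly slows
the G1/S transition, well below the level that destroys the limit cycle —
and r places the culture-driven period at 48.0 h. Oscillations are lost for
sufficiently large k_GREB1 and for r outside a finite band, as the tests
assert qualitatively; the exact boundary values depend on the signaling
scale and are not portable constants.

**Phase calling.** Interior CDK1 minima (found by prominence-filtered peak
detection with local quadratic refinement) mark mitotic exit; the APC
threshold is frozen once per cell at the first interior APC minimum plus 5 %
of the rise to the following maximum, with downward/upward crossings starting
G1/S and S-G2-M. Threshold crossings are refined by linear interpolation.
Degenerate inputs (no interior extrema) return an arrest verdict — a
single-phase sequence, G1 when the final CDK1 activity is below 0.5. The
threshold is derived per cell, from its own exposure-window trajectory; the
caller is responsible for classifying a window that starts on (or after
reaching) the regime of interest, since a deep transient APC minimum would
otherwise anchor the threshold.

## Protocol simulation

The in-silico protocol mirrors the wet-lab sequence: culture (E2 clamped at
the complete-medium equivalent 0.156) → optional 24 h knockdown (E2 still
clamped at 0.156, since transfection happens in complete medium) → 24 h
starvation (E2 clamped at 0) → exposure (E2 spiked to the effective dose and
left to deplete freely; default 100 h, 100 cells). Culture is never a fixed
duration: the signaling steady state is found by residual-controlled long
integration (residual < 10⁻⁸) and the driven oscillator's limit cycle by
integrating until consecutive periods agree to 0.1 %. Cell-to-cell
variability comes only from the initial cell cycle phase, sampled uniformly
along one culture period with a seeded generator. Knockdowns remove all
positive terms of the target's equation from the knockdown phase onward and
persist for the rest of the protocol.

Because the coupling is one-way, the signaling layer is integrated once per
protocol and each cell's two-variable oscillator is driven by the
interpolated signaling inputs (0.1 h grid) — identical results to joint
integration at a fraction of the cost, and the signaling trajectory is
bit-identical across cells by construction.

Phase durations are quantified in the exposure window only. In the
exposure's non-stationary drive, successive cycles shorten as signaling
builds up, so condition comparisons stratify by cycle index; pooled medians
can invert (a Simpson effect) when a knockdown changes how many cells reach
the later cycles.

The elementary starvation degradation model (`dX/dt = −d_X·X` per target) is
kept separate from the full model's degradation constants; its closed form
is used both as the fitting oracle and the log-linear initializer.

## Calibration

Fitting is bounded multi-start least squares (`scipy.optimize.least_squares`,
trust-region reflective, finite-difference Jacobians — at this problem size
they reach the same optima as sensitivity-equation gradients with far less
machinery). Latin hypercube sampling initializes the starts (one sample per
stratum per dimension; rates, stimulations, initial states and doses drawn
log-uniformly). Residuals compare `observable_totals` of an exposure-style
simulation (steady-state start, free E2 spike) with the data; replicates
enter as separate rows with unit weights — residual weighting across
reporters and doses is deliberately uniform and flagged in the fit report.
The lowest effective dose is pinned to 0.001; all other doses, the
stimulation rates, the target degradation rates and the initial states are
free by default. Binding and complex-degradation constants are only weakly
identified by protein totals and stay fixed unless explicitly freed.

Converged starts are clustered into optima (costs within 1 % relative,
parameter vectors within 5 % bound-normalized L∞); the result object always
reports all clusters so non-identifiability surfaces as multiple or wide
clusters rather than disappearing behind the single best cost. On noiseless
synthetic 6-dose data the generating stimulation and degradation rates are
recovered essentially exactly; with 10 % multiplicative noise the
stimulation/dose trade-off widens recovery to a few tens of percent
(`analysis/03_fit_synthetic.py`).

## FUCCI track pipeline

The pipeline follows the fixed rule set: dotted lineage relabeling; removal
of sub-5-sample childless tracks; family-track construction (one family per
final-generation descendant, ancestors repeated across sibling families);
removal of families with ≤ 30 samples or more than 4 Geminin-crash
divisions; per-channel min-max normalization over the experiment; centered
10-sample rolling means for the readouts (5 left / 4 right — the even-window
convention) and a trailing 2-sample mean for division detection (drop
steeper than 0.5 SD of the smoothed trace; adjacent flags merge into one
event); the log-ratio with ±100 sentinels below the 10⁻⁴ normalized
intensity floor; phase assignment with G1/S precedence whenever |r| < 2 and
r is not a sentinel; flip correction (≤ 4-sample excursions that revert) to
fixpoint, then the mitotic G1/S → G1 correction. Durations count a run of k
samples as k·Δ (Δ from the data, 0.5 h for FUCCI movies); runs touching a
subtrack boundary are censored and excluded from summaries; ancestor samples
are counted once (assigned to the lexicographically first family) and
leftover subtracks of ≤ 5 samples are dropped. Condition comparisons use
Welch's one-way ANOVA with Games–Howell post-hoc tests (pingouin), with a
degenerate-variance guard for constant groups.

The bundled linker (`link_tracks`) is a deliberately simple greedy
maximum-overlap tracker honoring the 40 px centroid-displacement limit and
recording one-to-two links as divisions; it exists to close the loop from
label movies to tracks, not to compete with production trackers (no gap
closing, no apoptosis handling).

## Synthetic data

The generators are first-class, seeded, and emit ground truth sufficient to
score every downstream module.

* **Expression tables** — exposure-style simulations per dose multiplied by
  lognormal replicate noise (σ = 0.1 by default, a stand-in chosen to mimic
  typical replicate spread, not an estimate from data).
* **FUCCI tracks** — piecewise-linear Cdt1/Geminin templates keyed to a
  scripted phase sequence (not a mechanistic reporter model): Cdt1 high in
  G1 and decaying across G1/S, Geminin rising from G1/S through S-G2-M with
  a crash at division, one colorless frame after mitosis, binary lineages.
  The template levels adjacent to each phase boundary are calibrated so that
  the pipeline's centered 10-sample smoothing leaves each recovered boundary
  within about one frame of the script; by default founders start beyond the
  post-mitotic Cdt1 accumulation window so the first frames show settled
  readouts. What passing the recovery oracle shows is that the *rule set* is
  implemented faithfully — real FUCCI data adds photobleaching, segmentation
  errors and heterogeneous reporter kinetics that these templates do not
  emulate.
* **Label movies** — drifting elliptical nuclei on a jittered grid with
  scripted splits; geometries that would overlap raise instead of merging
  silently.

## Image maps

The cell distance map is the per-object Euclidean distance transform,
max-normalized per object (single-pixel objects map to 1.0). The neighbor
distance map removes each object in turn, takes the distance to the
remaining objects, masks, max-normalizes, inverts, composites, applies a
flat 3×3 grayscale closing and raises to the 10th power. Reconstruction
smooths both predictions (Gaussian σ = 1.5), thresholds the smoothed CDP at
0.15 for the mask, seeds from connected components of CDP − NDP² > 0.25
(seed map left unclipped) and floods the negative smoothed CDP by
marker-based watershed within the mask — basins at cell centers; the
elevation choice is ours, the thresholds are the fixed post-processing
constants.

## Problem sizes and numerics

Integration uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ (fits use rtol 10⁻⁶ for
speed); E2 clamping zeroes the derivative rather than resetting state.
Oscillation detection requires ≥ 3 prominence-filtered peaks (5 % of the
observed range) with spacing variation < 10 %; peak times are refined by
local quadratic fits so period estimates do not inherit grid quantization.
Default study sizes: 100 virtual cells per protocol, 6 doses × 56 hourly
timepoints × 3 replicates for calibration data, 20 multi-start fits in the
acceptance script (unit tests use smaller counts), 96-frame FUCCI movies at
0.5 h, 20–25 nucleus fields for the segmentation round trip.

## Known limitations

* The shipped rate constants are a qualitative calibration, not a fit to
  measurements; quantitative durations (e.g. the ~20 h in-silico G1/S) are
  longer than typical experimental medians, as expected for a two-variable
  caricature of the cycle tuned only to total period.
* TFF1's long-term decay is not captured (its induction relaxes within the
  measurement window), one reason TFF1 is excluded from the cell cycle
  coupling.
* PR-knockdown arrest is reached asymptotically: cells caught mid "last
  gasp" CDK1 rise can take tens of hours to settle, so arrest statistics use
  population medians and division counts rather than per-cell tail maxima.
* The FUCCI generator's recovery guarantees hold for boundaries that clear
  the movie edges by at least half a smoothing window; edge-adjacent
  transitions can shift by ~2 frames.
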