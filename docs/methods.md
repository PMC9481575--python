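# Methods

## Scope and model

`chromopull` analyzes stretching (force–extension) traces of long
nucleosome arrays — heterogeneous chromatin fibers of tens to hundreds of
nucleosomes reconstituted on lambda-phage, native genomic, or '601'-array
DNA — and simulates such traces with known ground truth.

### DNA elasticity

All conversions between force, extension, and base pairs go through the
worm-like chain. Two functional forms are exposed:

* the high-force extensible expansion `z/L = 1 − ½√(kBT/(F·Lp)) + F/S`,
  used for every fit (all fitting windows lie at or above 0.3 pN, and the
  composite form below switches well before the expansion degrades);
* the extensible Marko–Siggia interpolation, solved by bisection, used for
  forward simulation below 1 pN.

The default `"auto"` form is the composite: Marko–Siggia below 1 pN, the
expansion at and above. The discontinuity at the crossover is < 0.5 % of
`z/L` and both the generator and the fitters use the same composite, so it
cancels in round trips. Constants: `kBT = 4.11 pN·nm` (298 K), rise
0.34 nm/bp — the latter fixed by the exact 200 bp ↔ 68 nm equivalence the
detector threshold is defined with. Two lambda lengths are kept: 48,502 bp
(the phage genome) as the default template and 48,548 bp (genome plus
labeled handles) as the reference length of the count projection
`N_projected = N_observed · 48,548/L_observed`.

### Fiber statistical mechanics

Nucleosomes are independent and identical. A folded-class nucleosome has
three states — stacked (sequesters one NRL of DNA), state 1 (92 bp
wrapped, cost `ΔG1`), state 2 (79 bp wrapped, additional cost `ΔG2`,
i.e. 13 bp more released). Unfoldable nucleosomes (`N_unfold = N_total −
N_folded`) have no stacked state and start in state 1. Occupancies are
Boltzmann weights `exp(−(G_i − F·Δz_i(F))/kBT)` with `Δz_i` the extension
gained in state `i`: the WLC extension of the DNA released relative to
stacking, minus the per-nucleosome share of the folded domain's Hookean
extension `F/(k_fiber·N_folded)`. Model extension is the WLC extension of
all non-sequestered DNA plus `p_stacked·F/k_fiber`.

`k_fiber` is the whole-folded-domain stiffness (the per-tether quantity
reported for real fibers, 0.18–0.53 pN/nm); a per-nucleosome
interpretation is available as `stiffness_mode="per_nucleosome"`. One
modeling caveat: the per-nucleosome Hookean share grows as `1/N_folded`,
so assigning a whole-fiber stiffness of ~0.25 pN/nm to a folded domain of
only a few nucleosomes makes stacking spuriously re-favored at high force.
The model is meaningful when the folded domain's compliance per nucleosome
is small against the ~35 nm gained on unstacking — in practice
`k_fiber·N_folded ≳ 3 pN/nm`, comfortably true for real fibers. The trace
generator honors the series-spring picture during the last-turn cascade:
as nucleosomes leave the folded class the remaining domain stiffens as
`k·N₀/N`, keeping the per-nucleosome compliance constant.

The last-turn release (79 bp, 25–27 nm above 10 pN) is deliberately not an
equilibrium state: it is simulated as an irreversible per-nucleosome event
and analyzed only through the `79 bp × N_total` contour reduction.

## Per-trace inference

Both nucleosome counts exploit that the apparent WLC contour is linear in
the count, so every window sample inverts to a count estimate; the default
estimator is the median of these per-sample estimates (robust to samples
contaminated by a nearby rupture), with plain least squares as an option.
Counts are continuous and rounded to the nearest integer.

* **N_total**, window 8–15 pN, contour `L − 79·N_total`. Within this
  window, last-turn releases (which begin above 10 pN) progressively hand
  79 bp per nucleosome back to the free DNA; for a saturated lambda fiber
  a window-wide fit is thereby biased low by 2–3 nucleosomes. The
  estimator therefore restricts itself to the window portion at or below
  the last-turn onset (`count_force_cap_pN`, default 10 pN) whenever
  enough samples remain there — in that regime the 79 bp reduction holds
  exactly.
* **N_folded**, window 0.5–2 pN, contour `L − NRL·N_folded −
  92·N_unfold`. The 92 bp correction for unfolded (beads-on-a-string)
  nucleosomes is on by default: those nucleosomes demonstrably sequester
  their wrapped DNA at low force, and without the correction the folded
  count of a half-saturated lambda fiber would be inflated by ~35
  nucleosomes. It can be disabled (`correct_unfolded=False`) to reproduce
  the bare recipe.
* **Pending-loop correction.** A chromatin loop that ruptures above a
  counting window is still closed inside it and its DNA reads as extra
  folded nucleosomes (~1 nucleosome per 105 bp of loop). The pipeline
  therefore runs rupture detection first and subtracts, per sample, the
  measured sizes of all events whose rupture force lies above that
  sample's force. Loops below the detection floor (see below) remain
  invisible and contribute their full bias; a single undetectable 250 bp
  loop costs ~2 folded-count units.

**Model fit.** With counts fixed, (`k_fiber`, `ΔG1`, `ΔG2`) are fitted by
Levenberg–Marquardt least squares on extension residuals over 0.3–10 pN.
Initialization is deterministic: `k` from the extension excess over the
free-DNA WLC at ~0.7 pN, `ΔG1` from the plateau force × plateau step of a
trial model, `ΔG2` at 4.5 kT. Rupture events are masked (samples of each
event ± 5 dropped) by default; masking alone leaves the pre-rupture
extension deficit in the data, so fitted stiffness on rupture-containing
traces is biased — the same bias the method shows on real data. The
optional `rupture_handling="stitch"` adds each measured release back to
the pre-rupture samples, which removes most of the offset but still leaves
`k` sensitive to the few-percent step-measurement error, because the
entire low-force Hookean signal is only a few nm. Quantitative stiffness
estimates should come from traces without large ruptures; masked fraction
> 50 % sets a `low_confidence` flag, `N_total = 0` a `degenerate` one.

**Cohorts.** Groups are summarized as mean ± sd with 5–95 % percentile
whiskers (linear interpolation) and values beyond the whiskers listed as
outliers; pairwise group comparisons use a two-sided Welch t-test by
default (Mann–Whitney U optional).

## Rupture detection

The detector follows the published recipe: 15-point centered median filter
(edges use shrunken windows), candidate steps where consecutive filtered
samples increase by more than 68 nm (200 bp of free DNA), candidates
closer than 5 samples merged, closed 1–15 pN keep window, unsticking
filter `dR > 0.1 µm` (bead XY averaged over 5 samples each side of the
event), and classification low/high at 8 pN (exactly 8 pN → high).

Two quantities are measured differently from the naive reading, for
accuracy:

* **Step size.** The endpoint difference of the filtered trace is biased
  on the unstacking plateau: the baseline there rises several nm per
  sample with appreciable curvature, and the median filter's order
  statistics at a noisy step also swallow ~2.5 noise sd. Event sizes are
  instead measured by changepoint regression on the raw trace — least
  squares of a cubic baseline plus a step indicator over a symmetric
  ±60-sample window around the event, transition core excluded, window
  clipped at neighboring events (filtered endpoint difference as the
  fallback near trace edges). With a symmetric window the even polynomial
  terms are orthogonal to the step and the cubic absorbs the plateau's odd
  curvature; measured sizes are unbiased within ~5 % down to 400 bp
  events sitting mid-plateau.
* **Detection floor.** Candidacy still requires a single-sample filtered
  increase above 68 nm, so steps below ~300 bp at low force (where
  relative extension is ~0.86 and the filter's order-statistic loss bites)
  are censored. This is intrinsic to the recipe, not to this
  implementation. Consequently, rate-recovery experiments configure
  generated loop sizes ≥ 400 bp — above the floor — so that "the detector
  recovers the configured rate" is a well-posed statement; the generator's
  *default* loop-size distribution keeps the smaller-loop mass (lognormal,
  median 400 bp, clipped to 250–10,000 bp) to mirror real fibers, where
  sub-threshold ruptures likewise exist but cannot be counted.

Rates are `10 × (kept low-class events) / (summed template length in
kbp)`, counting every recorded trace in the denominator.

## Synthetic data

The generator emulates the fibers the analysis is designed for:

* clustered placement — clutches of 3–10 nucleosomes at one-NRL spacing,
  separated by 100–300 bp nucleosome-free gaps (rescaled down if the
  layout overruns the template); uniform non-overlapping placement as the
  alternative;
* equilibrium extension from the fiber model, defaults `k_fiber`
  0.25 pN/nm, `ΔG1` 20 kT, `ΔG2` 4.5 kT, NRL 197 bp, 39 % of nucleosomes
  folded — mid-range values for reconstituted fibers; the resulting
  plateau sits at ~2.5 pN, inside the observed 2–5 pN band;
* last-turn releases per nucleosome at forces from Normal(20, 5) pN
  truncated below 10 pN (only the >10 pN onset is constrained by
  observation; mean and sd are package choices placing most releases
  inside a 40 pN ramp);
* loop ruptures at configured (size, force) pairs, forces uniform over
  1–15 pN when drawn, sizes as above;
* Gaussian extension noise, default sd 10 nm (typical bead-tracking noise
  at video rates; acquisition details are package choices), white XY bead
  noise of 0.02 µm, optional injected unsticking jumps;
* protocol: logarithmic force ramp 0.3 → 40 pN over 40 s at 60 Hz
  (2400 samples).

All randomness derives from a single seed (cohorts via spawned child
streams), and each trace embeds its full truth record; cohorts emit a JSON
manifest.

What the generator does *not* emulate — and what passing round trips
therefore do not demonstrate: force-calibration error and drift, hysteresis
between stretch and relief, nucleosome positioning sequence preferences,
cooperativity between nucleosomes, kinetic (loading-rate-dependent)
rupture forces, and correlated low-frequency bead noise. Recovery numbers
on synthetic cohorts are upper bounds on what identical settings achieve
on real traces.

## Problem sizes

The test suite and acceptance checks run cohorts sized to exercise the
statistics without waste: 100 traces of 40-nucleosome fibers on 12 kbp
templates for parameter recovery (counts exact to ±1/±2; fitted-parameter
medians within a few percent of truth), 200 lambda-scale traces for
rupture-rate recovery at 0.56 events per 10 kbp, 25×3 inserted loops for
detector sensitivity, and 30 step-free traces for the false-positive rate.

## Known limitations

* Stiffness estimates on traces with large pending loops are biased (see
  above); the package reports them anyway, flagged, matching how the
  method behaves on real data.
* `ΔG2` is weakly identified when the fit window barely covers the second
  unwinding transition (~4–7 pN); its deterministic 4.5 kT initialization
  then dominates the estimate.
* The equilibrium model has no hysteresis; relief (force-decreasing) data
  are not modeled, and only extension increases are counted as ruptures.
* Counting assumes the template length is known (or previously fitted at
  F > 40 pN); errors in `L_DNA` propagate 1:1 into `79·N_total`.
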