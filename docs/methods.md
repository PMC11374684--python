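# Methods

## Minimal model of MaSC clone fate

The mammary epithelium is treated as a collection of MaSC-descendant units:
one self-renewing stem cell supporting roughly five to ten short-lived
descendants. A stochastically recombined (confetti-labelled) cell founds a
clone that is *MaSC-rooted* with probability 1/u (u = `unit_size`, default 5)
and *descendant-rooted* otherwise.

Per oestrous cycle:

* a MaSC-rooted clone of size n is **activated** with probability
  `p_activate` (default 0.1 — active roughly once per ten cycles, from the
  observed growth characteristics). An activated clone is **wholly lost**
  with probability q, otherwise its size becomes round(n·f) with
  f = `expansion_factor` (default 2), never less than n+1. The whole clone
  shares one fate — loss and expansion are perfectly correlated within the
  clone, which is what makes the log-size statistics multiplicative
  (log-normal-like) rather than the power-law scaling of independent per-cell
  stem-cell replacement.
* a descendant-rooted clone never expands and survives the cycle with
  probability `descendant_persistence` (default 0.8, i.e. a mean lifetime of
  five cycles — gone within the first few months, matching the steep early
  drop of surviving clones towards the 1/u plateau).

**Homeostasis.** The mean labelled-cell count is conserved iff
(1 − q)·f = 1, so q is derived, not free: q = 1 − 1/f, giving q = 1/2 at
f = 2 — half of all activated clones are lost per cycle. `loss_prob` may be
set explicitly only with `homeostasis=False` (e.g. mutant clones resistant to
loss during side-branch regression use q below the homeostatic value, which
produces a net spreading advantage: a strictly larger μ-slope at matched
p_activate).

Conditioned on survival, ln n is a random walk with per-cycle drift
p_a(1 − q)·ln f and matching linear variance growth, so μ(t) and σ²(t) are
linear in cycle number (R² ≈ 0.995 at 50,000 clones over cycles 10–60).

**Randomness.** One root seed; clone i consumes a fixed contiguous block of
the generator stream (one rooting uniform plus two uniforms per cycle), so
enlarging `n_clones` appends clones without reshuffling earlier ones. The
optional stochastic expansion factor (`expansion_jitter_sd`, default 0 = off)
draws a log-normal multiplier with mean f from the same per-cycle block (the
loss uniform, conditioned on survival, is mapped through the normal
quantile), preserving determinism and the homeostatic mean.

**Discreteness caveat.** Sizes are integers and induction is a single cell.
With deterministic f = 2, surviving sizes are exactly powers of two, and even
with a stochastic factor the clones that have never been activated form an
atom at n = 1. At the default activation rate the expected number of
activations by cycle t is t/10, so through cycles 10–60 the rescaled
log-size distribution is a coarse, time-varying lattice: two-sample KS tests
between sampling times reject, and the sup-deviation of the pooled rescaled
CCDF from ½·erfc(x/√2) is ≈ 0.3. The erfc collapse is an asymptotic
(many-activation) property of the model, not a finite-time one; the
corresponding end-to-end check is therefore expected to fail at these
parameters and is kept as an honest negative. The lattice model below, whose
per-event expansion factors are continuous (block refill ratios), reaches the
collapse regime within ~60–150 cycles.

## 1D lattice (ribbon) model

The ductal epithelium is reduced to a ring of L sites (one MaSC each;
periodic topology avoids edge effects). Per cycle, `events_per_cycle`
remodelling events occur (default round(p_a·L/ℓ), matching the minimal
model's per-site activation rate). An event selects a uniformly random block
of ℓ contiguous sites (`block_length`, the side-branch territory), loses each
site independently with `site_loss_prob` (default 0.5), and refills the block
by proportional expansion of the surviving sites' labels in their original
left-to-right order. Survivor counts are scaled back to ℓ by
largest-remainder (Hamilton) apportionment, ties to the leftmost run; a
fully lost block is recolonised ⌈ℓ/2⌉ sites from the left flank and ⌊ℓ/2⌋
from the right. The site count is conserved exactly and every tracked clone
remains one contiguous run on the ring (asserted by enumeration and fuzzing).

Phenomenology: at intermediate times (typical sizes between one site and ℓ)
clone growth is multiplicative and the rescaled size distributions pass the
same collapse test as the minimal model; once typical sizes exceed the block
scale, expansion proceeds only by interface drift between neighbouring
clones, and the growth rate of var(ln size) collapses (measured at
L = 10,000, ℓ = 20: the late-time rate is ~0–5% of the early rate).
Labels are passive — dynamics do not depend on them — so the tracked-label
density is purely a sampling choice: full labelling (density 1) is used for
variance curves (maximal statistics), sparse labelling (0.05, clone counts
comparable to the experimental tables) for collapse testing, and dense
labelling (0.3) for the neighbour-correlation analysis, where adjacent
clones must lie within a block length of each other for fates to be shared.

## Clone-size scaling statistics

* Moments use the population (1/N) variance of ln n, matching the moment
  definition ⟨(ln n − ⟨ln n⟩)²⟩; single-cell clones are retained (ln 1 = 0),
  no pseudo-counts.
* The CCDF uses the strict inequality C(w) = P(ln n > w), right-continuous.
* `rescale` standardises within stratum; the output is invariant to n → n^a.
* The collapse test runs all pairwise two-sample KS tests on the rescaled
  samples with Holm correction (calibrated by simulation; the published
  analysis' exact test lives in unpublished supplementary material, so ours
  is declared here), plus each stratum's sup-deviation from ½·erfc(x/√2)
  (equal to the KS distance to the standard normal). Strata below
  `min_n = 20` clones or with zero log-variance are excluded with a warning.
* Surviving clone fractions divide each timepoint's mean clone count by the
  14-day reference count.
* Normality checking uses a Monte-Carlo-calibrated KS test against the
  fitted normal (Lilliefors-style, 999 calibration replicates by default).
  Note that for integer sizes at modest μ/σ the test will always reject at
  large n because of discretisation atoms; it is informative only when the
  size support is effectively continuous.

## Ripley statistics in 1D

K(r) = D/(N(N−1)) · Σ_{i≠j} 1(|x_i − x_j| ≤ r) with distances measured as
arc length along the duct. Under CSR E[K(r)] = 2r, so the normalised
L(r) = K(r)/2 − r is zero under CSR, positive under clustering, negative
under regularity (the script the published analysis used normalises in its
own repository; this normalisation is declared and tested against the
analytic CSR expectation and an O(n²) brute-force oracle). Default edge
correction reflects the pattern at both domain ends; "none" is provided for
comparison since ducts are long relative to the radii of interest (default
radii: 40 log-spaced values from 5 µm to D/4). Envelopes are pointwise
quantiles of L over seeded CSR simulations with matched N and D (≥ 39
simulations for a 95% band). Because L(r) is strongly correlated across r,
single-pattern envelope coverage is calibrated over replicates, not per
pattern.

Branch-level uniformity compares observed clone counts per branch level
(number of bifurcations separating a segment from the main duct; unbranched
elongations do not count) against the slot-weighted expectation via a
chi-square statistic with a Monte-Carlo multinomial null (10,000 draws) —
small per-level counts make the asymptotic chi-square unreliable.

## Synthetic data

The generator emulates the study conditions: recombination in one cell per
100 (four confetti colours → one per 400 per colour; with 5–10-cell units,
one label per 40–80 units), observation at 14/64/120/225 days, 5.5 days per
oestrous cycle (midpoint of the 4–7-day range), and per-mouse log-normal
timescale multipliers with log-scale s.d. 0.3 representing mouse-to-mouse
variability in effective cycle number. Side-branch vs main-duct location is
assigned independently with probability 0.5 (the true split is not
published; it is exposed in the design), and an optional location-specific
loss-probability shift emulates the mutant side-branch bias (off by
default). Colours are uniform over the four fluorophores; same-colour
collisions are not merged — labelling is sparse enough that mergers are
negligible, and clone loss dilutes them further. Cluster-pattern
displacements are truncated (discarded) at the domain edges rather than
reflected; edge behaviour is tested through the envelope, not assumed.

What the generator does **not** emulate: transformation and tumour
morphology (the `transformed` flag is a pass-through), pregnancy-specific
remodelling (only expressible as altered elapsed cycles), within-clone
spatial structure, and measurement error in cell counting. Passing tests on
these data therefore validate the statistical machinery and the model's
internal consistency, not the biological fit to real glands.

## Inference

* `infer_effective_cycles` fits shared μ- and σ²-growth lines and per-mouse
  effective cycle numbers by alternating least squares (closed-form t-update,
  relative tolerance 1e−8, ≤ 500 iterations), anchored so the mean effective
  cycle number at each nominal day equals day/5.5. With a single nominal
  timepoint the data carry no timescale information and the anchor value is
  returned directly.
* `fit_model_params` is a simulated method of moments over
  (unit_size, p_activate, loss_prob): targets are the log surviving-count
  ratios relative to the earliest timepoint plus the OLS slopes of μ and σ²
  against nominal cycles, weighted by inverse two-level bootstrap variance
  (clones within mouse, then mice; unweighted available). Simulations reuse
  common random numbers so the objective is deterministic per seed; a coarse
  grid precedes Nelder–Mead refinement boxed to admissible ranges
  (u ∈ [1, 40], p_a ∈ [0.005, 0.6], q ∈ [0.05, 0.95]). The expansion factor
  is assumed (default 2), not fitted: it is confounded with p_activate
  through the per-cycle drift p_a(1 − q)ln f. For the same reason, data
  without clone spread (ovariectomy-like) identify only the products
  p_a·q and p_a(1 − q); the reported check there is that the fitted drift is
  nil. Recovery on synthetic cohorts (6 mice × 3 glands, ~5,000 induced
  clones, 4 timepoints, 20 replicates) returns mean estimates within ±0.2
  (u), ±0.01 (p_a) and ±0.03 (q) of the generating values.
* `estimate_unit_size` inverts the long-term surviving fraction (20% → 5
  cells, 10% → 10 cells).

## Problem sizes and numerical choices

Simulation sizes used in the shipped analyses and tests — 50,000 clones ×
60 cycles (minimal model), three replicate 10,000-site × 2,000-cycle lattice
runs, 200 CSR replicates for Ripley calibration, 20 recovery replicates —
were chosen so every stochastic check sits several standard errors from its
threshold while the whole suite stays fast. Ties in size rounding go half-up;
extinct clones are exactly 0 and extinction is absorbing; apportionment ties
go to the leftmost survivor; all stochastic functions take explicit seeds and
are reproducible bit-for-bit.

## Known limitations

* The exact published update rule and fitted parameter values live in
  unpublished supplementary material; this implementation follows the
  main-text statements (p_a ≈ 0.1, f = 2, q = 1/2, u ∈ [5, 10]) and validates
  itself by parameter recovery, not by reproducing the original fits.
* The finite-time discreteness of integer clone sizes (above) means the erfc
  collapse holds for the lattice model and for real-valued asymptotics, but
  not for the minimal model at the default activation rate within 60 cycles.
* The lattice refill rule is one concrete member of the class of cooperative
  block-remodelling rules; the claimed phenomenology (log-normal phase,
  block-scale suppression, Gaussian-like crossover) is the tested surface,
  not rule-for-rule identity with the original.
* Whether glands are pooled within mouse before computing per-mouse moments
  is not published; moments are pooled per mouse across glands here, with
  per-gland strata available through `group_moments` keys.
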