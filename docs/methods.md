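# Methods

## Models and procedures

### Aerosol size-distribution metrics

A mobility sizer reports particle number concentrations on geometrically
spaced diameter channels over a fixed window (default 6–225 nm).  The binned
summary is

- `N = Σ nᵢ` (particles/cm³),
- `CMD = exp(Σ nᵢ ln dᵢ / N)` — the count-weighted geometric mean diameter,
  which equals the median for a lognormal distribution,
- `GSD = exp(√(Σ nᵢ (ln dᵢ − ln CMD)² / N))`.

An alternative CMD estimator interpolates the 50th count percentile on the
log-diameter axis (`estimator="interpolated_median"`); cumulative counts are
referenced to mid-bin mass, since the plain cumulative sum refers to the
bin's upper edge and biases the median by half a channel.  The default is the
geometric mean because the internal estimator of a given instrument is
generally not documented; on the discretised lognormals used in the tests
the two agree within 1 %.

Surface and volume concentrations follow the Hatch–Choate lognormal moment
identities (`S = NπCMD²exp(2 ln²GSD)`, `V = N(π/6)CMD³exp(4.5 ln²GSD)`), and
`binwise_moments` accumulates `Σ nᵢπdᵢ²` and `Σ nᵢ(π/6)dᵢ³` channel by
channel as a model-free cross-check; the two routes agree within 0.5 % for
distributions resolved on ≥128 geometric bins inside the window.  Moments
are computed only over the supplied instrument range — no tail extrapolation
is attempted, mirroring what the instrument can actually see.

Mass concentration is `ρV·1e-9` µg/m³ with the bulk material density
(19.32 g/cm³ for gold, 10.49 g/cm³ for silver).  Mobility-derived mass at
bulk density can disagree with filter-based or spectrometric mass when the
effective particle density differs from bulk; the campaign summary annotates
this assumption rather than applying any hidden correction factor.
Multi-day campaigns are summarised as mean ± SD of daily values.

When bin edges are supplied, the representative diameter is the geometric
midpoint `√(lo·hi)` (channels are geometrically spaced); plain midpoints are
accepted as-is otherwise.

### Lung-burden processing

Whole-lung burden is tissue concentration (ng/g, ICP-MS) × whole lung weight
(g).  Spiked-lung standard curves are fit by ordinary least squares and
inverted for correction (`corrected = (raw − intercept)/slope`), clamping
negative values to zero with a censoring flag and flagging extrapolation
outside the spiked range.  Solution-scale values below the LOD are
substituted at LOD/2 by default (alternatives: 0 or LOD); values between LOD
and LOQ are retained with a below-quantification flag.  The substitution
default is the common occupational-hygiene convention; nothing in the
pipeline depends strongly on it because study burdens sit far above the
limits.

Group cells are summarised as mean ± SE (SE = sd/√n, ddof = 1; single-animal
cells report SE 0 with an `se_undefined` flag).  Retention is
100·mean(t)/mean(PEO-1) — the ratio-of-means convention — with the baseline
treated as a fixed reference (retention at PEO-1 is exactly 100 ± 0).  The
E-1 sacrifice (after the first exposure day) precedes the end of exposure
and is excluded from retention and kinetics.  Because animals are sampled
destructively, a literal per-animal ratio does not exist; the
`mean_of_ratios` mode pairs animals with baseline animals by rank as an
approximation and is provided because published retention tables are not
always consistent with ratio-of-means arithmetic.  Co/single burden ratios
default to ratio-of-means with a first-order (delta-method) SE; the null
expectation 0.5 reflects the co-exposure aerosol carrying half the mass
concentration of each single exposure.  Control background is not
subtracted by default.

### Clearance kinetics

Time axis: PEO-1 ↦ 0 d, PEO-7 ↦ 6 d, PEO-28 ↦ 27 d.

The one-phase model `M(t) = P₁e^(−λ₁t)` is fit by default as a linear
regression of log-retention on time with free amplitude (`P₁` absorbs
baseline error; the fit is then invariant to rescaling a mass-scale series).
A fixed-amplitude variant regresses through the origin of log space, and a
natural-scale objective is available.

The two-phase model `M(t) = P₁e^(−λ₁t) + P₂e^(−λ₂t)` with `P₁+P₂ = 1` is
always fit on the natural scale (log-scale fitting would distort the
compartment fractions).  The slow rate is parameterised as a fraction of the
fast rate, so `λ₁ ≥ λ₂` holds by construction; this matters because with a
fixed fraction the mirrored assignment (fraction attached to the slow
compartment) is a distinct exact solution of the same equations.
Optimisation is bounded trust-region least squares from 16 log-spaced,
seed-jittered starts (first start deterministic); best SSE wins, and the
whole procedure is deterministic given the seed.  λ bounds default to
[1e-6, 10] per day.  Fits are unweighted by default (inverse-variance
weighting would require SEs the three-point series cannot really support).

With three points (one of them the baseline, which the constraint fixes),
the free-fraction model has three parameters and two informative
observations: the estimator raises an identifiability error instructing use
of `fast_fraction`.  The independent `exact_constrained_solve` eliminates
λ₁ from the 6-day equation and brackets λ₂ between the value at which λ₁
diverges and the value at which λ₁ = λ₂, solving by Brent's method to 1e-12;
least-squares and bracketing solutions agree within 1e-6 relative on valid
3-point problems, and a coincident-rate generating model is returned as the
boundary (one-phase collapse) solution.

Model comparison uses small-sample AICc on natural-scale SSE with
k = kinetic parameters + 1; at n = 3 the correction term is undefined, AICc
is flagged unreliable and an a-priori model assignment (one-phase for
biopersistent, two-phase for biosoluble analytes) is required — the same
a-priori reasoning sparse regulatory designs rely on.

`fraction_cleared_by(fit, t) = 100·(1 − M(t))` gives the percent of the
baseline burden cleared by day `t`, e.g. the ~45 % of silver solubilised and
removed within 5 days implied by the co-exposure parameters.

### Simulator

The exposure calendar is 6 h/day, 5 days/week, 4 weeks: exposure on days
1–5, 8–12, 15–19, 22–26, with sampling at E-1 (day 1), PEO-1 (27), PEO-7
(33) and PEO-28 (54).  The calendar mapping is a package convention; only
the post-exposure day offsets matter for the kinetics.

Each exposure day deposits `daily_deposit` ng.  A fraction
`rapid_initial_loss` (default 0) of the day's deposit is removed within the
deposition day — a proxy for rapid dissolution and ion clearance of
biosoluble particles, which accumulate far less burden per exposure day than
they deposit; the Ag-like presets use 0.85, an illustrative value, not a
measurement.  The remainder splits `fast_fraction`/(1 − `fast_fraction`)
between two pools that decay as `exp(−λ)` per day.  Deposition is lumped at
the end of each 6-h window rather than integrated continuously; at these
rate scales the difference is below 1 % and the daily stepping stays in
closed form, making mass balance (retained + cleared + initial losses =
deposited) exact to floating-point rounding.

Sampling noise is multiplicative lognormal with unit mean on the whole-lung
burden (burdens are positive and right-skewed), default CV 0.25, matching
the scatter implied by published group SEs (SE·√n/mean ≈ 0.22–0.3); lung
weights are drawn independently (lognormal, mean 1.4 g, CV 0.08 — a typical
whole-lung weight for young adult male Sprague-Dawley rats) and tissue
concentration is back-computed, so simulated tables are schema-identical to
real input.  Default group sizes follow the study design: 4 animals at E-1,
5 per post-exposure day.  Everything is reproducible bit-exactly from the
seed.

### Parameter recovery

`recovery_experiment` repeatedly generates noisy group means at the three
post-exposure timepoints, normalises to the PEO-1 mean and fits the
configured model, summarising the recovered half-times (median, bias, RMSE)
against truth.  Its default design is a post-exposure **bolus**: the truth's
compartment fractions hold at the PEO-1 baseline and the burden decays
biexponentially from there.  This is the experiment the retention-model fit
actually describes.  The alternative `mode="full_schedule"` takes the
baseline state from a full intermittent-exposure simulation; there the fast
pool is heavily depleted by PEO-1 (for silver-like rates it holds ~9 % of
the burden rather than the per-deposit third), so the constrained fraction
is taken from the true trajectory's pool split and fast-phase estimates are
intrinsically noisy — a real limitation of three-point designs that the
simulator exposes rather than hides.  Fit failures are counted, never fatal.

At the default conditions (200 replicates, n = 5, CV 0.25, bolus design,
silver-like truth) the median recovered half-times land within 15 % of
truth; the fast phase carries most of the Monte-Carlo spread because its
signal at day 6 (~0.09 of the retained fraction) is comparable to the noise
on a group-mean ratio.

## What the synthetic data do and do not show

The simulator emulates group structure, intermittent build-up, two-pool
decay and lognormal sampling scatter.  It does not model deposition-fraction
physics, inter-animal kinetic heterogeneity (only multiplicative noise),
dissolution chemistry, or why a biosoluble aerosol retains ~10× less burden
than a biopersistent one after a single exposure day (the
`rapid_initial_loss` knob reproduces the magnitude but not the mechanism).
Passing recovery tests therefore demonstrate correctness of the fitting
machinery under the stated noise model, not that real three-point studies
pin down fast-phase half-times with that precision.

## Numerical choices and degenerate inputs

- Two-phase multistart: 16 starts, seeded jitter, best SSE; optimiser
  tolerances 1e-14 with a 10 000-evaluation budget (budget-capped candidates
  are kept and compete on SSE).
- Exact solver bracket endpoints are inset by 1e-13; an unbracketed residual
  below 1e-9 at the λ₁ = λ₂ endpoint is treated as the degenerate
  coincident-rate solution.
- Empty distributions, all-zero counts, non-ascending diameters, gsd < 1,
  non-positive spikes/weights/rates, duplicate-only calibration levels and
  increasing retention series all raise explicit errors rather than
  producing numbers.
- Report CSVs are written with fixed `%.10g` float formatting and no
  timestamps, so pipeline reruns are byte-identical; human-facing tables
  round to reporting precision (0.1 % retention, 0.01 ratios, 0.1 d
  half-times) while JSON keeps full precision.

## Problem sizes

The test suite and the acceptance script run the solver cross-check on 100
random 3-point problems, the recovery experiment at 200 replicates × 5
animals, and the CLT check on 1 000 resamples of a 5-animal group — sizes at
which the Monte-Carlo summaries are stable while the whole suite stays
interactive.

## Known limitations

- Printed half-times from sparse published summary tables are reproducible
  only to within ~5–10 % because the underlying per-animal fitting data are
  not published; the package fits means and documents the tolerance rather
  than tuning to printed values.
- Whether published compartment fractions were fixed a priori or estimated
  is generally unknowable from summary tables; both paths are supported.
- The delta-method ratio SEs assume independent cell means and moderate CVs.
- AICc-based model choice is meaningless at n = 3 and the package refuses to
  do it silently.
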