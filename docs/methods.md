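# Methods

## Stimulus model

Images are classic 2-D gradient noise. A square of side 8.7 cm is divided
into a 3 × 3 grid of cells; at each of the 4 × 4 cell corners a unit
gradient vector is drawn at an angle uniform on [0, 2π). The noise value
at a point is the bilinear blend — in coordinates smoothed by the cubic
ease curve f(t) = 3t² − 2t³ — of the four dot products between corner
gradients and corner-to-point offsets, with offsets measured in cell
units. The field vanishes exactly at every lattice corner; the cubic
(rather than the later quintic) ease curve is the deliberate choice of
the original formulation of the algorithm.

**Pixel calibration.** Physical units are primary: all geometry is in cm
with the origin at the top-left, x rightward, y downward. The pixel
density is configurable (`scale_px_per_cm`, default 40 px/cm, giving
348 × 348 px so that the σ = 0.35 cm target spans ~14 px). Pixel (i, j)
is sampled at its centre ((j+0.5)/s, (i+0.5)/s) cm.

**Luminance mapping.** The raw noise sampled on only a 3 × 3 grid has a
spatial mean that fluctuates appreciably between seeds (the boundary
corner gradients do not cancel). The mapping therefore centres the
sampled field on its per-image mean and applies the symmetric gain
g = 127/max|n − n̄| about the mean level 128:
L = clamp(round(128 + g(n − n̄)), 0, 255). Every image then has mean
luminance 128 (the reference level of the target-polarity rule) and uses
the full 8-bit range. The cost is that lattice corners — where the raw
field is exactly zero — map to 128 − g·n̄ rather than exactly 128; the
zero-at-corner property is asserted on the raw field, not on luminance.

**Artifact screening.** Occasional seeds produce visibly directional
("stripey") textures. As an automated surrogate for screening by eye,
the DC-excluded 2-D power spectrum is summed into 8 orientation bins
over [0, π); the score max/mean bin energy is ≥ 1, near 1 for isotropic
images and near the bin count for gratings. Candidates with score ≥ 2.5
(config-exposed) are rejected and generation continues with the next
sequential child seed. The threshold was chosen so that obvious gratings
fail by an order of magnitude while typical seeds pass; it is a proxy,
not a model of human screening.

**Targets.** A 2-D Gaussian with σ = 0.35 cm (interpreted as a standard
deviation; a FWHM reading would roughly halve the visible size) and peak
amplitude 40, 50 or 60 luminance steps is added at a position uniform
over the image with a 1.0 cm edge margin, so the full scoring disk lies
inside the image. Polarity is positive (bright) iff the base image at
the centre pixel is below 128; the tie at exactly 128 goes to negative.
The per-pixel increment is polarity · round(A·exp(−d²/2σ²)) with d in
cm, so the increment reaches zero beyond d ≈ 1.04 cm at A = 40 — a
visible disturbance about 2 cm across. Pixels driven outside [0, 255]
are clamped and counted; the clamped-pixel count is recorded in the pair
sidecar as a machine proxy for "target invisible in a single image"
checks (it is reported, never silently acted on).

**Presentation formats.** Spatial plans place the two images 3 cm apart
on one canvas (left/right or top/bottom) and name the image that remains
on screen for marking (right for horizontal, top for vertical).
Sequential plans alternate the two images in 400 ms frames separated by
a 200 ms or 0 ms blank, repeated to fill the 30 s search limit (25
cycles of 1200 ms, or 75 frames of 400 ms). Plans are data structures,
not rendered video; timing-accurate playback is out of scope.

## Observer model (synthetic-data generator)

The generator's defaults encode the study conditions: 30 participants,
each seeing 30 pairs (10 per amplitude) in all four formats (3600
trials), with group-level targets

| condition   | total miss | change blindness | time median |
|-------------|-----------:|-----------------:|------------:|
| horizontal  | 23 %       | 7 %              | 9 s         |
| vertical    | 43 %       | 6 %              | 9 s         |
| seq_isi200  | 19 %       | 2.4 %            | 6 s         |
| seq_isi0    | 0.3 %      | 0 %              | 1.5 s       |

The seq_isi0 time median (1.5 s) and the lognormal spread
(sd_log = 0.5) are not published numbers; they encode "fast, effortless
pop-out" and a right-skewed search-time distribution of plausible width.

**Outcome mixture.** Human data cannot distinguish true change blindness
followed by a guessed mark from a correct detection marked imprecisely;
the simulator makes the distinction explicit. A trial times out with
probability p_cb (truncation, not censoring, of the time distribution,
so p_cb alone controls the timeout rate and calibration stays
closed-form). Otherwise a detection time is drawn from a lognormal with
the condition's median, truncated to (0, 30], and the mark is uniform
over the image with probability p_guess, else the target centre plus
isotropic N(0, 0.3² cm²) jitter clipped to the image. p_guess is
recovered in closed form from
m_total = p_cb + (1 − p_cb)·p_guess·(1 − p_chance); p_chance defaults to
the published-convention chance level 0.083. (Uniform guesses actually
hit the 1 cm disk with geometric probability π/75.69 ≈ 0.042, and ~0.4 %
of jittered marks fall outside the disk; both push recovered miss rates
under one percentage point above target — inside the recovery
tolerances and accepted for consistency with the published chance
model.)

**Individual differences.** A general search-ability factor g ~ N(0,1)
loads (λ = 1.0, 0.8, 1.0, 0) on the guess-rate logits of the horizontal,
vertical and 200 ms-ISI conditions, and a vertical-specific factor
s ~ N(0,1) (η = 0.9) adds variance unique to vertical comparisons —
the mechanism for the reported pattern that horizontal and 200 ms-ISI
misses co-vary most strongly while the vertical condition stands apart.
Loadings were chosen to reproduce the correlation *ordering*, not exact
r values (binomial counting noise at 30 trials attenuates and blurs the
latter). Population logits are de-biased numerically (Gauss–Hermite
quadrature + Brent root-finding) so that E[expit(μ + σZ)] equals the
target rate exactly; without this the logistic-normal mixing would
inflate cohort means by 3–4 percentage points. Timeout probabilities
scale proportionally with the participant's guess rate (normalised so
the cohort mean stays on target), so poor searchers both time out and
guess more. A mild monotone amplitude effect multiplies p_cb by
1.15/1.0/0.85 for strengths 40/50/60 (an assumption — nothing
per-strength is published; the multipliers average to 1 over the
stimulus set, leaving calibration unchanged, and can be set to 1).

**What the generator does not emulate:** block order, practice and
fatigue (trials are exchangeable), eye movements and saccade mechanics,
per-pair difficulty, or any dependence of detection time on outcome.
Passing recovery tests shows the scoring/analysis chain is correct and
the calibration self-consistent — not that the generative model is a
faithful process model of human observers.

## Scoring and chance model

Classification is exhaustive and mutually exclusive: timeout if
undetected; else hit iff the mark–target distance is ≤ 1 cm (boundary
inclusive — measure-zero for real data but deterministic); else AOI
miss. Per-participant percentages partition each 30-trial block; mean
detection time is over hits only. Group summaries are means with
t-based 95 % CIs.

The default chance level follows the published area expression
2πr²/side² = 6.28/75.69 ≈ 0.083, which every downstream printed number
(the 0.083 probability, the miss cutoffs) derives from; whether that
expression was intended or is a typo for the circle area πr² is
unresolved, so the geometric convention (`circle`, 0.042) is provided
as a first-class option for corrected analyses. Reproduction is the
default; correction is opt-in.

Binomial significance uses exact tail sums. Sidedness is not stated for
the published cutoff; tail doubling reproduces it (misses below 24 of
30 at α = .05) and is the default, with one-sided and minimum-likelihood
variants available. Only above-chance deviations count toward the miss
cutoff: a two-sided test would otherwise "flag" scores significantly
*below* chance, which demonstrate no localization ability. With this
semantics the cutoff is non-decreasing in α and non-increasing in the
chance probability. The Bayesian counterpart integrates the binomial
likelihood over a Beta(a, b) prior (uniform default; marginal likelihood
1/(n+1)). Under the uniform prior, BF₁₀ > 10 first occurs at 8 hits of
30 — misses below 23 — one trial higher than the published cutoff of
22, whose generating prior/sidedness is unknown; the implementation
exposes the prior parameters and no default claims to reproduce 22.

Imported trial logs with a detection time above 30 s are coerced to
timeouts with a warning (the simulator cannot produce them).

## Inferential statistics

All tests are implemented from their formulas; scipy supplies only
distributions, special functions and quadrature. Cross-checks against
independent implementations (pingouin, statsmodels, brute-force
enumeration, second hand-coded routes) live in the test suite.

- **RM-ANOVA**: two-way decomposition with subjects as blocks;
  F = MS_cond/MS_err, df (k−1, (k−1)(n−1)) — (3, 87) for 30 × 4.
  Uncorrected df by default (matching the published reporting style);
  Greenhouse–Geisser ε optional. The attached Bayes factor is a BIC
  approximation (condition model vs subjects-only null) and is labelled
  approximate in its metadata; reproducing a full mixed-model JZS ANOVA
  BF is explicitly out of scope.
- **Paired t + JZS BF**: two-sided; BF₁₀ integrates the noncentral-t
  likelihood over a Cauchy(0, 0.707) prior on effect size by adaptive
  quadrature (rel. tol. 1e−8). A zero-variance difference with nonzero
  mean reports infinite t with p = 0 and a degeneracy flag.
- **Pearson r + BF**: exact sampling-density integral over a stretched
  beta prior on ρ (width κ = 1 → uniform); BF omitted with a flag at
  |r| = 1. r² (shared variance) is reported alongside r.
- **"N−1" χ²**: (ad − bc)²(N−1)/(mnrs) on the 2 × 2 table, i.e.
  (N−1)/N times Pearson's χ², with df = 1. Fractional counts p·n are
  permitted — the behaviour of the proportions calculator this test
  mirrors, and what reproduces the worked p = .019 for 0 % vs 17 % at
  n = 30 (integer 5/30 gives ≈ .021). Degenerate tables (an empty
  outcome column) return χ² = 0 with a flag.
- **Steiger's z**: Fisher-transformed dependent correlations sharing one
  variable, covariance from the pooled r̄ formula, two-tailed normal p.
  The 3 × 3 correlation matrix is checked for positive
  semi-definiteness.
- **Multiple testing**: post hoc p-values are unadjusted by default (the
  reporting convention the package mirrors); Holm adjustment is
  available by flag and attached to the pairwise results' metadata.

`analyze_experiment` chains the full sequence per metric (omnibus
RM-ANOVA, all pairwise post hocs with BFs), plus per-individual "N−1"
χ² tallies across condition pairs, the between-condition miss
correlation matrix with BFs, and the three dependent-correlation
comparisons; it skips the Steiger block when a tiny cohort yields
|r| = 1 or fewer than four participants.

## Numerical and design choices

- Exact binomial tails and beta-binomial marginals in log space; no
  normal approximations anywhere in the chance model.
- JZS and correlation BFs by `scipy.integrate.quad`; integration
  failure raises with diagnostics rather than returning NaN.
- Seeds: one master seed per pipeline run; stages derive child seeds by
  fixed offsets, candidate lattices use sequential child seeds, and the
  target-placement stream is spawned independently, so re-running one
  stage never perturbs another. A stimulus manifest suffices to
  regenerate every pixel byte-identically.
- Trial logs are CSV with '.' decimals and a mandatory header; floats
  are written with 17 significant digits and parsed with round-trip
  precision, so write-then-read is lossless.
- Test problem sizes: recovery and type-I calibration use 200 replicate
  cohorts of 30 participants × 30 trials × 4 formats; the acceptance
  script averages 60 cohorts. These sizes give Monte-Carlo standard
  errors an order of magnitude below the stated tolerances.

## Known limitations

- The observer model is a calibration device, not a process model; it
  says nothing about eye movements, memory load, or why vertical
  comparisons are harder.
- The RM-ANOVA Bayes factor is a BIC approximation and can differ from
  mixed-model JZS values by orders of magnitude at extreme evidence.
- The published Bayesian binomial cutoff (misses below 22) and the
  published BF₁₀ = 2.5 for t(29) = 1.3 are not reproduced by the
  default derivations here (see above); both discrepancies are
  documented rather than fitted.
- Anisotropy screening is a spectral proxy; a seed a human would reject
  for a subtle artifact may pass.
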