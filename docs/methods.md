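# Methods

## Model

The package treats a latent construct measured on a bounded continuum —
satisfaction with life is the motivating case — as X = 10·Z, Z ~ Beta(α, β),
α, β > 0.  The beta family is flexible enough for the left-skewed shapes
real wellbeing data show (most respondents are positive, with a long lower
tail), is closed under mirror reflection (swapping α and β reflects the
density about 5), and has closed-form moments: mean 10·α/(α+β) and
sd 10·√(αβ/((α+β)²(α+β+1))).  A k-option response scale is modelled as a
partition of [0, 10] by upper boundaries 0 ≤ b₁ ≤ … ≤ b_k = 10; a
respondent with latent score in (b_{i−1}, b_i] reports option i.  A
published frequency table is therefore an interval-censored observation of
X, and every transformation in the package reduces to manipulating the pair
(boundary set, frequency vector).

Assumptions worth making explicit: one homogeneous population per table
(boundaries are population averages, not subgroup-specific); frequencies
are representative of that population; the latent construct itself is
comparable across the surveys being homogenized (same concept, same
population, same period).

## Fitting a beta to boundaries + frequencies

Identifiability by option count: k = 2 leaves one interior constraint for
two shape parameters — undetermined, rejected with an explicit error.
k = 3 gives two constraints F(b₁) = P₁, F(b₂) = P₂ for two unknowns: solved
exactly by root-finding (residual tolerance 1e-9); degenerate cumulative
frequencies (P₁ = 0 or P₂ = 1) collapse the scale to two effective options
and are rejected.  k ≥ 4 is overdetermined and needs a best-fit criterion.

Three criteria are implemented, all comparing observed relative frequencies
p_i with the model's interval probabilities q_i(α, β):

* `chi2` — minimum Pearson chi-square, Σ(p_i − q_i)²/q_i.  **Default.**
* `ml` — maximum likelihood for grouped data, reported as the KL divergence
  Σ p_i log(p_i/q_i) so a perfect fit scores 0; terms with p_i = 0 drop out
  (0·log 0 := 0).
* `cdf_lsq` — Σ(F(b_i) − P_i)² over interior boundaries, a diagnostic
  least-squares criterion on the cumulative scale.

The three agree to high precision whenever the data are actually generated
by censoring a beta distribution (the well-specified case) and typically
differ by a few hundredths of a mean point on real published tables, where
no beta fits exactly.  Minimum chi-square is the default because it is the
classical minimum-distance estimator for grouped frequency data
(asymptotically equivalent to ML) and because its results on the bundled
published tables agree with the printed means of the historical
applications of this method, where ML and `cdf_lsq` land a few hundredths
higher on the 4-option item.  When criteria disagree by more than 0.05 in
mean, report both — the package exposes all three precisely so that this
sensitivity is one function argument away.

Numerics: optimization is over (log α, log β), unconstrained, clipped to
|log shape| ≤ 12.  Start values come from method-of-moments on the
mid-interval discrete distribution (variance clipped into the feasible
region μ(1−μ)); Nelder-Mead with fatol 1e-10 / xatol 1e-9, a unit start and
five jittered restarts (fixed internal RNG — the restarts are part of the
algorithm, not a source of run-to-run variation).  The best of all starts
is returned; non-convergence raises an error carrying the best iterate.

## Classic transforms

Rank numbers, linear stretch (including the %SM = (mean/n)·100 variant on
0–100), fixed word values from a lexicon, and mid-interval values of a
judge-assessed boundary set all produce per-option point values that the
frequency approach turns into a mean and sd.  The sd uses the population
form over relative frequencies; an optional total-count argument applies
the n/(n−1) correction when the weights were counts.  Fixed-word-value
vectors are deliberately not required to be monotone: ignoring scale
context is the method's defining (and criticized) property.  Only the three
published expert values ship with the package ("fairly satisfied" 6.5,
"very happy" 9.3, "not very happy" 3.7); full lexicons are user-supplied
CSV files.

## Reference distribution method

Given a reference beta R (fitted to a deliberately chosen item in a
reference year — ideally an 11-point numeric item fitted under equal-width
boundaries of width 10/k), the boundary below option i+1 of any other item
fielded that year is b_i = R⁻¹(P_i), the reference quantile at the
cumulative frequency through option i.  Cumulative probabilities are
clipped to [1e-9, 1−1e-9] before inversion (the quantile function has
infinite slope at the endpoints for many shapes); the final boundary is 10
by definition, and a zero-frequency first option produces a zero-length
interval with a warning rather than an error.  At least three options are
required — with two, the subsequent refit is undetermined.

By construction, refitting the reference-year table under its own derived
boundaries returns R (the coincidence property); the package asserts this
to within 0.05 in mean across shapes α, β ∈ [1, 8] and k ∈ {4, 5, 7}.  The
flip side is a documented degeneracy: a survey fielded *once* and
transformed against a reference echoes the reference mean exactly and adds
no information; at least two waves are needed before the method says
anything about the survey itself.

Time series: boundaries derived in the reference year are held fixed and
each year is refitted.  Re-anchoring at a design/mode change takes
(bounds, bridge, target): `bridge` is a table measured under the regime
where `bounds` are valid — the double measurement fielded in both designs
during the change year when one exists, else the adjacent year's table
(acceptable when year-to-year movement is small) — and is used to fit a new
reference; `target`, the same-period table under the other design, is
quantile-matched against that reference to obtain its boundary set.  The
choice between double-measurement and adjacent-year bridging is explicit
caller input; the package does not guess.  Overlapping homogenized series
are combined by uniting their year ranges; overlapping years report both
means and their average, flagged.

Reconstruction: when a published analysis prints the boundary column some
reference implied for a known frequency table, the reference itself can be
recovered by fitting the beta CDF through the (interior boundary,
cumulative frequency) pairs — `cdf_lsq` by default, since the pairs are
points on the CDF.  This is an artifact-level tool, not part of the method
proper.  Its precision is limited by the rounding of the published column:
1-decimal boundary columns published for two different scales under the
same reference are generally *not* exactly consistent with any single beta,
and reconstructed tail quantiles (cumulative probabilities below ~0.05)
can be off by 0.1–0.2 on the continuum even when central boundaries
reproduce to the printed decimal.  The bundled cross-consistency test
documents exactly this: the central boundary matches at 1 decimal, the two
tail boundaries differ by 0.14–0.16 from the printed column.

## Synthetic scenarios

The generator emulates the measurement process the method is built for:
one latent beta per year (optionally drifting), one boundary set per
survey, and a multinomial draw of n respondents per wave over the implied
interval probabilities, reported as a frequency table.  An optional mode
shift replaces a survey's boundary set from a given year onward — a
redesign that changes category usage while the latent truth is untouched.
All randomness flows from explicit seeds (waves get sub-seeds from one
root generator); per-respondent latent scores are available behind a flag
but the pipeline consumes only tables.

What it does *not* emulate — and what passing tests therefore do not show
about real data: judge-rating noise in boundary elicitation, item/wording
effects beyond what a boundary shift can express, non-beta latent
distributions, correlated sampling designs, and drift in the boundaries
themselves over time (the method assumes boundary stability between design
changes; the synthetic truth enforces it).

Default study conditions used in the simulation-based checks: waves of
n = 100,000 (national-survey scale), constant truth Beta(6, 3) (left-skewed,
mean 6.67) for the mode-shift scenario, a 9-year drift from mean 6.4 to 7.1
for the two-survey scenario, a 5-option asymmetric scale with boundaries
(3.6, 5.3, 7.2, 8.8, 10.0), a 4-option scale with (3.0, 5.3, 7.9, 10.0),
and an 11-point numeric reference item under equal-width boundaries.
Expected behaviour at these sizes: re-anchored series jump < 0.15 year over
year under constant truth while the naive stretch mean jumps ≈ 0.8 at the
design change; two surveys homogenized against one reference agree within
0.1 in overlapping years.

## Display conventions

All computation is at full precision.  Reported means and boundaries are
rounded half away from zero to 1 decimal *only* in display fields
(`*_display` in CLI reports), matching how such tables are printed (4.45 →
4.5).  Percent weight columns must sum to within [99, 101] — rounded
published tables rarely hit 100 exactly — and anything outside that window
is treated as a transcription error.  Input files may list options in
either order, but the order must be declared; internal storage is always
ascending (least positive first).

## Known limitations

* 2-option scales cannot be homogenized by the continuum or reference
  methods at all, and 3-option scales fit with zero degrees of freedom.
* A single-wave survey transformed against a reference inherits the
  reference's errors systematically (see degeneracy above).
* Boundary stability over time is assumed, not tested, between design
  changes.
* The method corrects for scale diversity only — not for lead-question
  wording, time-frame differences, or multi-item inventories.
* Reconstructed references from rounded published columns carry tail
  uncertainty of order 0.1–0.2 on the continuum.
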