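# shm — scale homogenization for survey rating scales

Survey questions on the same topic — life satisfaction and happiness are
the canonical case — are fielded with wildly heterogeneous response scales:
4-option verbal scales, asymmetric 5-option scales, 11-point numeric
scales.  Their results are not directly comparable, which breaks
cross-survey comparisons and time series whenever a questionnaire changes.
`shm` implements the family of *scale homogenization methods* that map
responses from any such scale onto a common 0–10 continuum, for researchers
who work with published frequency tables (no microdata required).

## Methods

**Frequency approach** (discrete): each option gets a point value v_i and a
table with relative frequencies p_i is summarized by m = Σ v_i p_i,
s = √(Σ p_i (v_i − m)²).  Point values can come from rank numbers
(v_i = i), linear stretch (k equally spaced values with the extremes pinned
to 0 and 10; %SM = (mean score/n)·100 is the 0–100 variant), fixed word
values (context-free expert ratings of labels), or the midpoints of
judge-assessed option intervals.

**Continuum approach**: the latent score is X = 10·Z with Z ~ Beta(α, β),
so X has density f(x|α,β) = [10^(α+β−1) B(α,β)]⁻¹ x^(α−1) (10−x)^(β−1) on
[0, 10].  A response scale is a partition of the continuum by upper
boundaries b_1 ≤ … ≤ b_k = 10 (option i ↔ interval (b_{i−1}, b_i]), making
an observed frequency table interval-censored data.  The fitted shapes give
the transformed moments

    mean = 10·α̂/(α̂+β̂),   sd = 10·√(α̂β̂ / ((α̂+β̂)²(α̂+β̂+1))).

With k = 3 the fit is exact; with k = 2 it is undetermined; with k ≥ 4 a
best fit is found by minimum Pearson chi-square over the interval
probabilities (default), maximum likelihood, or least squares on the CDF at
the interior boundaries.

**Reference distribution method**: instead of judge-assessed boundaries,
the boundary below option i+1 is placed where the CDF of a *reference* beta
distribution (fitted to a deliberately chosen item in a reference year)
equals the cumulative frequency through option i.  Those boundaries are
then held fixed to transform the survey's whole time series; at a survey
design/mode change, a new reference is fitted in the bridge year and the
other side of the change is re-anchored against it.  Overlapping surveys
homogenized against one reference chain can be combined into a single
series.

## Worked example

The package bundles the published 2008 frequency tables and boundary sets
for two Dutch life-satisfaction items (`shm fixtures` lists them).  Export
one and compare every method:

```
$ shm compare-methods --freq eb2008.csv --bounds eb_judges.json \
      --order asc --year 2008 --survey-id Eurobarometer
```

```json
{
  "rows": [
    {"method": "rank",              "mean": 3.472,  "mean_display": 3.5},
    {"method": "linear_stretch",    "mean": 8.24,   "mean_display": 8.2},
    {"method": "context_frequency", "mean": 7.7037, "mean_display": 7.7},
    {"method": "context_continuum", "mean": 7.7279, "mean_display": 7.7,
     "note": "criterion=chi2"}
  ]
}
```

Reading: rank numbers live on the raw 1–4 scale (3.47 is meaningless next
to another survey's 1–5 ranks); linear stretch pins the extremes to 0/10
and says 8.2; using the judges' option intervals instead — midpoints
(7.70) or the best-fitting beta distribution (7.73) — pulls the mean down
to 7.7, because "very satisfied" only occupies the top fifth of the
continuum.  The matching 5-option POLS item gives 5.9 under linear stretch
but 6.9 under the continuum fit: the two surveys disagree by 2.3 points
under naive stretching and by 0.8 once the labels' meaning is modelled.

Deriving boundaries from a reference distribution (here the beta
reconstructed from the published 2008 reference, α≈8.0, β≈2.8):

```
$ shm derive-bounds --ref-alpha 8.01 --ref-beta 2.78 --freq eb2008.csv --order asc
{"upper_bounds_display": [3.7, 4.9, 7.5, 10.0], ...}
```

i.e. quantile matching places "fairly satisfied" at 4.9–7.5 on the
continuum for this item.  `shm transform-series`, `shm reanchor` and
`shm simulate` drive the time-series workflow; see `docs/methods.md`.

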