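# Methods

## Task model

A session presents 24 dual videos, each 60 s, pairing a male and a female
talking head of which exactly one conveys negative information about a
shared topic (six topics: security, health, appearance, social,
employment, safety; four videos per topic). Within a video the two heads
swap sides nine times, producing ten positional arrangements; once per
arrangement a pair of 200-ms probes is flashed, one at each locus, with
necessarily different identities drawn from the eight outer cells of a
3×3 grid (numpad keys 1–4, 6–9; key 5 is the centre and never valid).
The participant reports at most one identity per presentation.

### Counterbalancing

The stimulus set fixes three counts simultaneously: the negative script
is spoken by the male head in 12 of 24 videos; 12 videos start with the
male head on the left; and within each initial-left-gender subset, six
start with negative content on the left. Assigning each topic one video
per (negative-speaker gender × initial-left gender) cell realises all
three exactly, so the counts are invariants of every generated set, not
sampling targets.

### Switch schedules

Inter-switch intervals are i.i.d. on {5, 6, 7} s. Nine such draws can sum
past 60 s, so draws are rejected unless the sum lies in [50, 55], which
makes the tenth (final) arrangement last 5–10 s — the smallest change to
the stated interval alphabet that leaves every arrangement viable. The
sum of nine draws is centred at 54, so rejection is cheap (acceptance
≈ 2/3). Segments are half-open `[start, end)` in seconds from video
onset, and the left-locus valence alternates at every switch.

### Probe timing

Probe onsets are uniform on `[arrangement start + 1.0 s, arrangement end
− 1.5 s]`. The margins are a design choice (the timing of probes
relative to switches is otherwise unconstrained): they prevent a probe
from colliding with a switch and leave response time before the next
one. The shortest arrangement (5 s) leaves a 2.5 s window, so the margins
are always satisfiable.

### Presentation order

The constraint that a topic may not repeat before all five other topics
have appeared since its last occurrence is rigid: once every topic has
appeared, the only topic allowed to recur is the least-recently-presented
one. The valid orders are therefore exactly {topic permutation π repeated
in four rounds} × {within-topic orderings}, i.e. 6!·(4!)⁶ orders.
Sampling π and the within-topic orders uniformly is exactly uniform over
the valid set; naive rejection sampling of full shuffles is infeasible
(no hit in 2·10⁵ attempts), which is why the constructive sampler is
used. A brute-force validity checker is retained and exercised in tests,
including exhaustive enumeration of a reduced two-topic case (8 of 24
orderings valid).

## Scoring

A response matching the negative-locus identity is a negative-locus
identification; matching the benign-locus identity, a benign-locus
identification; anything else — no response, the centre key, or a key
matching neither probe — is unidentified. One response per presentation
is assumed. "Identifying a probe" for the exclusion rule means either
kind of correct identification, and the 80% threshold is inclusive with
denominator 240 (all presentations, responded or not). A participant
with zero correct identifications has an undefined index and is
necessarily excluded; nothing is imputed.

Trait anxiety is the sum of 20 items on 1–4 after reverse-keying the
nine anxiety-absent items (1, 3, 6, 7, 10, 13, 14, 16, 19, 1-based).
The six-item state short form is administered on a continuous 0–100
scale; the per-administration score is the mean of the six items after
reflecting the three anxiety-absent items (x → 100−x), which keeps the
score on the response scale. No aggregation beyond the mean is assumed.
The state-anxiety change score is the mean of the six post-block scores
minus baseline (positive = elevation).

## Reliability

The binary item matrix contains exactly the trials that define the
index: entry (i, j) is 1 for a negative-locus identification, 0 for a
benign-locus one, missing when unidentified, so each row mean equals the
participant's index.

* **KR-20** `= (k/(k−1))(1 − Σ pⱼqⱼ / σ²_X)` with item proportions pⱼ
  over observed entries, missing entries mean-imputed to pⱼ before the
  total-score variance, and population-convention variances throughout.
  The population convention makes KR-20 coincide with Cronbach's alpha
  exactly on complete dichotomous data — an identity the tests verify to
  1e-12 against an independent alpha implementation. Mean imputation
  keeps the matrix complete while conditioning on the same trials as the
  index; missingness is ~7% at the default identification rate.
* **Split-half**: per participant, the index is recomputed within each
  half over identified trials only; halves are correlated across
  participants and stepped up with Spearman–Brown `2r/(1+r)`. The
  odd/even split uses presentation parity. The permutation variant
  partitions each participant's 240 slots into random equal halves,
  independently per participant and permutation, and summarises the
  distribution of corrected coefficients by its mean and 2.5/97.5
  percentiles. Participants with an empty half are dropped from that
  correlation with a warning.

Item "j" refers to the j-th presentation slot, whose content differs
across participants because orders are randomized; trial-level
reliability of this kind treats slots as exchangeable, which the
permutation procedure makes explicit.

## Correlation and mediation

Pearson correlation with the two-sided t test (df = n−2) and the
Cohen's-d equivalent `d = 2r/√(1−r²)`. The mediation model standardizes
all three variables (sample-SD convention) and fits OLS for mediator ~
predictor (a), outcome ~ predictor + mediator (c′, b), and outcome ~
predictor (c); `c = c′ + a·b` holds as an algebraic identity and is
asserted in tests to 1e-10. The indirect-effect CI is a bias-corrected
(no acceleration) bootstrap: cases are resampled with replacement, the
standardized indirect effect recomputed per resample — using the
equivalent correlation algebra `a = r_xm`, `b = (r_my − r_xm r_xy)/(1 −
r_xm²)`, which vectorizes over resamples — and percentile endpoints are
shifted to Φ(2z₀ ± 1.96) with z₀ = Φ⁻¹(fraction of resamples below the
point estimate), clamped away from 0/1 by one resample. An exactly
collinear predictor/mediator pair raises an estimation error rather than
returning one of the infinitely many least-squares solutions.

Coverage behaviour, measured by the test suite: with a true indirect
effect (a = b = 0.3, n = 154) the interval covers the true value at the
nominal 95%; under the complete null (both paths zero) the a·b sampling
distribution is spiked at zero and the interval is conservative
(observed coverage near 1). That conservativeness is a documented
property of indirect-effect bootstrap intervals, not a defect, so the
null-coverage test asserts a lower bound at the nominal level.

## Simulator

Per respondent: latent bias θ and trait anxiety are jointly Gaussian
(correlation `rho_latent`) before truncation of θ to (0, 1) and of the
trait score to [20, 80] (then discretized to the integer sum scale);
identification ability δ is truncated normal on (0, 1]. Per
presentation: the attended locus is negative with probability θ, an
identification occurs with probability δ, and an identified probe is
always the attended-locus one (no cross-locus leakage), so E[I | θ] = θ
and the index variance decomposes as latent variance plus mean binomial
error `ī(1−ī)/(δ̄·n_trials)`. `calibrate_from_descriptives` inverts that
decomposition: from observed index mean 0.48, SD 0.13, identification
rate 0.9326 and 240 trials it returns latent SD ≈ 0.1256, implying a
true-score variance fraction ≈ 0.93 — which is why calibrated cohorts
reproduce KR-20/split-half values in the low 0.9s.

Questionnaire generation writes raw items whose keyed scores equal the
latent targets: trait items are a random composition of the target sum;
state items carry zero-sum jitter so the keyed mean equals the target
exactly except under boundary clipping. State targets are baseline ~
N(35, 12) clipped to [0, 100] plus an elevation `4.83 + 2.5·z_θ + u`,
u ~ N(0, 11.3), plus per-block noise N(0, 8); the implied change-score
moments are mean 4.83 and SD √(2.5² + 11.3² + 8²/6) ≈ 12.0. The default
latent trait–bias correlation 0.207 is the disattenuation of an
observed correlation of 0.20 at reliability 0.93 (`r/√reliability`).
Baseline mean/SD are modeling choices (only the change score has stated
moments); all other defaults are the printed descriptives.

The simulator emulates stationary, exchangeable trials. Real data also
contain learning and fatigue across blocks, topic-content effects,
reaction-time structure, and possible cross-locus identifications —
none of which are modeled — so passing tests show the estimators behave
correctly under the task's own measurement model, not that any given
human cohort satisfies that model.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 154 (matching the retained
sample the descriptives refer to), 25 replicates for the KR-20 average,
10,000 permutations/bootstrap resamples for the headline quantities, and
reduced resampling counts (50–1,000) inside property suites, with large-n
identities checked at n = 5,000. All randomness flows from
`numpy.random.default_rng` seeded per run; replicate seeds are spawned
from a single seed sequence and kept below 2³¹. Percentiles use numpy's
default (linear) interpolation. Degenerate inputs (zero variance,
empty halves, collinearity, sub-floor observed variance in calibration)
raise typed errors rather than returning NaN.

## Known limitations

* The exclusion denominator is fixed at 240 presentations; if the
  original logs dropped technically invalid trials first, the boundary
  cases could differ.
* The state-scale aggregation (mean of keyed items) is one reasonable
  choice; any affine variant rescales the change score without altering
  standardized analyses.
* KR-20's mean imputation treats unidentified presentations as missing
  at random given the item; respondents near the exclusion boundary
  violate this mildly.
* The mediation bootstrap standardizes within each resample; intervals
  on the raw-scale indirect effect would differ by the SD ratio.
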