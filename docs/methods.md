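# Methods

`msea` implements two complementary statistics for locating and quantifying
somatic-mutation hotspots on protein-coding transcripts, plus the simulation
harness used to characterize their power and type-I error. This note records
the models, the defaults and why they are what they are, the numerical
choices, and the known limitations.

## The clustering statistic

Each transcript is analyzed as a unit. Let `L` be its amino-acid length and
`Y = (y_1, …, y_L)` the per-position counts of mutation records (one record =
one mutation in one sample; recurrent mutations contribute multiple records
at one position). A walker traverses positions 1..L keeping a mutation
accumulation score (MAS), starting at 0:

- at a mutated position `j` the score rises by `y_j · S_inc`, with
  `S_inc = 1 / ΣY`;
- at a non-mutated position it falls by `S_dec = 1 / #non-mutated positions`.

Total rise and total fall both equal 1, so `MAS_L = 0`: the curve is a bridge,
and a sharp climb marks a cluster. The mutation enrichment score is

    MES = max(MAS) − min(MAS)

and the hotspot interval is the stretch over which the curve climbs from its
minimum to its maximum. Conventions the definition leaves open, fixed here:
extrema take the first (leftmost) occurrence; when the minimum precedes the
maximum the interval is `[argmin+1, argmax]` (the positions actually driving
the climb), otherwise `[argmax, argmin]`; endpoints are clamped to `[1, L]`.

Significance comes from a randomization null: each replicate redraws `ΣY`
record positions uniformly **with replacement** over 1..L (replacement keeps
recurrent pile-ups representable) and recomputes MES. With `n_perm`
replicates,

    NES = (MES − mean(MES_π)) / sd(MES_π)
    p_emp = #{MES_π ≥ MES} / (1 + n_perm)

`n_perm` defaults to `10·L`, floored at 1,000 for short transcripts so that
the null moments behind NES stay stable. The empirical p follows the counting
formula literally and can be exactly 0; a conventional
`(1 + #{≥})/(1 + n_perm)` variant is available behind `pseudo_count=True`
(default off). Replicates that happen to cover every position (possible only
when `ΣY ≥ L`) leave `S_dec` undefined and are redrawn.

Randomness is controlled by one master seed per run; each transcript gets a
child seed derived by hashing `(master seed, transcript_id)`, so results are
independent of processing order.

### Background adjustment and calibration

Two safeguards use the scenario's background (silent) mutation set:

1. **Silent-hotspot veto.** A transcript whose silent mutations themselves
   form a hotspot at nominal p < 0.05 keeps its statistics but is flagged and
   excluded from the significant list. Backgrounds with fewer than 4 records
   (the same bar as working-set eligibility; the bar is a declared choice)
   are untestable and never veto.
2. **Pooled empirical null.** Background NES values from all transcripts are
   pooled, median-centered, and a normal null `f0 = N(mu0, sigma0)` is fitted
   by truncated-normal maximum likelihood on the central 90% of the sample:
   the window is fixed at the empirical 5%/95% quantiles and the optimizer is
   iterated (warm restarts) until both parameters move by less than 1e-6.
   Observations in the excluded tails — where genuinely selected background
   sets would sit — never enter the fit, which is what makes the estimate
   robust to tail contamination. Window fraction and tolerance are exposed in
   the API. An alternative scheme that re-derives the window from the fitted
   normal each round was evaluated and rejected: it has an attracting
   two-cycle (the window edge hops across individual observations) and is
   chaotically sensitive to floating-point noise, which breaks shift
   equivariance of the calibration.

   Working NES values, also median-centered, are standardized against `f0`
   and converted to one-sided upper-tail normal p-values (clustering is a
   one-directional alternative). When fewer than 50 background NES values are
   available the run falls back to raw empirical p-values and is prominently
   marked uncalibrated rather than failing.

   A caveat the simulations quantify: for transcripts with few mutations the
   cross-transcript NES null is right-skewed (skew ≈ 0.5 at 8 records on
   L = 500), so a location–scale normal calibration controls the 0.05
   rejection rate (≈ 0.05 measured on 500 pure-null transcripts) but cannot
   make the calibrated p exactly uniform over (0,1). The empirical
   randomization p, which is uniform by construction, is the right quantity
   for judging overall inflation; the calibrated p drives ranking and
   significance calls.

Benjamini–Hochberg adjustment is applied across transcripts, and each gene is
represented by its most significant transcript (ties break to the
lexicographically smallest transcript ID). Default significance cutoffs:
adjusted p < 0.05 for the clustering test, < 0.2 for the domain test (its
min-over-models p is deliberately anti-conservative and eligible-gene counts
are smaller); both are configuration.

## The domain mutation-rate test

The hypothesis-driven test asks whether counts are elevated inside annotated
domains. With `X` a binary region indicator of length `L`:

    h0: E(Y|X) = exp(β0)          h1: E(Y|X) = exp(β0 + β1·X)

Counts are sparse and zero-heavy, so `Y` is modelled as negative-binomial
(NB2, `Var = μ + α·μ²`) rather than Poisson; `α` is a per-model nuisance
estimated by maximum likelihood, not counted in the test's degrees of
freedom. The likelihood-ratio statistic `2(llf_h1 − llf_h0)` is referred to
chi-square with 1 df. The test is two-sided in `β1`; the sign is reported and
depleted-domain hits are annotated, but not filtered, in the output.

Because domains overlap, three indicator constructions are tested per
transcript: each domain alone (M1), maximal merged runs of overlapping
domains (M2 — merging requires at least one shared position; touching
intervals stay separate), and the union of all domains (M3). Constant
indicators (a domain covering the whole protein) are unidentifiable and
dropped with a logged reason. The transcript-level p is the minimum over all
indicators, with provenance; ties break M1 < M2 < M3, then lexicographically.
Min-selection makes the transcript-level p anti-conservative, which is why
the relaxed 0.2 adjusted-p cutoff exists for this test.

### Numerical details of the NB fit

The NB2 log-likelihood is written with the log-gamma ratio
`lgamma(y+r) − lgamma(r)` expanded as `Σ_{k<y} log(r+k)` for integer counts,
which stays exact as `r = 1/α → ∞`; together with `log1p(μ/r)` terms this
makes the likelihood stable over `α ∈ [1e-8, 1e4]` and lets the fit collapse
cleanly onto the Poisson likelihood at the boundary (agreement ≤ 1e-6 in
log-likelihood). Optimization is bounded L-BFGS-B from several starts
(null slope and group-means slope, dispersions 0.5 and 1e-6); `β1` is capped
at ±20 on the log scale so complete separation (all mutations inside the
region) stays finite. The flat dispersion ridge near the Poisson boundary
occasionally ends a gradient line search abnormally; a run is accepted when
any start converges to the shared optimum, and a simplex polish certifies the
rare cases where none does. Non-convergence is reported per indicator
(`converged=False`, p set to 1) instead of dropping the transcript.

## Mutation sets and eligibility

Records carry one of six classes (silent, missense, nonsense, frameshift
indel, in-frame indel, splice) and an optional precomputed deleteriousness
flag (external predictors; a missing flag is treated as benign, with a
run-level warning when a deleteriousness-filtered scenario is used). Working
versus background partitions follow the named scenarios: six for the
clustering test (NS/S, (del NS)/S, (del NS)/Splus, (NS+I)/S, (del NS+I)/S,
(del NS+I)/Splus — "Splus" backgrounds add benign missense SNVs to silent
SNVs) and four working sets for the domain test (NS, del NS, NS+I, del NS+I).
Splice records count as non-silent when they carry a valid amino-acid
position — a declared policy, since annotation pipelines differ on giving
splice variants a protein position. Indels are assigned the single position
of their first affected residue; multi-residue spread is not modelled because
the count vector never splits one record across positions.

Eligibility requires at least 4 working records per transcript; the domain
test additionally requires at least one usable (non-constant) indicator.
Positions are 1-based inclusive throughout. Records are deduplicated on
(transcript, position, class, change string, sample). The S/NS ratio is
computed on SNVs only (silent / (missense + nonsense)); splice records are
excluded because the class does not separate splice SNVs from splice indels.

## The simulation harness

The generator reproduces the conditions under which the methods were
characterized, and its defaults are those conditions:

- **Clustering scenarios** — protein length `L = 500` (RefSeq proteins
  average 559, median 429); spanning-window lengths 10/50/100/200/300;
  4 or 8 mutations (the eligibility bar is 4); window starts swept evenly so
  the windows cover the sequence (capped at 10 locations); recurrence on or
  off (with replacement vs. distinct positions); 100 replicates per cell;
  power = fraction of replicates with the per-transcript empirical p < 0.05.
- **Domain scenarios** — a single domain of length 100/200/300/400 (annotated
  domains median 92, mean 136), centered in an `L = 500` protein by default
  (a declared default — the length condition is stated only for the
  clustering study; both are sweepable); mutations placed uniformly in one of
  the four domain quarters (boundaries rounded half-up), the whole domain,
  or — as the type-I null mode — uniformly over the whole protein; power uses
  the min-over-models transcript p.

Generated records are missense with synthetic sample IDs and flow through the
identical I/O, profile-building and eligibility path as real data. Every
replicate is reproducible from `(seed, rep)`; non-recurrent draws use uniform
sampling without replacement (distribution identical to rejection sampling).
Power simulations run no pooled calibration: each replicate is a
single-transcript experiment, so the clustering power is defined on the
empirical randomization p.

What the generator does **not** emulate: covariation of mutation rate with
expression and replication timing, transcript-length and mutation-load
heterogeneity across a cohort, annotation-version mismatches, sequencing
artifacts, and non-uniform background mutability along a transcript. Passing
simulation checks therefore demonstrates correctness of the statistics under
the stated null and planted-cluster models, not robustness to those
real-data effects.

Problem sizes used by the shipped checks — 100 replicates per power cell,
500 transcripts for the null-calibration cohort, 200 transcripts (20 planted)
for the recovery cohorts, 1,000 random profiles for the conservation
property — are the package's chosen defaults for a reproducible desk-scale
characterization; all are sweepable upward through the same API.

## Known limitations

- Nonsense and frameshift mutations in tumor suppressors scatter rather than
  cluster; neither statistic is designed to detect them.
- The domain test loses power on highly recurrent single-codon hotspots: a
  recurrent pile-up inflates the fitted dispersion under h0, so the domain
  indicator adds little likelihood — the clustering test is the sensitive one
  there. With few mutations and a domain covering most of the protein, the
  best attainable LRT p can exceed 0.05 (complete separation caps the
  likelihood gain), giving zero power in that corner of the grid.
- The calibrated p is not exactly uniform under the null for low mutation
  loads (NES skew; see above); rankings and 0.05-level error control are
  unaffected in the simulated conditions.
- Fusion breakpoints, regulatory regions and weighted (impact-scored) walks
  are out of scope.
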