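# Methods

This note documents the models and procedures implemented in
`srmbuilder`, the parameters that matter, the design decisions taken
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Input model

The pipeline consumes long-format transition-level quantification
reports: one row per (protein, modified peptide sequence, precursor
charge, product ion, replicate) carrying an integrated chromatographic
peak area (arbitrary units) and an apex retention time (minutes). This
is the shape of the per-transition export produced by chromatogram
extraction after a peptide-centric DIA search, regardless of which
software produced it; the reader accepts CSV or TSV with a configurable
column map rather than binding to one vendor schema. Modified sequences
are opaque identifiers — no masses are recomputed, because the workflow
selects among transitions that were already characterized upstream.

## Interference QC

Co-elution is formalized as a median-deviation rule. For one peptide in
one replicate, the consensus apex is the median of its transitions'
apex RTs; transition *i* is flagged iff `|apex_i − median| > τ`.
Defaults: τ = 0.1 min. A transition is *clean* iff unflagged in every
replicate (strict AND): a transition unreliable in any replicate is
unreliable for a targeted assay.

Properties of this rule, all tested: it depends only on relative apex
positions (invariant to a global RT shift); widening τ never flags more
transitions; a single transition is never flagged (co-elution is
undefined); with two transitions the median is their midpoint, so both
are flagged when they disagree by more than 2τ — with no third witness
there is no way to arbitrate, and symmetric rejection is the
conservative choice. The median consensus tolerates a minority of
interfered transitions of either sign; when half or more of a peptide's
transitions are corrupted the consensus itself is not trustworthy, and
no local rule can recover that case.

## Normalization and stability scoring

Replicate loading differences are corrected by total-ion-current (TIC)
normalization: each area is multiplied by (mean replicate total)/(own
replicate total), which equalizes per-replicate totals. Note the
normalization target is itself data-dependent: rescaling one replicate
by *c* changes every normalized value by one common factor (the new
mean total) while leaving all ratios, intensity ranks and %CV values
exactly unchanged — which is the invariance that matters downstream.

Per peptide, clean transitions are ranked by mean area across
replicates (ties broken by ascending product m/z then ion label). The
top `min(N, clean count)` transitions — one fixed set, never re-ranked
per replicate — are summed within each replicate, and the percent
coefficient of variation of the sums is computed with the sample
(n−1) standard deviation, the standard small-sample convention at 3
replicates. Peptides observed in fewer than two replicates are marked
non-quantifiable. The mean (rather than, say, a single reference
replicate) is used for transition ranking as the most stable summary of
three replicates.

## Selection rules

The quantifiability filter keeps peptides with at least
`min_clean_transitions` (default 3) clean co-eluting transitions and
%CV within `cv_threshold_pct` (default 20; inclusive `≤` by default,
strict `<` available as `cv_comparison: lt`).

Per protein the ranked rules are: (1) when more peptides qualify than
the `n_peptides_per_protein` (2) to be kept, only the
`top_k_peptides_by_intensity` (5) by mean summed area are considered —
with `n_peptides_per_protein` or fewer candidates everything is kept
directly; (2) from that pool the `n_peptides_per_protein` with the
lowest %CV are selected; (3) each selected peptide carries its
`n_transitions_per_peptide` (5) most intense clean transitions in rank
order. Proteins with fewer than `require_min_peptides_per_protein`
qualifying peptides (default 1; set 2 for panels that demand
two-peptide support) are dropped and written to a log with a reason
(too few qualifying peptides / too few clean transitions / %CV above
threshold — when a protein's peptides failed for mixed reasons the
clean-transition deficit is reported first).

Two conventions make selection a pure function of its input: all ties
break lexicographically (peptide sequence, then product m/z), and when
one sequence was measured at several precursor charge states only the
more intense precursor enters selection (peptides, not precursors, are
the selection unit). The implementation is verified against an
independent exhaustive-enumeration oracle (minimize the CV sum over all
subsets of the intensity pool, lexicographic tie-break) on thousands of
random instances, including tie-heavy ones.

## Retention-time calibration and scheduling

Standards with known iRT values spiked into every sample anchor a
linear map `RT = a·iRT + b`, fitted by ordinary least squares
(`scipy.stats.linregress`); the fit reports RMSE and the slope's
standard error, and refuses to fit on fewer than two distinct iRT
values. Assay targets get their iRT by inverting the calibration fitted
on the DIA-side standards at the peptide's median apex RT; scheduling
onto the SRM gradient re-projects those iRTs through a second
calibration fitted on the same standards as measured on that setup.
Both directions use the same fit.

Each target is acquired for `window_min` (5) minutes centred on its
predicted RT, clipped to `[0, gradient_length]` (default 60 min);
fully out-of-gradient predictions are clipped to the boundary and
reported as warnings. Collision energy is the standard charge-dependent
linear ramp `CE = slope(z)·m/z + intercept(z)` rounded to 0.1 eV, with
shipped defaults (2+: 0.03·m/z + 2.905; 3+: 0.038·m/z + 2.281, higher
charges falling back to the highest defined) kept as editable
configuration because these coefficients are instrument-specific.

Concurrency is counted by a sweep over sorted window endpoints with the
half-open convention `[start, end)` (abutting windows do not overlap);
standards are conservatively modelled as monitored across the whole
gradient in every method, so their transitions count everywhere. The
sweep is verified against a dense-grid (0.01 min) counting oracle.
Partitioning into methods uses greedy first-fit in predicted-RT order:
deterministic, near-optimal on overlapping-interval instances, and not
claimed minimal; every emitted method is checked feasible
(`peak ≤ max_concurrent_transitions`, default 200) and the transition
multiset is conserved exactly, with the full standard set replicated
into each method. Method count is non-increasing in capacity (tested).

## Synthetic data

The generator emulates the triplicate DIA screen the pipeline consumes:
lognormal peptide base abundances (log-mean 13 ≈ 4×10⁵ a.u., log-SD 1),
transition intensities decaying geometrically over rank (ratio 0.7,
chosen so "top 5 most intense" is well separated and tests are free of
fragile ties), a linear iRT→RT model (defaults 0.5 min/iRT + 5 min over
iRT ∈ [0,100], i.e. elution between 5 and 55 min of a 60-min gradient)
with Gaussian apex jitter, and three replicates.

Two planting choices are deliberate and worth understanding:

* **Replicate noise is planted, not sampled.** The multiplicative noise
  acts at the peptide × replicate level (a whole peptide's transitions
  rise and fall together, as injections do) and each peptide's
  log-multipliers are standardized so the planted log-scale scatter
  equals `noise_cv` exactly. At three replicates an i.i.d. noise draw
  would give the *estimated* %CV a wide sampling distribution whose
  median sits ≈17% below the truth, making parameter-recovery
  assertions about the estimator meaningless; planting the dispersion
  makes "%CV recovers `100·noise_cv`" a sharp, testable statement.
  Real data keeps the sampling spread: passing this recovery test shows
  the estimator computes the right statistic, not that three replicates
  pin down a peptide's true CV.
* **Unstable peptides decay monotonically.** A planted-unstable peptide
  is modulated by `exp(±unstable_extra_cv)` linearly across replicates —
  the signature of degradation in an autosampler across days, which is
  precisely what the replicate %CV screen exists to catch — plus the
  ordinary noise. With the default 0.6 this yields ≈55–60% CV, failing
  a 20% screen for every seed.

Interfered transitions get their apex shifted by
`±interference_shift_min` in all replicates (alternating sign), capped
at ⌊(m−1)/2⌋ per peptide so the median consensus stays anchored.

The generator emits areas post-integration; raw chromatograms, isotope
envelopes, digestion kinetics, and peptide-to-protein inference are out
of scope. Consequently the tests demonstrate the pipeline's logic and
statistics, not chromatographic peak picking.

### Panel presets

`preset_pain_panel(seed)` plants an 87-protein candidate panel: 2
proteins undetected; 67 of the 85 detected carry 3 peptides × 6 clean
transitions at ≈3% CV (passing a screen of ≥2 peptides with ≥5 clean
transitions and %CV ≤ 20); 18 fail, cycling deterministically through
the three failure modes (single qualifying peptide / two interfered
transitions leaving only 4 clean / unstable peptides). Because failures
are planted by construction (deterministic decay, large apex shift, low
3% noise), the per-stage counts — and the resulting 134-peptide,
670-transition assay — are identical for every seed, while sequences,
intensities and retention times still vary with the seed.

`preset_ad_panel(seed)` plants 180 candidates (10 undetected, 74 with a
single peptide, 96 with two well-behaved peptides) plus a synthetic
reference list that shares both peptides for 25 proteins: selection
yields 192 peptides, 50 shared, 74.0% uniquely selected, exercising the
overlap report end to end.

## Numerical and degenerate-input conventions

Delimiters are auto-detected between comma and tab; decimal points
only. Structural file faults (missing column, unparseable numeric,
duplicate key) raise typed errors naming the column/row; value-domain
violations (negative area, non-positive m/z) divert rows to a rejects
table with row numbers — no row is ever silently dropped. m/z values
are exported with 4 decimals, RT and CE with 2. Exit codes: 2
configuration, 3 data, 4 capacity.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data at desk scale: the panel presets are a few thousand report rows,
oracle comparisons use ~1000 random selection instances (≤10 proteins ×
≤8 peptides) and 200 random schedules against a 0.01-min grid, and the
recovery studies use 100 seeds (interference, calibration) and 500
peptides (%CV). The full suite completes in well under a minute.

## Known limitations

Greedy partitioning is not optimal and makes no attempt to flatten the
concurrent-target density across the gradient. The interference rule is
a deliberate re-specification of "peak apex not co-eluting" as a median
deviation test — upstream search engines use richer chromatogram-shape
evidence. No proteotypicity check against a proteome database is
performed, no limit-of-detection/quantification estimation, and no
matrix-matched calibration; peptide identity is string equality on the
modified sequence.
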