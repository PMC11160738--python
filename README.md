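# srmbuilder

Develop scheduled SRM (selected reaction monitoring) assays for
triple-quadrupole mass spectrometers directly from replicate DIA
(data-independent acquisition) experiments.

## The problem

A targeted bottom-up proteomics assay measures a protein through a few
proxy peptides, each monitored as precursor → product-ion pairs
("transitions"). Picking peptides that respond well *in the matrix of
interest* is the expensive step of assay development. Replicate
narrow-window DIA runs of a pooled sample already contain the needed
evidence: which peptides are detectable, which transitions co-elute
without interference, how stable each peptide's signal is across
replicates, and a retention-time index (iRT) for scheduling.
`srmbuilder` turns such replicate transition-level reports into
instrument-ready, retention-time-scheduled transition lists.

## The method

For each peptide with transitions across `R` replicates (typically 3):

1. **Interference QC** — within each replicate the consensus apex is the
   median apex RT over the peptide's transitions; a transition is flagged
   when `|apex − median| > τ` (default τ = 0.1 min), and *clean* only if
   unflagged in every replicate.
2. **Stability** — per replicate, the areas of the peptide's top-N clean
   transitions (one fixed set, ranked by mean area; N = 5) are summed
   (after TIC normalization), and the percent coefficient of variation
   `%CV = 100·s/x̄` (sample SD, n−1) is computed over the replicate sums.
3. **Filter** — keep peptides with ≥ 3 clean co-eluting transitions
   (configurable) and %CV ≤ 20.
4. **Select** — per protein: when more peptides qualify than will be
   kept, consider only the top 5 by summed intensity, then keep the 2
   with the lowest %CV; each carries its 5 most intense clean transitions.
5. **Schedule** — fit `RT = a·iRT + b` by least squares over spiked-in
   standards, centre a 5-min window on each target's predicted RT,
   assign charge-dependent linear collision energies
   (`CE = slope·m/z + intercept`), and partition targets greedily
   (first-fit in RT order) into as many methods as needed to keep the
   peak number of concurrent transitions ≤ 200, standards included in
   every method.

A seeded synthetic-data generator (`srmbuilder.synth`) plants ground
truth — interfered transitions, unstable peptides, pass/fail protein
panels — so the whole pipeline is testable without any instrument data.

## Worked example

Simulate a chronic-pain protein panel (87 candidate proteins; 2
undetectable, and 18 of the 85 detected planted to fail the screen),
then build the assay requiring 5 clean transitions and 2 peptides per
protein:

```sh
srmbuilder simulate --preset pain_panel --seed 7 --out demo/sim
srmbuilder build-assay --report demo/sim/report.csv \
    --standards demo/sim/standards_dia.csv \
    --min-clean-transitions 5 --require-min-peptides-per-protein 2 \
    --out demo/assay
```

```
input_rows: 4158
rejected_rows: 0
detected_peptides: 231
detected_proteins: 85
qualifying_peptides: 207
qualifying_proteins: 73
selected_peptides: 134
selected_transitions: 670
dropped_proteins: 18
```

67 proteins pass with 2 peptides × 5 transitions each: **134 target
peptides, 670 target transitions**. `demo/assay/dropped_proteins.csv`
explains every exclusion (too few qualifying peptides, too few clean
transitions, or %CV above threshold). Scheduling the assay onto a
different (SRM-side) gradient via its own standards file:

```sh
srmbuilder schedule --assay demo/assay/assay.csv \
    --standards demo/standards_srm.csv --out demo/methods
```

```
 method  n_targets  n_transitions  peak_concurrency  peak_time_min  rt_start_min  rt_end_min
      1        134            709               169          30.57          3.41       47.92
wrote 1 method file(s) to demo/methods
```

All 670 target transitions plus 39 standard transitions fit in a single
method: the peak concurrency (169 transitions open at 30.57 min) stays
below the 200-transition capacity, so no split is needed. Lower
`--max-concurrent-transitions` and the partitioner emits multiple
methods, each containing the full standard set.

The `ad_panel` preset demonstrates assay-overlap comparison
(`srmbuilder compare`): 96 two-peptide proteins give 192 selected
peptides of which 50 are shared with the reference list — 74.0%
uniquely selected.

## Library use

```python
import srmbuilder as sb

rep = sb.generate_report(sb.preset_pain_panel(7))
cfg = sb.SelectionConfig(min_clean_transitions=5, require_min_peptides_per_protein=2)
qc = sb.qc_summary(rep.report, cfg.apex_tolerance_min)
summaries = sb.summarize_peptides(sb.tic_normalize(rep.report), qc, 5)
result, kept, rejected = sb.build_targets(summaries, cfg)
len(result.targets)   # 134
```

See `docs/methods.md` for the model, parameter and design details.
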