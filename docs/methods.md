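# Methods

## Signal model and slope extraction

The kinetic model underlying the whole kinome stage is that a reporter
peptide's fluorescence grows linearly with incubation time while the
kinase reaction is far from substrate saturation, and that CCD counts are
proportional to exposure time. The generator enforces this by
construction: observed intensity = `background + v·m·t·(e/100 ms)`, with
`v` the peptide's baseline phosphorylation velocity (intensity/min at the
100 ms projection), `m` the product of planted activity multipliers, `t`
cycle time and `e` exposure. The extraction stage assumes only the same
two linearities.

**Exposure fusion.** The instrument does not document how its four
exposures are combined. We fit a through-origin regression of intensity
on exposure within each cycle and evaluate it at 100 ms
(`100·Σ(e·I)/Σ(e²)`). This uses all four channels, weights the
best-exposed (largest `e`) observations most, and is robust to a single
saturated channel; a config switch (`exposure=e`) selects one channel
rescaled by `100/e` instead. An additive background contributes a
time-constant offset after fusion, so it moves the kinetic intercept, not
the slope.

**Kinetic fit and R².** Ordinary least squares of fused intensity on
cycle time, per peptide × sample. R² is the coefficient of determination
of this *time* regression — the "undetectable and nonlinear" criterion
refers to signal development over time, not to the exposure fit.
Conventions at degeneracy: zero residual variance → R² = 1; zero total
variance (flat trace) → slope 0, R² = 0. Fewer than two distinct cycle
times is an error, not a silent zero.

**QC.** `qc_pass = (R² ≥ 0.80)` with the boundary inclusive (the exclusion
rule is stated as R² *below* 0.80). Slopes are floored at
`slope_floor = 1e-6` intensity/min before any ratio is formed:
phosphorylation velocity cannot be negative and a zero denominator would
make FC undefined. Peptide exclusion is scoped per comparison: a peptide
failing QC in any sample of a comparison is dropped from that comparison
(both groups), because a ratio needs two valid terms.

## Fold changes and thresholds

FC is the ratio of group means of the floored signals (ratio-of-means;
replicates are unpaired chips, so this is the stable choice;
mean-of-ratios is available for sensitivity checks). Differential:
FC ≥ 1.30 or ≤ 0.70, both inclusive. Note the pair is not exactly
reciprocal (1/1.30 ≈ 0.769), so the up/down sets under a group swap are
exactly exchanged only for reciprocal thresholds; the swap tests use
`down = 1/up` where exactness is asserted. Percent activity change is
reported as `(2^mean_log2FC − 1)·100`.

## Upstream-kinase statistics

The null draws `n_diff` peptides uniformly without replacement from the
comparison's QC background — the universe the experimental hits actually
came from, not the full chip — 2000 iterations by default. Retention
requires ≥ 3 substrates in the background (prevents near-zero null means
from dominating). The batch analyzer shares one set of 2000 draws across
kinases: each kinase's marginal null is identical to per-kinase sampling,
and the per-kinase `sampling_null` entry point with its own seed remains
for oracle and determinism checks. Null sd uses the sample estimator
(ddof = 1); the exact hypergeometric mean `nK/N` and variance
`n(K/N)(1−K/N)(N−n)/(N−1)` serve as the independent oracle, plus full
subset enumeration for tiny backgrounds.

Degenerate cases carry explicit flags, never silent division:

* `sd_null = 0`: z = 0 if observed equals the null mean, else a signed
  infinity sentinel flagged `unstable_z`;
* `mean_null = 0` with observed = 0 (e.g. an empty differential set):
  Δ confidence = 1 flagged `degenerate_null` — the kinase sits exactly at
  its (trivial) null expectation. This limit convention is what makes
  null-calibration summaries well defined on no-effect runs, where under
  the reference conditions the differential set is empty in almost every
  run (triplicate averaging puts the 1.30/0.70 thresholds several noise
  SDs from 1);
* `mean_null = 0` with observed > 0: Δ = NaN, flagged `undefined_delta`;
* no QC-passing substrate fold changes: flagged `no_substrate_fc`.

`mean_substrate_log2fc` averages over ALL QC-passing substrates of the
kinase in the comparison, not only differential ones — the average-activity
line of a per-substrate MEOW panel. Up- and down-differential peptides are
pooled for hit counting. The kinome summary exports, per kinase, the
median z as `color_value` and the mean |MEOW| as `size_value` — documented
analogues of the proprietary "kinase statistic" and "final score" used for
kinome-tree node color and size; we emit the node-attribute table and
leave tree drawing to external tools.

## Transcriptome contrasts

Gene filter: FPM = count/library_size·1e6 ≥ 5 (inclusive) in at least
⌈0.75·n⌉ samples. Significance for the partition is strict padj < .05.
Shared genes split by sign of the two log2FCs; a shared gene with log2FC
exactly 0 on either side is a measure-zero degenerate case reported in a
separate `shared_flat` bucket and counted in `shared_total`. The
dependence score is the raw difference `log2FC_b − log2FC_a` (the printed
equation; no significance weighting), ranked with lexicographic gene-id
tie-breaks so top/bottom lists are deterministic; `top_n` beyond half the
universe is truncated with a warning so the lists cannot overlap.

Enrichment is a local hypergeometric upper-tail test against a
user-supplied GMT, BH-adjusted across the tested pathways. The
"amalgamated enrichment score" is instantiated as
`AES = n_overlap · (−log10 padj)` — monotone in both of its stated
components (overlap size, significance). This combiner is an
interpretation, exposed as a pluggable function (`aes_fn`), since no
closed form is published.

## Synthetic generator: what it emulates, what it does not

Defaults are the study conditions: STK 144 / PTK 196 panels; 13 cycles at
0–60 min; exposures 10/20/50/100 ms; 2 genotypes × 3 treatments ×
3 replicates; 20 kinases with 5–15 substrates and overlap fraction 0.3;
baseline velocities log-uniform over [1, 100] (≈ two decades of dynamic
range, as on real arrays); intensity CV 0.1; additive background 50;
saturation ceiling off by default (applied after noise when on). Peptides
targeted by several affected kinases combine multipliers multiplicatively
(simplest composable rule; `combine_multipliers="max"` available). One
global seed spawns fixed per-stage child streams, so each stage is
independently reproducible.

Contrast tables plant exact category truth: effect genes draw
log2FC ~ N(±effect, null_sd) with padj ~ U(0, 0.01); null sides draw
log2FC ~ N(0, null_sd) with padj ~ U(0.05, 1). Keeping null padj above
the significance cutoff is deliberate — a planted-truth generator must
make its labels true by construction, or exact-recovery tests would be
ill-posed; set `null_padj_min=0` for a full-range uniform null.

Not emulated: spot morphology and image quantification (intensities enter
already spot-quantified), wash-cycle kinetics, protein-loading effects,
chip-to-chip batch factors, substrate competition/saturation kinetics, and
any real kinase–substrate annotation (identifiers are synthetic; no
curated database ships). Passing tests therefore demonstrate that the
*analysis chain* is correct and calibrated under its own assumptions — not
that those assumptions hold on any particular real dataset, nor anything
about real kinase biology.

## Reference experiments and problem sizes

The benchmark experiments (`kinomeflow.benchmarks`) simulate only the two
sample groups the scored comparison uses (KO vs. control, TGFb,
triplicate): 144 peptides × 6 samples × 13 cycles × 4 exposures per run.
Null calibration pools per-kinase Δ confidence and z over 20 seeded
no-effect runs at CV 0.1; recovery plants one kinase at multiplier 2.0
with 8 exclusive substrates at CV 0.15 (decoy kinases draw from the other
136 peptides, making exclusivity structural) and asks how often it tops
|MEOW| over 20 seeds; the partition round-trip draws 50 random planted
configurations (200–1000 genes) at zero log2FC noise and demands exact
set-level recovery. All run in a few seconds on one core.

## Known limitations

* The sampling-analyzer and vendor ranking internals are not public; z,
  Δ confidence conventions at degeneracy, and the summary statistics here
  are documented analogues, asserted to be calibrated on the synthetic
  benchmark, not to be bit-identical to proprietary output.
* Ratio-of-means vs. mean-of-ratios and collapse-then-fit vs.
  fit-then-combine orderings are genuinely underdetermined by the
  published description; both alternatives are exposed via options.
* Differential-expression estimation itself is out of scope: contrast
  tables are consumed (or synthesized), never fit from counts here.
* At realistic replicate noise the FC thresholds are conservative, so
  no-effect runs typically yield empty differential sets; calibration
  statements then rest on the degenerate-case conventions above.
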