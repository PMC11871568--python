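# kinomeflow

Upstream-kinase inference from peptide-microarray kinase-activity data,
plus the dual-contrast transcriptome logic used to ask which gene responses
depend on a receptor — packaged as a tested, reproducible pipeline with a
planted-truth synthetic benchmark.

## Who this is for

Groups running kinome activity profiling on peptide microarrays (e.g.
PamChip-style serine–threonine and tyrosine-kinase panels, 144 and 196
reporter peptides) alongside bulk RNA-seq contrasts — for instance to
dissect how a receptor knockout rewires kinase signaling and the
transcriptional response in hepatic stellate cells. The analysis steps that
are usually locked inside vendor software are implemented here as plain,
documented functions, and every step can be exercised end to end on
synthetic data whose ground truth is known.

## The method

**Slope signals.** Each reporter peptide is imaged every 5 min for 1 h at
four CCD exposures (10/20/50/100 ms). Within each cycle the exposures are
fused by a through-origin regression of intensity *I* on exposure *e*,
projected to 100 ms: `100 · Σ(e·I) / Σ(e²)`. The per-peptide signal is the
OLS slope of the fused intensity on cycle time; peptides with kinetic
R² < 0.80 are flagged undetectable/nonlinear (0.80 itself passes).

**Differential phosphorylation.** Per peptide, FC = mean(group A signal) /
mean(group B signal) over replicates; a peptide is differential when
FC ≥ 1.30 or FC ≤ 0.70 (inclusive). A peptide must pass QC in every sample
of the comparison; those peptides form the comparison's *background*.

**Upstream kinases.** For each kinase with ≥ 3 annotated substrates in the
background, the observed hits are `|substrates ∩ differential|`. A null is
built from 2000 random draws of equally sized peptide sets from the
background (without replacement), giving

    z     = (observed − mean_null) / sd_null
    Δconf = observed / mean_null
    MEOW  = mean substrate log2FC × Δconf

MEOW ("measurements extensively of winner") is the direction-aware kinase
activity score; exact hypergeometric moments are available as an oracle.
Across comparisons, kinases are summarized by median z (tree node color)
and mean |MEOW| (node size).

**Transcriptome contrasts.** Given per-gene (log2FC, padj) tables for the
treatment response in control and knockout cells, genes significant
(padj < .05, strict) in both contrasts partition into shared-up,
shared-down and opposite; genes significant in one contrast are
condition-specific. The per-gene dependence score
`log2FC_KO − log2FC_control` ranks genes; the top and bottom 100 feed a
local hypergeometric over-representation test against a GMT collection,
BH-adjusted, summarized by AES = n_overlap × (−log10 padj).

**Synthetic benchmark.** `kinomeflow.synthetic` generates kinetic tables in
which chosen kinases have their activity multiplied in chosen conditions
(intensity = background + velocity·t·exposure/100 with lognormal noise),
and paired contrast tables with planted shared/opposite/unique responders —
so parameter recovery, null calibration and partition round-trips are all
testable with known truth.

## Worked example

`examples/02_upstream_kinase_inference.py` simulates a 144-peptide STK chip
(knockout vs. control, TGFb-treated, triplicates, 10% intensity CV) with
kinase `KIN_001` doubled in activity in the knockout, then runs the full
kinome chain:

```
15 up + 0 down differential peptides of 142 in the QC background
kinase_id  observed_hits  mean_null      z  delta_confidence  mean_substrate_log2fc  meow
  KIN_001             15      1.635 11.734             9.172                  1.004 9.207
  KIN_009              2      0.544  2.160             3.676                  0.418 1.535
  KIN_002              4      1.260  2.709             3.175                  0.343 1.088
top kinase substrate activity change: +100.5%
```

The planted kinase tops the MEOW ranking: all 15 of its substrates land in
the differential set against ~1.6 expected by chance (Δconf ≈ 9, z ≈ 12),
and its mean substrate log2FC ≈ 1 recovers the planted doubling (+100%).
The other examples cover signal extraction, the dual-contrast partition
(recovering a planted 299/364/4 shared-up/shared-down/opposite structure),
and pathway enrichment.

A thin CLI mirrors the library:

```bash
kinomeflow run-all --seed 1 --out-dir runs/demo
kinomeflow extract-signals --kinetics runs/demo/kinome/kinetics.tsv --out signals.tsv
```

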