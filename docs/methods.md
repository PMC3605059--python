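# Methods

## Coordinates and regions

All coordinates are 0-based, half-open (BED-native); 1-based inputs are not
supported. The TSS is the strand-dependent end of the unit span
(`span.start` on +, `span.end − 1` on −). The promoter window is symmetric,
TSS ± 100 bp (200 bp total); the phrase "surrounding the TSS" does not by
itself fix symmetry, but the symmetric reading matches the analogous 400-bp
cohesin-scoring window (TSS ± 200) and is adopted throughout. The gene body
is the portion of the unit span strictly downstream, in transcription
direction, of the promoter window: it starts at TSS + 100 and runs to the
annotated end. The upstream promoter half lies outside the unit span, so
the downstream promoter half plus the body exactly reconstitutes the span.
A unit whose span ends at or before TSS + 100 (in transcription direction)
has an empty body, is flagged, and is excluded from pause and efficiency
computations. Windows that would extend below coordinate 0 are clamped with
a warning.

Interval overlap is half-open with a 1-bp minimum: touching intervals do
not overlap. Overlap queries use a sorted sweep checked in the test suite
against an all-pairs scan.

## PRO-seq quantification

Counts are summed over each region on the unit's sense strand only —
promoter-proximal pausing is a sense-strand phenomenon and the antisense
divergent peak would otherwise contaminate the promoter window. The library
size defaults to the total reads in the sample's two strand tracks. RPM =
raw × 10⁶ / library; density = RPM / region length; replicates are each
normalized to RPM and then averaged (raw counts are reported but never
pooled across replicates). Activity requires ≥ 1 RPM — inclusive — in both
promoter and body of the replicate-averaged control table. The pause index
is the ratio of promoter to body density and is therefore independent of
library size; it is undefined (NA, never an exception) where body density
is zero. Fold-changes are log2 with a default pseudocount of 0, flagging
units with a zero on either side as missing; a nonzero pseudocount is
exposed for plotting.

## Cohesin groups and binding calls

A probe belongs to a region iff its midpoint lies inside it (avoids double
counting at edges). Group edges are 1, 2 and 4 mean-score units over the
400-bp TSS window, left-closed at interior edges ([1,2), [2,4)); a score of
exactly 4 goes to the top group, and negative scores (possible for
MAT-style enrichment) fall in the lowest group with the cohesin-free genes.
Binding can be evaluated from interval call sets (1-bp minimum overlap) or,
for synthetic tracks, by thresholding runs of consecutive probes — the two
modes agree exactly on noiseless data. Track correlations are Pearson on
raw probe values matched by position, with no smoothing.

## Differential occupancy

Per-probe differences are taken on a shared grid; the median m and SD σ are
genome-wide (all chromosomes jointly), but runs never cross a chromosome.
σ is the SD about the mean; for the near-symmetric difference distributions
this rule targets, the SD about the median is indistinguishable. The span
of a probe run counts one probe spacing beyond the last probe start, so
three 35-bp features span exactly 105 bp — the stated equivalence that
fixes the convention. Emitted intervals cover
[first probe start, last probe start + spacing). Identical tracks give
σ = 0 and, by convention, no calls. Regions overlapping both an UP and a
DOWN interval are rescored NONE and logged (a deterministic replacement for
ad-hoc visual adjudication); an alternative rule keeps the direction with
the larger overlapping span. No FDR control is applied — the fixed 2σ rule
is the method.

## CRMs

A DHS yields a candidate CRM iff it directly overlaps (≥ 1 bp) at least one
H3K4me1 and one H3K27ac interval — the conservative reading of mark
co-occurrence, config-exposed. The element is 200 bp centred on the DHS
interval midpoint (the only summit information interval inputs carry).
Extragenic elements must not overlap any annotated unit span (all units,
not only active ones) and must lie ≥ 500 bp — inclusive — from every TSS,
measured from the nearest element edge. Change fractions at CRMs are
computed only over CRMs bound by the factor in the control condition.

## Efficiency

Per-gene mRNA signal is the sum over all of a gene's array probes. For
genes with several active transcription units, body densities combine as
(Σ body RPM) / (Σ body lengths). Efficiency = mRNA / body density, defined
only where body density > 0; group plots use the control-condition density,
fold-changes use matched condition pairs. Group medians are computed on the
ratio and displayed as log2 (medians are order-preserved under log, so the
choice is presentational). KS p-values use the asymptotic two-sample
distribution with no multiple-testing correction.

## Synthetic-data generator

The generator's defaults are the study conditions; they are not tuned per
run.

**Genome.** 2,000 non-overlapping stranded units on one chromosome; gene
lengths lognormal (median 2.5 kb, σ = 0.5, minimum 600 bp), intergenic gaps
uniform 0.8–2.2 kb — a gene-dense invertebrate-like layout.

**Cohesin.** Units fall into the four score groups with fractions
(0.4, 0.2, 0.2, 0.2); within-group levels are drawn uniformly (zero-group:
70% exact zeros, remainder below 1), keeping a 0.15 margin from the
interior edges so that, at the default ChIP noise, group recovery from the
simulated track fails only near edges (the suite checks ≥ 95% agreement).
A unit is cohesin-bound iff its level is ≥ 1.

**Pausing and transcription.** Group median pause indices are geometric
from 2.0 to 7.4, so the designed top/zero ratio is 3.7; within-group spread
is lognormal (σ = 0.35). Body densities are lognormal (median 1, σ = 0.6);
promoter density = PI × body density.

**Depletion.** Modelled multiplicatively: promoter density × 0.75 at
cohesin-free units (a designed median 25% pause decrease) and body density
× 3.7/(0.75·8.7) ≈ 0.567 at bound units, which maps the control top/zero
pause ratio of 3.7 to 8.7 after depletion.

**PRO-seq.** Region read counts are Poisson with means proportional to
density × length, scaled to 2 × 10⁶ reads per replicate with 2% uniform
background. Promoter reads land on a geometrically decaying pause peak at
TSS + 20..60 on the sense strand (the peak shape is a modelling choice; any
within-promoter shape serves); body reads are uniform. The recorded library
size equals the reads written, exactly.

**ChIP.** Probes every 35 bp (three features = 105 bp). Point sites
(cohesin at TSSs and CRMs, histone marks at CRMs) contribute a triangular
kernel of half-width 300 bp, normalized so the mean score over the 400-bp
window equals the site amplitude; broad Pol II occupancy (promoter and body
blocks for Rpb3/Ser2P/CycT/Cdk12) contributes flat blocks proportional to
the condition-specific densities. Gaussian noise σ = 0.25. Binding calls
are merged probe runs where the noiseless signal reaches 1.5 score units —
above the reach of any sub-threshold cohesin level, below the weakest bound
site.

**CRMs.** 60 DHS+H3K4me1+H3K27ac elements: 75% centred in wide intergenic
gaps (extragenic by construction), 25% near or inside units to exercise the
filter, plus 30 decoy DHS carrying at most one mark. 96% of true CRMs are
cohesin-bound, 45% Pol II-associated; mark amplitudes scale with the CRM's
cohesin level to create the designed positive correlation.

**Expression.** Per-gene mRNA = efficiency factor × body density ×
lognormal noise (σ = 0.25), split across 1–3 probes. Efficiency factors are
geometric 1 → 2 across the four groups: the top group makes twice the mRNA
per transcribing polymerase.

All generators are pure functions of (config, seed); the pipeline driver
derives one child seed per stochastic stage from a single master seed.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline consumes: stranded
pause-peaked count tracks, probe-grid enrichment with additive noise,
group-structured pausing, multiplicative depletion effects, feature
co-occurrence at regulatory elements. It does not emulate mappability or
GC/probe-sequence bias, array saturation, divergent antisense transcription
(off by default, flag-enabled for strandedness tests), chromatin-domain
autocorrelation, or biological heterogeneity beyond the modelled lognormal
spreads. Passing recovery tests therefore demonstrates correctness of the
quantification and calling logic under the designed conditions, not
robustness to every artefact of real arrays or libraries.

## Problem sizes and numerical choices

The standard study uses 2,000 units × 2 replicates × 2 conditions at
2 × 10⁶ reads (≈ 250k probes per ChIP track) and completes in a few seconds;
the efficiency-recovery check uses 2,500 units (≈ 500 per group); the CRM
fraction-recovery check uses 1,200 units with 500 extragenic elements.
Ties and edge cases: activity threshold inclusive at 1 RPM; group edges
left-closed with 4.0 in the top group; TSS distance inclusive at 500 bp;
change-span inclusive at 105 bp; conflicted change regions NONE. Degenerate
inputs (empty tracks, regions without probes, zero body density, σ = 0
difference tracks, empty strata) yield flagged missing values or empty
results, not exceptions, except where a precondition is violated
(mismatched probe grids, non-stranded annotations, overlapping bedGraph
records), which raise immediately with the offending location.

## Known limitations

- The change caller assumes both tracks share one probe grid; arrays with
  differing designs must be intersected upstream.
- Genome-wide σ mixes signal and noise probes; under very widespread true
  change the threshold inflates and calls become conservative.
- The CRM element width (200 bp) and mark co-occurrence rule are fixed,
  simple conventions; enhancer-state segmentation is out of scope.
- Expression preprocessing (background correction, probe-set
  summarization beyond summation) is assumed done upstream.
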