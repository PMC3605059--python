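# pausedelta

Genome-wide analysis of RNA polymerase II activity for nascent-transcription
(PRO-seq/GRO-seq) and tiling-array ChIP data, centred on promoter-proximal
pausing and its relationship to cohesin occupancy.

The package is for regulatory-genomics analysts who have, per condition:
stranded base-resolution PRO-seq 3′-end count tracks (bedGraph), MAT-score
style probe-resolution ChIP enrichment tracks, significant-binding interval
sets (BED), DHS / H3K4me1 / H3K27ac peak sets, and a per-probe mRNA
expression table. Every stage is also exercisable at desk scale through a
synthetic-data generator with known ground truth.

## What it computes

For each annotated transcription unit with TSS-containing promoter window
*P* (200 bp, TSS ± 100) and gene body *B* (the rest of the unit span
downstream of the promoter window):

- **RPM quantification** — sense-strand read counts over *P* and *B*,
  normalized to reads per million (RPM) of the sample's total mapped reads;
  replicates are normalized individually and averaged. Units with
  ≥ 1 RPM (inclusive) in both regions in the control condition are *active*.
- **Pause index** — PI = (RPM/bp in *P*) / (RPM/bp in *B*); the standard
  promoter-proximal pausing statistic.
- **Cohesin groups** — active units binned by mean ChIP score over the
  400-bp TSS window into four groups at score edges 1, 2 and 4
  (G1 < 1 ≤ G2 < 2 ≤ G3 < 4 ≤ G4).
- **Differential occupancy** — with per-probe score differences *d*
  (treated − control), genome-wide median *m* and SD σ, an UP (DOWN) call is
  a maximal run of consecutive probes with *d* ≥ *m* + 2σ (*d* ≤ *m* − 2σ)
  spanning ≥ 105 bp (three 35-bp array features). Regions are labelled by
  1-bp overlap; regions hit in both directions are rescored NONE.
- **CRM prediction** — a 200-bp element centred on each DHS midpoint that
  overlaps both an H3K4me1 and an H3K27ac interval; the *extragenic* subset
  excludes elements overlapping any transcription unit or within 500 bp of a
  TSS.
- **Efficiency** — per-gene steady-state mRNA signal (summed over array
  probes) divided by gene-body PRO-seq density: mRNA produced per
  transcribing polymerase.
- **Group statistics** — two-sample Kolmogorov–Smirnov tests between
  cohesin groups and Fisher's exact tests on change-frequency tables.

## Worked example

Run the full synthetic study (2,000 transcription units, two PRO-seq
replicates per condition at 2 × 10⁶ reads, 35-bp ChIP probe grid):

```
$ pausedelta report --seed 3
{
  "n_units": 2000,
  "n_active": 2000,
  "replicate_pearson_r": 0.9984361941094401,
  "pause_ratio_top_vs_zero_control": 3.571727967342347,
  "pause_ratio_top_vs_zero_depleted": 8.339576479812003,
  "median_pause_change_unbound_pct": -24.669866942518894,
  "n_crms": 60,
  "n_extragenic_crms": 45,
  "extragenic_crm_cohesin_bound_pct": 100.0,
  "efficiency_ratio_top_vs_zero": 1.9166440601988612
}
```

Reading the output: the two simulated control replicates correlate at
r = 0.998 on per-unit total RPM; the median pause index of the top cohesin
group is 3.6× that of the cohesin-free group in the control condition
(designed 3.7) and rises to 8.3× after simulated depletion of the cohesin
loader (designed 8.7), driven by a median 24.7% pause decrease at
cohesin-free genes (designed 25%); all 45 extragenic CRMs recover their
designed cohesin binding (96% in expectation); and the top cohesin group
produces 1.9× the mRNA per transcribing polymerase of the cohesin-free
group (designed 2×).

The same stages run on real files via the other subcommands:

```
pausedelta quantify --annotation genes.bed --plus plus.bg --minus minus.bg --out quant.tsv
pausedelta groups   --cohesin rad21.bg --annotation genes.bed --out groups.tsv
pausedelta diffcall --treated rpb3_rnai.bg --control rpb3_mock.bg --out changes.bed
pausedelta crm      --dhs dhs.bed --k4me1 k4me1.bed --k27ac k27ac.bed \
                    --annotation genes.bed --out crms.bed
pausedelta efficiency --expression expr.tsv --quant quant.tsv --out eff.tsv
```

or from Python through `pausedelta.quantify_regions`, `pause_index`,
`assign_cohesin_groups`, `call_change_intervals`, `predict_crms`,
`efficiency_table`, etc.

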