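# enhquant

Spike-in-normalized enhancer signal quantification and degron-sensitivity
classification for ChIP-Rx / eRNA experiments.

## The problem

Acute degradation of a chromatin-bound oncoprotein (e.g. the EWS::FLI1
fusion in Ewing sarcoma, removed with PROTAC degraders) changes occupancy
and transcription *globally*, so ordinary depth normalization of ChIP-seq is
misleading. Experiments therefore mix in exogenous reference chromatin
(*Drosophila* S2 cells at a fixed 1:4 cell ratio) before immunoprecipitation:
reads mapping to the spike-in genome measure each library's combined
depth/IP-efficiency scale, independent of treatment effects on the target
genome. `enhquant` implements the enhancer-centric analysis built on that
design:

1. **regions** — ingest enhancer loci (BED), extend intervals shorter than
   600 bp to 600 bp around the binding-site anchor, and link each locus to
   the gene with the nearest promoter (smallest |TSS − anchor|).
2. **spikenorm** — count target vs spike reads per sample and downsample
   each sample's target reads by `f_s = min_t(S_t) / S_s` (spike mode; depth
   mode uses target counts), so retained target depth per spike read is
   equal across a comparison group and no sample is ever upsampled.
3. **quant** — per-locus **rpk** (overlapping reads / locus kb) on the
   normalized reads; exclusion of loci where *both* control and treatment
   fall below an assay floor (30 rpk for ChIP, 10 rpk for eRNA);
   per-locus `log2((t + 1)/(c + 1))` fold changes; ±3 kb / 50 bp binned
   "tornado" signal matrices around each anchor.
4. **sensitivity** — genes with `log2FC < −0.5` and `FDR < 0.05` (strict) in
   a differential-expression table are *downregulated*; those linked to an
   enhancer are *sensitive*, and all their enhancers form the sensitive
   enhancer set. Set-overlap summaries compare systems.
5. **peaks** — narrowPeak ingestion, fraction of enhancers overlapped by a
   factor's peaks, and squared Pearson correlation of per-locus intensities.
6. **stats** — Mann–Whitney U (exact for small tieless samples), Kruskal–
   Wallis, BH-FDR, and Bliss drug-synergy scores
   (`score = 100 × (observed − (E_a + E_b − E_a·E_b))`).
7. **synthdata** — a seeded generator that emulates the whole study design
   (planted enrichment, depletion at a sensitive subset, spike mixing with
   depth jitter, planted DE structure, planted peak coverage) with ground
   truth for every stage.

## Worked example

Simulate a 100-enhancer study and run the full pipeline:

```bash
enhquant simulate --seed 1 --n-enhancers 100 -o demo
cat > demo/run.yaml <<CFG
loci: demo/loci.bed
tss: demo/tss.bed
chrom_sizes: demo/chrom.sizes
control_reads: demo/reads_ctrl_rep1.bed
treatment_reads: demo/reads_treat_rep1.bed
control_id: ctrl_rep1
treatment_id: treat_rep1
de_table: demo/de_table.tsv
peaks: demo/peaks_factor_a.narrowPeak
peaks_factor: factor_a
outdir: demo/out
CFG
enhquant run demo/run.yaml
```

prints

```json
{
 "config": "e27fd32cdd60",
 "log2fc_sensitive_vs_other_U": 1.0,
 "log2fc_sensitive_vs_other_p": 2.561737564547219e-07,
 "n_down_genes": 10,
 "n_loci": 100,
 "n_loci_passing_filter": 100,
 "n_sensitive_enhancers": 10,
 "n_sensitive_genes": 10,
 "normalization": "spike",
 "peak_n_overlapped": 86,
 "peak_overlap_fraction": 0.86,
 "seed": 1,
 "system": "degrader",
 "version": "0.1.0"
}
```

The generator planted 10 sensitive enhancers (10% of 100) and peaks at 86%
of loci; the pipeline recovers both exactly, and the Mann–Whitney test
confirms the fold-change separation between sensitive and unperturbed loci
(p ≈ 2.6 × 10⁻⁷). `demo/out/` holds the per-stage tables:
`norm_factors.tsv` (here the control keeps all reads, the deeper treatment
sample is downsampled to f ≈ 0.851), `signal_table.tsv`, `fold_change.tsv`
(median log2fc ≈ −1.05 at sensitive loci vs ≈ −0.01 elsewhere),
`tornado_treatment.tsv`, the sensitivity calls, and `run_summary.json`.
Each table starts with `# key: value` provenance lines (config hash, seed,
version), so reruns with an identical config are byte-identical.

Individual stages are also available as `enhquant normalize | quantify |
classify | peaks | synergy`, and everything is importable as a library
(`from enhquant import build_signal_table, ...`).

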