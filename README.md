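# bindmodes

Characterize *how* a DNA-binding protein engages a genome from ChIP-seq and
sequence alone. Archaeal histone-fold proteins, bacterial nucleoid-associated
proteins (NAPs) and transcription factors (TFs) leave distinct genomic
fingerprints, and the same handful of statistics separates them:

* **Dinucleotide periodicity spectra.** Histone-wrapped genomes space
  AA/TT/TA dinucleotides every ~10 bp (the helical repeat facing the histone
  surface); negatively supercoiled genomes show ~10.7–11 bp. `bindmodes`
  binarizes the genome into the indicator signal of a dinucleotide set and
  estimates its spectral density with a Yule–Walker autoregressive fit
  (order selected by AIC), S(f) = σ² / |1 − Σₖ aₖ e^(−2πifk)|², normalized to
  unit mean over the frequency grid. Band peaks (e.g. 9.5–10.5 bp) are
  called when the in-band maximum exceeds 1.5× the median off-band density.
  The same analysis runs on bound loci (concatenated peak sequences) with a
  resampling null of random genome segments matched in number and length,
  reporting an empirical p = (k+1)/(n+1).
* **Peak feature statistics.** Replicate-majority peak sets (per-base
  majority intersection), peak count, mean/median width, genome coverage,
  peak-center genic/intergenic classification, and an exact hypergeometric
  test for intergenic enrichment with the genome's base-pair composition as
  background: X ~ Hypergeom(N = genome bp, K = intergenic bp, n = peaks).
* **Start-site occupancy profiles.** Strand-oriented coverage matrices over
  ±400 bp around each ORF translation start, normalized to replicon mean
  depth, averaged into metagene profiles — sharp promoter bumps for TFs,
  flat lines for NAPs, nucleosome-free troughs with phased downstream peaks
  for histones.
* **Axis classification.** The numbers map onto qualitative axes (binding
  frequency, peak width, location preference, sequence mode) under explicit,
  configurable thresholds.

A first-class synthetic-data module generates genomes of configurable G+C
with optionally planted phase-periodic dinucleotides, annotations hitting a
target coding fraction, and paired IP/input Poisson coverage in TF, NAP and
histone archetypes with full ground truth — so the entire pipeline is
exercisable and testable offline.

## Worked example

```python
import bindmodes as bm

genome = bm.make_genome(1_000_000, gc_fraction=0.6, seed=101)
annotation = bm.make_annotation(genome, n_genes=900, coding_fraction=0.85, seed=102)

# a genome carrying a 10-bp AA/TT/TA comb at strength 0.3
planted = bm.plant_periodic_dinucleotides(genome, period=10, strength=0.3, seed=104)
peak = bm.genome_periodicity(planted).peaks["10bp"]
print(peak.detected, round(peak.period, 2), round(peak.prominence, 2))
# True 10.0 2.08        <- 10-bp band called at period 10.0, 2.1x baseline
print(bm.genome_periodicity(genome).peaks["10bp"].detected)
# False                 <- unplanted control stays below threshold

# TF-archetype ChIP experiment: call peaks, classify, test enrichment
ip, inp, truth = bm.simulate_chip_coverage(genome, annotation, "TF", seed=103)
peaks = bm.simple_peak_caller(ip, inp)
stats = bm.peak_stats(peaks, genome)
cl = bm.classify_peak_locations(peaks, annotation, genome)
enrichment_p, _ = bm.intergenic_enrichment_test(cl)
print(stats.n_peaks, round(stats.coverage_pct, 2), f"{enrichment_p:.3g}")
# 20 0.81 3.18e-09      <- 20 narrow sites, <1% of the genome, strongly intergenic
summary = bm.build_summary("TF", stats, cl)
print(summary.frequency, summary.width_class, summary.location)
# low narrow promoter-preferring
```

The numbered scripts under `analysis/` run the full narrative — simulate
datasets, genome and bound-locus spectra, peak features across the
TF/NAP/histone trio, occupancy profiles, the resampling null, and the
cross-archetype summary table — writing their tables under `results/`.

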