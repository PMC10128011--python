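# Methods

## Dinucleotide periodicity by autoregressive spectral estimation

A genome (or a concatenation of bound loci) is reduced to a binary signal
x_i ∈ {0,1}, i = 1..n−1, marking positions whose dinucleotide belongs to a
chosen set — {AA, TT, TA} by default, which is closed under reverse
complement so the spectrum is strand-symmetric. Dinucleotides containing N
never match. The G/C analogue defaults to {GG, CC, CG, GC}, the
reverse-complement-closed counterpart; the exact set is configurable because
different closures are defensible.

The signal is demeaned and its biased autocovariances r_0..r_p are computed
exactly by FFT (no subsampling; n ≈ 5×10⁶ at lag ~65 is routine).
Levinson–Durbin recursion yields Yule–Walker fits of every order
0..max_order, with max_order = min(n−1, ⌊10·log₁₀ n⌋) — the classical
default of AR spectrum routines — and the order minimizing
AIC(p) = n·log σ²_p + 2p is kept. The spectral density

    S(f) = σ² / |1 − Σ_{k=1..p} a_k e^{−2πifk}|²

is evaluated on 2,000 evenly spaced frequencies in (0, 0.5] cycles/bp
(0.00025 cycles/bp ≈ 0.025 bp of period resolution near 10 bp, enough to
separate 10.0/10.3/10.4/11.0 bp) and divided by its grid mean, so every
spectrum has unit mean and spectra of different genomes are directly
comparable.

**Band peak calls.** Within a period band (defaults: 9.5–10.5 bp and
10.5–11.5 bp), the peak height is the in-band maximum of the normalized
density and the baseline is the median density over periods 4–50 bp with the
band excluded — the 3-bp codon-usage line and the low-frequency slope from
local A+T drift both fall outside this window. A peak is *detected* when
height/baseline ≥ τ = 1.5. The threshold is an explicit configuration knob:
detection is intrinsically a binary call on a continuous statistic and any
cutoff is a choice; 1.5 separates planted combs at strength ≥ 0.3 from
unplanted i.i.d. backgrounds across the tested seeds while staying well
above the ≈1.05 prominence of white-noise spectra.

**Replicon handling.** Genome-wide spectra analyze the concatenation of all
replicons in file order; junctions contribute at most (replicon count − 1)
spurious dinucleotides out of megabases, and the count is logged. A
per-replicon mode is available where copy-number or composition differences
matter.

**Region mode.** Bound loci are extracted in list order and concatenated
into one sequence before binarization, so junction dinucleotides are
included (and logged); with typical peak sets this adds tens of positions to
tens of kilobases. Total extracted length must reach 200 bp (2 bp in the
fixed-window mode, which caps the AR search order at window−2 instead).

**Resampling null.** The band peak height of bound loci is compared with
n_draws (default 100) sets of random genome segments matched in number and
length: replicons are chosen with probability proportional to length among
those that fit, starts uniformly; segments may overlap each other and may
overlap real peaks (excluding them would require the peak list to define the
null, and with <1% of a genome bound the effect is negligible). The
empirical p uses the (k+1)/(n+1) convention so it is never exactly zero.
Because this p lives on a lattice of n_draws+1 values, calibration checks
apply the randomized probability integral transform
(n_exceeding + U)/(n_draws + 1), which is exactly Uniform(0,1) under the
null, before a Kolmogorov–Smirnov test; the continuous-uniform KS applied
directly to the lattice over-rejects (~4% at a nominal 1% in direct
simulation of perfectly calibrated ranks).

## Peak features

Replicate peak sets are merged by per-base majority: each replicate's peaks
are self-unioned, the genome is partitioned by the count of covering
replicates (an event sweep, verified against brute-force per-base counting),
and maximal intervals with count ≥ ⌊R/2⌋+1 survive, with bookended survivors
merged. Width statistics use end − start; genome coverage uses the union of
peaks over the genome's total length.

A peak's location class is decided by its center, ⌊(start+end)/2⌋ (floor is
the deterministic tie-break for even widths), which is *coding* iff it lies
inside the union of gene intervals under half-open membership; strand is
ignored. Intergenic enrichment uses the exact hypergeometric tails with a
base-pair universe: N = genome bp, K = intergenic bp, n = peaks, k =
intergenic centers; enrichment_p = P(X ≥ k), depletion_p = P(X ≤ k). A
region-count universe is an alternative reading of the same test; the
base-pair universe is used because it requires no arbitrary partition of
intergenic space into countable units, and the choice is documented so
alternates can be compared.

## Start-site occupancy

For each gene, a window of ±W (default 400; ±800 suits eukaryotic inputs
with larger intergenic spans) around the ORF translation start is read from
the coverage track, oriented so negative columns are upstream on both
strands, and divided by the mean depth of the gene's own replicon —
normalization is per replicon, not per genome, because replicons can differ
in copy number. The ORF start (gene start on +, end−1 on −) anchors the
profile rather than the transcription start site: it is well annotated
everywhere, and in halophilic archaea most transcripts are leaderless so the
two nearly coincide. Windows crossing replicon ends contribute missing cells
rather than dropping the gene; per-column gene counts make this auditable.
Profiles are unsmoothed by default. The IP/input ratio track is
(ip + ε)/(input·s + ε) with ε = 1 and s = total_ip/total_input scaling the
input to equal total depth.

## Synthetic data

The generators produce the statistical structure the analysis assumes, with
ground truth, so every stage is testable offline:

* **Genomes** are i.i.d. bases at configurable G+C (default scenarios use
  0.6, a halophile-like composition). Planting overwrites two bases with a
  uniformly chosen set member at every position ≡ 0 (mod P) with
  probability s; s = 0.3 at P = 10 is the default planted scenario.
* **Annotations** place non-overlapping stranded genes to a target coding
  fraction (default 0.85, matching the 84–87% coding regime of the archaeal
  genomes of interest) with intergenic gaps ≥ 20 bp.
* **Coverage** is input = Poisson(λ_bg) and IP = Poisson(λ_bg·e(x)) per base
  with λ_bg = 20 (an optional gamma-Poisson overdispersion knob exists, off
  by default — Poisson is the simplest model that exercises every stage).
  TF mode plants ~20 Gaussian bumps (sd 75 bp, fold 5–20) centered in
  intergenic gaps with probability 0.8; NAP mode tiles non-overlapping
  plateaus (0.4–2 kb, fold 2–6) to an 11% coverage target; histone mode
  lays phased boxcar nucleosome footprints (core 120 bp at fold 2, linker
  30 bp; eukaryote-like 147+20 available) downstream of every ORF start
  with a fold-0.3 depletion trough over the 180 bp upstream. Boxcars rather
  than smooth bumps represent core protection and make the phasing geometry
  exact. `seed` fixes the enrichment landscape and `noise_seed` the Poisson
  sampling, so replicates of one landscape differ only in noise.
* **The peak caller** thresholds a moving-average-smoothed (150 bp) ratio
  track at fold_threshold × background, where the background is a low
  quantile (10%) of the smoothed ratio capped at 1. The cap makes
  sparse-enrichment tracks behave as a plain fold cutoff; the relative
  threshold is what makes genome-wide (histone-like) enrichment callable at
  all, since library-size scaling necessarily pushes such signal toward the
  genome mean. Runs must persist ≥ 100 bp; features closer than the
  smoothing bandwidth may merge — both documented behaviors, not bugs.

What the synthetic data does **not** emulate: read-level artifacts
(mappability, GC bias, fragment-size effects), overdispersed biological
replicate variation, repeat-driven false peaks, or composition
heterogeneity along real genomes. Passing tests therefore demonstrate the
correctness and calibration of the computations under the stated generative
model, not robustness to every artifact of real libraries — curated real
peak lists and tracks can be supplied through the I/O layer when available.

## Classification thresholds

The axis labels are pure functions of the numeric fields under one
configuration block, echoed in every output: frequency low below 3% genome
coverage (strict) and high at ≥ 10% (TFs typically fall at 0.3–3.7%, NAPs
around 11%); width narrow below 700 bp (strict); location
promoter-preferring iff enrichment p < 10⁻³ *and* the intergenic peak
fraction exceeds the genome's noncoding fraction; sequence mode
periodicity-preferring iff the bound-locus 10-bp band is detected with null
empirical p ≤ 0.05, motif-like only on user-supplied motif evidence (motif
discovery is outside this package's scope). These cutoffs are explicitly
invented, not biological constants. Missing fields yield "unknown";
boundary values resolve by the strict inequalities above.

## Numerical and design notes

* Coordinates are 0-based half-open everywhere internally; 1-based
  conventions (wiggle, NCBI-style tables) are converted at I/O boundaries.
* Constant binary signals (zero variance) are rejected explicitly rather
  than producing a degenerate spectrum; numerically singular Levinson steps
  truncate the order search.
* The AR implementation is cross-checked in the tests against closed-form
  AR(2) spectra, FFT periodograms on comb signals, and statsmodels'
  Yule–Walker estimates (biased variant); the hypergeometric tails against
  exhaustive enumeration at N ≤ 60. On stochastic AR(2) realizations the
  *raw* periodogram's band argmax is itself dispersed across the resonance
  width (observed up to ~9×10⁻³ cycles/bp at n = 10⁴), so point agreement
  with it is only asserted for sharp comb peaks; the closed-form peak
  location serves as the AR(2) oracle.
* Default problem sizes in the analysis scripts and checks (1-Mb genomes,
  20-seed recovery sweeps, 200-instance oracle comparisons, 100-draw nulls)
  were chosen so the complete analysis reruns in minutes on one CPU while
  keeping every statistical check comfortably powered.
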