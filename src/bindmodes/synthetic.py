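"""Synthetic genomes, annotations and ChIP-seq coverage with ground truth.

The generators emulate the statistical structure the analysis assumes:
i.i.d. genomes of configurable G+C with optionally planted phase-periodic
AA/TT/TA dinucleotides; non-overlapping stranded gene annotations hitting a
target coding fraction; and paired IP/input coverage with Poisson noise and
planted enrichment in one of three archetypes —

* TF mode: few narrow Gaussian bumps, biased toward intergenic gaps;
* NAP mode: frequent broad plateaus placed uniformly to a target coverage;
* histone mode: phased nucleosome-footprint arrays downstream of every ORF
  start with a nucleosome-free depletion trough over the promoter.

Every generator takes a mandatory seed and records its full parameter set in
the returned truth object, so outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CoverageTrack,
    GeneAnnotation,
    GeneRecord,
    GenomeSequence,
    Interval,
    IntervalSet,
    merge_intervals,
    union_length,
)
from .occupancy import ratio_track

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Coverage-simulation parameters; defaults are the study conditions."""

    lambda_bg: float = 20.0  # background read depth per base
    overdispersion: float = 0.0  # gamma-Poisson mixing CV^2; 0 = pure Poisson
    # TF mode
    n_tf: int = 20
    tf_sd: float = 75.0  # bump standard deviation, bp
    tf_fold: tuple[float, float] = (5.0, 20.0)
    p_intergenic: float = 0.8
    # NAP mode
    nap_width: tuple[int, int] = (400, 2000)
    nap_fold: tuple[float, float] = (2.0, 6.0)
    nap_target_coverage: float = 0.11
    # histone mode ("archaeal-like" core+linker; eukaryote-like is 147+20)
    core: int = 120
    linker: int = 30
    histone_fold: float = 2.0
    nfr: int = 180  # nucleosome-free region width upstream of the ORF start
    nfr_fold: float = 0.3


@dataclass
class SyntheticTruth:
    """Ground truth and full parameter record for a simulated dataset."""

    mode: str
    seed: int
    planted_peaks: IntervalSet
    planted_period: float | None = None
    planting_strength: float | None = None
    coding_fraction: float | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "mode": self.mode,
            "seed": self.seed,
            "planted_period": self.planted_period,
            "planting_strength": self.planting_strength,
            "coding_fraction": self.coding_fraction,
            "params": self.params,
            "planted_peaks": [
                [iv.replicon, iv.start, iv.end] for iv in self.planted_peaks
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            mode=obj["mode"],
            seed=obj["seed"],
            planted_peaks=IntervalSet(
                [Interval(r, s, e) for r, s, e in obj["planted_peaks"]]
            ),
            planted_period=obj["planted_period"],
            planting_strength=obj["planting_strength"],
            coding_fraction=obj["coding_fraction"],
            params=obj["params"],
        )


def make_genome(
    length: int, gc_fraction: float, seed: int, replicon_id: str = "chr"
) -> GenomeSequence:
    """i.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return GenomeSequence({replicon_id: seq})


def plant_periodic_dinucleotides(
    genome: GenomeSequence,
    period: int,
    strength: float,
    dinucleotide_set: frozenset[str] | set[str] = frozenset({"AA", "TT", "TA"}),
    seed: int = 0,
) -> GenomeSequence:
    """Overwrite two bases at every position = 0 (mod period), with
    probability `strength`, by a uniformly chosen member of the set."""
    if period < 4:
        raise ValueError("period must be >= 4 (adjacent plants would overlap)")
    if not (0.0 <= strength <= 1.0):
        raise ValueError("strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    members = sorted(dinucleotide_set)
    out: dict[str, str] = {}
    for name, seq in genome.replicons.items():
        arr = np.array(list(seq))
        sites = np.arange(0, len(seq) - 1, period)
        hit = sites[rng.random(len(sites)) < strength]
        choices = rng.integers(0, len(members), size=len(hit))
        for pos, c in zip(hit, choices):
            arr[pos] = members[c][0]
            arr[pos + 1] = members[c][1]
        out[name] = "".join(arr)
    return GenomeSequence(out)


def make_annotation(
    genome: GenomeSequence,
    n_genes: int,
    coding_fraction: float,
    seed: int,
    min_gap: int = 20,
    min_gene_length: int = 60,
) -> GeneAnnotation:
    """Non-overlapping stranded genes hitting the target coding fraction.

    Gene lengths are drawn around the mean needed for the target; intergenic
    gaps are >= min_gap and randomly apportioned. Coding fraction is exact up
    to integer rounding (well within +/-1%).
    """
    if n_genes == 0:
        return GeneAnnotation([])
    records: list[GeneRecord] = []
    rng = np.random.default_rng(seed)
    total_len = genome.total_length
    gene_no = 0
    names = list(genome.replicons)
    alloc = {name: round(n_genes * len(genome.replicons[name]) / total_len) for name in names}
    alloc[names[-1]] += n_genes - sum(alloc.values())  # remainder to the last replicon
    for name, seq in genome.replicons.items():
        L = len(seq)
        n_here = alloc[name]
        if n_here <= 0:
            continue
        C = int(round(coding_fraction * L))
        G = L - C
        if n_here * min_gene_length > C or (n_here + 1) * min_gap > G:
            raise ValueError("infeasible packing: reduce n_genes or adjust fractions")
        # gene lengths: random weights scaled to sum C, floored at min length
        w = rng.uniform(0.5, 1.5, size=n_here)
        lens = np.maximum(min_gene_length, np.floor(w / w.sum() * C).astype(int))
        lens[-1] += C - lens.sum()  # absorb rounding in the last gene
        if lens[-1] < min_gene_length:
            raise ValueError("infeasible packing after rounding")
        # gaps: min_gap each plus a random split of the remainder
        extra = G - min_gap * (n_here + 1)
        split = rng.multinomial(extra, rng.dirichlet(np.ones(n_here + 1)))
        gaps = min_gap + split
        pos = 0
        for i in range(n_here):
            pos += int(gaps[i])
            start, end = pos, pos + int(lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            records.append(GeneRecord(name, start, end, strand, f"gene_{gene_no:05d}"))
            pos = end
    return GeneAnnotation(records)


def _intergenic_gaps(
    genome: GenomeSequence, annotation: GeneAnnotation
) -> dict[str, list[tuple[int, int]]]:
    gaps: dict[str, list[tuple[int, int]]] = {}
    genic = {
        rep: merge_intervals([(g.start, g.end) for g in genes], bookend=False)
        for rep, genes in annotation.by_replicon().items()
    }
    for rep, seq in genome.replicons.items():
        ivs = genic.get(rep, [])
        out = []
        prev = 0
        for s, e in ivs:
            if s > prev:
                out.append((prev, s))
            prev = e
        if prev < len(seq):
            out.append((prev, len(seq)))
        gaps[rep] = out
    return gaps


def _sample_counts(rng: np.random.Generator, lam: np.ndarray, overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, scale=lam / shape)
    return rng.poisson(lam).astype(float)


def simulate_chip_coverage(
    genome: GenomeSequence,
    annotation: GeneAnnotation,
    mode: str,
    seed: int,
    params: SimParams | None = None,
    noise_seed: int | None = None,
) -> tuple[CoverageTrack, CoverageTrack, SyntheticTruth]:
    """Paired IP/input coverage with planted enrichment of a given archetype.

    input = Poisson(lambda_bg) per base; IP = Poisson(lambda_bg * e(x)) with
    e(x) = 1 off-target and mode-specific enrichment on target (see module
    docstring). Truth records every planted interval and all parameters.

    `seed` fixes the planted enrichment landscape; `noise_seed` (default:
    same as `seed`) fixes the Poisson sampling, so replicate experiments of
    one binding landscape are simulated by varying `noise_seed` only.
    """
    if mode not in ("none", "TF", "NAP", "histone"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    rng_noise = np.random.default_rng(seed if noise_seed is None else noise_seed)
    enrich = {rep: np.ones(len(seq)) for rep, seq in genome.replicons.items()}
    planted: list[Interval] = []

    if mode == "TF":
        gaps = _intergenic_gaps(genome, annotation)
        all_gaps = [(rep, s, e) for rep, ivs in gaps.items() for s, e in ivs if e - s >= 40]
        names = list(genome.replicons)
        lens = np.array([len(genome.replicons[n]) for n in names], dtype=float)
        for _ in range(params.n_tf):
            if all_gaps and rng.random() < params.p_intergenic:
                rep, s, e = all_gaps[rng.integers(0, len(all_gaps))]
                c = int(rng.integers(s, e))
            else:
                i = rng.choice(len(names), p=lens / lens.sum())
                rep = names[i]
                c = int(rng.integers(0, lens[i]))
            fold = rng.uniform(*params.tf_fold)
            sd = params.tf_sd
            L = len(enrich[rep])
            lo, hi = max(0, int(c - 4 * sd)), min(L, int(c + 4 * sd))
            x = np.arange(lo, hi)
            enrich[rep][lo:hi] += (fold - 1.0) * np.exp(-0.5 * ((x - c) / sd) ** 2)
            planted.append(
                Interval(rep, max(0, int(c - 2 * sd)), min(L, int(c + 2 * sd)))
            )

    elif mode == "NAP":
        if params.nap_target_coverage > 0.9:
            raise ValueError("target coverage fraction > 0.9 is infeasible")
        names = list(genome.replicons)
        lens = np.array([len(genome.replicons[n]) for n in names], dtype=float)
        target_bp = params.nap_target_coverage * genome.total_length
        covered = 0
        attempts = 0
        while covered < target_bp and attempts < 100000:
            attempts += 1
            w = int(rng.integers(params.nap_width[0], params.nap_width[1] + 1))
            i = rng.choice(len(names), p=lens / lens.sum())
            if lens[i] <= w:
                continue
            s = int(rng.integers(0, lens[i] - w))
            iv = Interval(names[i], s, s + w)
            if any(
                p.replicon == iv.replicon and p.start < iv.end and iv.start < p.end
                for p in planted
            ):
                continue
            fold = rng.uniform(*params.nap_fold)
            enrich[iv.replicon][iv.start : iv.end] = fold
            planted.append(iv)
            covered += w
        if covered < target_bp:
            raise ValueError("could not reach target coverage after max retries")

    elif mode == "histone":
        step = params.core + params.linker
        for g in annotation:
            e_vec = enrich[g.replicon]
            L = len(e_vec)
            if g.strand == "+":
                nfr_lo, nfr_hi = g.start - params.nfr, g.start
                body = range(g.start, g.end - params.core + 1, step)
                cores = [(s, s + params.core) for s in body]
            else:
                nfr_lo, nfr_hi = g.end, g.end + params.nfr
                body = range(g.end, g.start + params.core - 1, -step)
                cores = [(s - params.core, s) for s in body]
            for s, e in cores:
                s, e = max(0, s), min(L, e)
                if s < e:
                    e_vec[s:e] = np.maximum(e_vec[s:e], params.histone_fold)
                    planted.append(Interval(g.replicon, s, e))
            s, e = max(0, nfr_lo), min(L, nfr_hi)
            if s < e:
                e_vec[s:e] = np.minimum(e_vec[s:e], params.nfr_fold)

    ip = CoverageTrack(
        {rep: _sample_counts(rng_noise, params.lambda_bg * e, params.overdispersion)
         for rep, e in enrich.items()},
        label="IP",
    )
    inp = CoverageTrack(
        {rep: _sample_counts(rng_noise, np.full(len(e), params.lambda_bg), params.overdispersion)
         for rep, e in enrich.items()},
        label="input",
    )
    # normalize to JSON-stable types so parameters round-trip exactly
    param_record = json.loads(json.dumps(dataclasses.asdict(params)))
    truth = SyntheticTruth(
        mode=mode,
        seed=seed,
        planted_peaks=IntervalSet(planted),
        params=param_record,
    )
    return ip, inp, truth


def simple_peak_caller(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    fold_threshold: float = 1.5,
    min_width: int = 100,
    smoothing_bw: int = 150,
    pseudocount: float = 1.0,
    background_quantile: float = 0.10,
) -> IntervalSet:
    """Call peaks as maximal runs where the smoothed IP/input ratio stays at
    or above `fold_threshold` times the background level for >= `min_width`
    bases.

    The background level is estimated per replicon as a low quantile of the
    smoothed ratio (`background_quantile`, capped at 1.0 so sparse-enrichment
    tracks behave as a plain fold cutoff). Library-size scaling in the ratio
    compresses genuinely enriched signal when enrichment covers much of the
    genome (histone-like tracks); thresholding relative to the background
    keeps the fold criterion meaningful there. Smoothing is a centered moving
    average of width `smoothing_bw`; bumps closer than the bandwidth may
    merge into one call.
    """
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    if fold_threshold <= 1.0:
        raise ValueError("fold_threshold must exceed 1")
    ratio = ratio_track(ip, input_track, pseudocount=pseudocount)
    out: list[Interval] = []
    kernel = np.ones(max(1, smoothing_bw)) / max(1, smoothing_bw)
    for rep, vec in ratio.depths.items():
        sm = np.convolve(vec, kernel, mode="same") if smoothing_bw > 1 else vec
        background = min(1.0, float(np.quantile(sm, background_quantile)))
        above = sm >= fold_threshold * background
        if not above.any():
            continue
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.concatenate(([0], starts))
        if above[-1]:
            ends = np.concatenate((ends, [len(vec)]))
        for s, e in zip(starts, ends):
            if e - s >= min_width:
                out.append(Interval(rep, int(s), int(e)))
    return IntervalSet(out)


def truth_coverage_fraction(truth: SyntheticTruth, genome: GenomeSequence) -> float:
    """Fraction of the genome covered by the union of planted intervals."""
    by_rep: dict[str, list[tuple[int, int]]] = {}
    for iv in truth.planted_peaks:
        by_rep.setdefault(iv.replicon, []).append((iv.start, iv.end))
    return sum(union_length(v) for v in by_rep.values()) / genome.total_length
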