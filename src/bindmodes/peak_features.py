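"""Binding-site statistics: replicate-majority peak sets, width and coverage,
genic/intergenic classification of peak centers, and hypergeometric
enrichment of peaks in intergenic space.

The hypergeometric universe is base pairs: N = genome length, K = intergenic
bp, draws = peaks, successes = peaks whose center falls in intergenic space.
Strand is ignored for coding membership.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core import (
    GeneAnnotation,
    GenomeSequence,
    Interval,
    IntervalSet,
    merge_intervals,
    union_length,
)

logger = logging.getLogger(__name__)


@dataclass
class PeakStats:
    n_peaks: int
    mean_width: float | None  # bp; None for an empty peak set
    median_width: float | None
    union_bp: int
    coverage_pct: float


@dataclass
class LocationClassification:
    centers: list[tuple[str, int]]  # (replicon, center bp) per peak
    classes: list[str]  # "coding" | "intergenic", parallel to centers
    k_intergenic: int
    n_peaks: int
    K_intergenic_bp: int
    N_total_bp: int
    enrichment_p: float | None = None
    depletion_p: float | None = None

    @property
    def intergenic_pct(self) -> float:
        return 100.0 * self.k_intergenic / self.n_peaks if self.n_peaks else float("nan")


def merge_replicate_peaks(
    peak_sets: list[IntervalSet], min_replicates: int | None = None
) -> IntervalSet:
    """Majority-intersection of replicate peak sets.

    The genome is partitioned by the per-base count of replicate sets whose
    (self-unioned) peaks cover it; maximal intervals where the count reaches
    `min_replicates` (default floor(R/2)+1, e.g. 2 of 3) are kept, and
    bookended survivors are merged.
    """
    R = len(peak_sets)
    if R < 2:
        raise ValueError("need at least 2 replicate peak sets")
    if min_replicates is None:
        min_replicates = R // 2 + 1
    replicons: set[str] = set()
    for ps in peak_sets:
        replicons.update(iv.replicon for iv in ps)
    out: list[Interval] = []
    for rep in sorted(replicons):
        # event sweep over the union of each replicate's merged intervals
        events: dict[int, int] = {}
        for ps in peak_sets:
            merged = merge_intervals(
                [(iv.start, iv.end) for iv in ps if iv.replicon == rep],
                bookend=False,
            )
            for s, e in merged:
                events[s] = events.get(s, 0) + 1
                events[e] = events.get(e, 0) - 1
        depth = 0
        run_start = None
        survivors: list[tuple[int, int]] = []
        for pos in sorted(events):
            prev = depth
            depth += events[pos]
            if prev < min_replicates <= depth:
                run_start = pos
            elif prev >= min_replicates > depth:
                survivors.append((run_start, pos))
                run_start = None
        out.extend(Interval(rep, s, e) for s, e in merge_intervals(survivors))
    return IntervalSet(out)


def peak_stats(peaks: IntervalSet, genome: GenomeSequence) -> PeakStats:
    """Count, width and genome-coverage statistics of a peak set."""
    peaks.validate_against(genome)
    n = len(peaks)
    if n == 0:
        return PeakStats(0, None, None, 0, 0.0)
    widths = peaks.widths()
    union_bp = sum(
        union_length([(iv.start, iv.end) for iv in ivs])
        for ivs in peaks.by_replicon().values()
    )
    return PeakStats(
        n_peaks=n,
        mean_width=float(widths.mean()),
        median_width=float(np.median(widths)),
        union_bp=union_bp,
        coverage_pct=100.0 * union_bp / genome.total_length,
    )


def _genic_union(annotation: GeneAnnotation) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for rep, genes in annotation.by_replicon().items():
        out[rep] = merge_intervals([(g.start, g.end) for g in genes], bookend=False)
    return out


def coding_fraction(annotation: GeneAnnotation, genome: GenomeSequence) -> float:
    """Fraction of genome bp covered by the union of gene intervals."""
    genic = _genic_union(annotation)
    covered = sum(
        sum(e - s for s, e in ivs)
        for rep, ivs in genic.items()
        if rep in genome
    )
    return covered / genome.total_length


def classify_peak_locations(
    peaks: IntervalSet, annotation: GeneAnnotation, genome: GenomeSequence
) -> LocationClassification:
    """Classify each peak center as coding or intergenic (strand-free).

    The center is floor((start+end)/2); it is coding iff it lies inside at
    least one gene interval (half-open membership).
    """
    peaks.validate_against(genome)
    genic = _genic_union(annotation)
    # flatten for binary search: center is coding iff it falls in a merged run
    search = {
        rep: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for rep, ivs in genic.items()
    }
    centers: list[tuple[str, int]] = []
    classes: list[str] = []
    for iv in peaks:
        c = iv.center
        centers.append((iv.replicon, c))
        if iv.replicon not in search:
            logger.warning(
                "peak on replicon %r absent from annotation: counted intergenic",
                iv.replicon,
            )
            classes.append("intergenic")
            continue
        starts, ends = search[iv.replicon]
        j = bisect_right(starts, c) - 1
        classes.append("coding" if j >= 0 and c < ends[j] else "intergenic")
    N = genome.total_length
    genic_bp = sum(
        sum(e - s for s, e in ivs) for rep, ivs in genic.items() if rep in genome
    )
    return LocationClassification(
        centers=centers,
        classes=classes,
        k_intergenic=classes.count("intergenic"),
        n_peaks=len(peaks),
        K_intergenic_bp=N - genic_bp,
        N_total_bp=N,
    )


def intergenic_enrichment_test(
    classification: LocationClassification,
) -> tuple[float, float]:
    """Exact hypergeometric tails for intergenic enrichment/depletion.

    X ~ Hypergeometric(N = genome bp, K = intergenic bp, n = peaks);
    enrichment_p = P(X >= k), depletion_p = P(X <= k). The classification's
    p-value fields are filled in place and the pair returned.
    """
    k = classification.k_intergenic
    K = classification.K_intergenic_bp
    n = classification.n_peaks
    N = classification.N_total_bp
    if not (0 < n <= N and K <= N and k <= n):
        raise ValueError("inconsistent hypergeometric parameters")
    dist = hypergeom(N, K, n)
    enrichment_p = float(min(1.0, dist.sf(k - 1)))
    depletion_p = float(min(1.0, dist.cdf(k)))
    classification.enrichment_p = enrichment_p
    classification.depletion_p = depletion_p
    return enrichment_p, depletion_p
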