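"""Per-protein binding-feature summaries and qualitative axis labels.

The three axes — binding frequency (genome coverage), peak width, and
location preference — plus a sequence-specificity mode separate the
canonical archetypes: TFs (low-frequency, narrow, promoter-preferring),
NAPs (high-frequency, broad, location-agnostic) and histones
(high-frequency, periodicity-associated). The numeric thresholds are
explicit configuration, not biological claims, and are echoed in every
output so alternative cutoffs can be compared.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .peak_features import LocationClassification, PeakStats
from .periodicity import NullDistribution, SpectralPeak


@dataclass
class AxisThresholds:
    """Classification cutoffs. Strict inequality defines 'low' and 'narrow'."""

    coverage_low_pct: float = 3.0  # frequency low iff coverage < this
    coverage_high_pct: float = 10.0  # frequency high iff coverage >= this
    width_narrow_bp: float = 700.0  # narrow iff mean width < this
    enrichment_alpha: float = 1e-3  # promoter-preferring needs p below this
    null_alpha: float = 0.05  # periodicity needs empirical p at or below this
    periodicity_band: str = "10bp"  # region band that defines the mode


@dataclass
class BindingFeatureSummary:
    protein: str
    n_peaks: int = 0
    mean_width: float | None = None
    coverage_pct: float | None = None
    intergenic_pct: float | None = None
    noncoding_pct: float | None = None
    enrichment_p: float | None = None
    genome_band_peaks: dict[str, SpectralPeak] = field(default_factory=dict)
    region_band_peaks: dict[str, SpectralPeak] = field(default_factory=dict)
    null_empirical_p: float | None = None
    motif_evidence: bool | None = None  # user-supplied; motif search is external
    # axis labels, filled by classify_axes
    frequency: str = "unknown"
    width_class: str = "unknown"
    location: str = "unknown"
    sequence_mode: str = "unknown"
    thresholds: dict = field(default_factory=dict)


def build_summary(
    protein: str,
    peak_stats: PeakStats,
    classification: LocationClassification | None = None,
    genome_peaks: dict[str, SpectralPeak] | None = None,
    region_peaks: dict[str, SpectralPeak] | None = None,
    null: NullDistribution | None = None,
    motif_evidence: bool | None = None,
    thresholds: AxisThresholds | None = None,
) -> BindingFeatureSummary:
    """Aggregate the per-protein numeric results and assign axis labels.

    An empty peak set leaves width/location/region fields missing and the
    frequency axis 'low'.
    """
    s = BindingFeatureSummary(
        protein=protein,
        n_peaks=peak_stats.n_peaks,
        mean_width=peak_stats.mean_width,
        coverage_pct=peak_stats.coverage_pct,
        genome_band_peaks=genome_peaks or {},
        region_band_peaks=region_peaks or {},
        null_empirical_p=null.empirical_p if null is not None else None,
        motif_evidence=motif_evidence,
    )
    if classification is not None and classification.n_peaks > 0:
        s.intergenic_pct = classification.intergenic_pct
        s.noncoding_pct = (
            100.0 * classification.K_intergenic_bp / classification.N_total_bp
        )
        s.enrichment_p = classification.enrichment_p
    return classify_axes(s, thresholds or AxisThresholds())


def classify_axes(
    summary: BindingFeatureSummary, thresholds: AxisThresholds | None = None
) -> BindingFeatureSummary:
    """Deterministic axis labels from the numeric fields; missing -> 'unknown'.

    frequency: low iff coverage < coverage_low_pct (strict), high iff
    coverage >= coverage_high_pct, else intermediate. width_class: narrow iff
    mean_width < width_narrow_bp (strict). location: promoter-preferring iff
    enrichment_p < enrichment_alpha AND intergenic_pct > noncoding_pct, else
    agnostic. sequence_mode: periodicity-preferring iff the configured region
    band is detected with null empirical p <= null_alpha; else motif-like if
    user-supplied motif evidence is present; else none.

    Idempotent: re-classifying an already labelled summary reassigns the same
    labels from the same numeric fields.
    """
    t = thresholds or AxisThresholds()
    s = summary

    if s.coverage_pct is None:
        s.frequency = "unknown"
    elif s.coverage_pct < t.coverage_low_pct:
        s.frequency = "low"
    elif s.coverage_pct >= t.coverage_high_pct:
        s.frequency = "high"
    else:
        s.frequency = "intermediate"

    if s.mean_width is None:
        s.width_class = "unknown"
    else:
        s.width_class = "narrow" if s.mean_width < t.width_narrow_bp else "broad"

    if s.enrichment_p is None or s.intergenic_pct is None or s.noncoding_pct is None:
        s.location = "unknown"
    elif s.enrichment_p < t.enrichment_alpha and s.intergenic_pct > s.noncoding_pct:
        s.location = "promoter-preferring"
    else:
        s.location = "agnostic"

    band = s.region_band_peaks.get(t.periodicity_band)
    if band is not None and band.detected and (
        s.null_empirical_p is not None and s.null_empirical_p <= t.null_alpha
    ):
        s.sequence_mode = "periodicity-preferring"
    elif s.motif_evidence:
        s.sequence_mode = "motif-like/unknown"
    elif band is None and not s.region_band_peaks:
        s.sequence_mode = "unknown" if s.n_peaks == 0 else "none"
    else:
        s.sequence_mode = "none"

    s.thresholds = dataclasses.asdict(t)
    return s
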