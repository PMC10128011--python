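"""Strand-aware ORF-start occupancy matrices and metagene profiles.

Each gene contributes a row of per-base depth over a window around its ORF
translation start site, oriented so negative columns are upstream on both
strands, and normalized to the mean depth of the gene's own replicon.
Averaging the rows yields the metagene occupancy profile: TFs show a sharp
promoter-proximal peak, phased nucleosome arrays show a promoter trough
followed by regularly spaced peaks, and architecture-free binders are flat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CoverageTrack, GeneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class OccupancyMatrix:
    gene_ids: list[str]
    positions: np.ndarray  # relative positions -W..+W, 0 = ORF start site
    values: np.ndarray  # (n_genes, 2W+1), NaN where outside the replicon

    @property
    def window(self) -> int:
        return (len(self.positions) - 1) // 2


@dataclass
class OccupancyProfile:
    positions: np.ndarray
    mean: np.ndarray  # per-position mean over non-missing rows
    n_genes: np.ndarray  # contributing genes per position


def occupancy_matrix(
    track: CoverageTrack, annotation: GeneAnnotation, window: int = 400
) -> OccupancyMatrix:
    """Depth around each ORF start, strand-oriented and replicon-normalized.

    For a forward gene with start s, column c holds depth[s + c]; for a
    reverse gene, depth[s - c] — so upstream is always at negative columns.
    Cells outside the replicon are NaN. Values are divided by the replicon's
    mean depth; a zero-mean replicon yields all-NaN rows with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    lengths = track.lengths()
    means = {rep: float(vec.mean()) if len(vec) else 0.0 for rep, vec in track.depths.items()}
    offsets = np.arange(-window, window + 1)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for g in annotation:
        if g.replicon not in lengths:
            raise ValueError(f"gene {g.gene_id!r} on replicon absent from track")
        gene_ids.append(g.gene_id)
        m = means[g.replicon]
        if m == 0.0:
            logger.warning("replicon %r has zero mean depth; all-missing rows", g.replicon)
            rows.append(np.full(len(offsets), np.nan))
            continue
        s = g.orf_start
        pos = s + offsets if g.strand == "+" else s - offsets
        row = np.full(len(offsets), np.nan)
        ok = (pos >= 0) & (pos < lengths[g.replicon])
        row[ok] = track[g.replicon][pos[ok]] / m
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, len(offsets)))
    return OccupancyMatrix(gene_ids=gene_ids, positions=offsets, values=values)


def average_profile(matrix: OccupancyMatrix) -> OccupancyProfile:
    """Per-position mean across genes, ignoring missing cells."""
    if matrix.values.shape[0] < 1:
        raise ValueError("occupancy matrix has no rows")
    n_genes = np.sum(~np.isnan(matrix.values), axis=0)
    mean = np.full(matrix.values.shape[1], np.nan)
    ok = n_genes > 0
    if ok.any():
        mean[ok] = np.nanmean(matrix.values[:, ok], axis=0)
    return OccupancyProfile(positions=matrix.positions, mean=mean, n_genes=n_genes)


def ratio_track(
    ip: CoverageTrack, input_track: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """IP/input binding-enrichment track, library-size scaled.

    Per base: (ip + eps) / (input * s + eps), where s = total_ip/total_input
    scales the input to equal total depth. A zero-total input leaves s = 1
    (logged), making the ratio degenerate but defined.
    """
    if ip.lengths() != input_track.lengths():
        raise ValueError("IP and input tracks have mismatched replicons/lengths")
    total_ip, total_in = ip.total(), input_track.total()
    if total_in > 0:
        s = total_ip / total_in
    else:
        s = 1.0
        logger.warning("input track has zero total depth; no library-size scaling")
    eps = pseudocount
    depths = {
        rep: (ip[rep] + eps) / (input_track[rep] * s + eps)
        for rep in ip.depths
    }
    return CoverageTrack(depths, label="ratio")
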