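"""Allele-level analysis: expected VAF, LOH detection, CNV filters/distances.

A tumor sample is a mixture of tumor cells (fraction p, the cellularity) and
normal cells.  For a site where the normal genotype carries ``g`` alt copies
out of 2 and the tumor carries ``c_alt`` of ``c_tot``, the expected variant
allele frequency is

    VAF = ((1-p) * g + p * c_alt) / ((1-p) * 2 + p * c_tot)

LOH at a germline-het site (g=1) is detected by comparing binomial
likelihoods of the observed alt/total reads under the retained-het model
(expected VAF exactly 0.5 for any p) against the best of a small family of
loss models (hemizygous loss of either allele, copy-neutral LOH in either
direction).  A site is called LOH when the log-likelihood ratio exceeds a
threshold (default 3.0, ~e^3 odds), and indeterminate below a depth floor.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .types import CNVSegment, LOHCall

#: (tumor_alt_copies, tumor_total_copies) loss states scored against
#: retained (1, 2): hemizygous loss of alt, hemizygous loss of ref,
#: copy-neutral loss of alt, copy-neutral loss of ref.
DEFAULT_LOSS_MODELS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (0, 2), (2, 2))


def expected_vaf(
    cellularity: float,
    germline_alt_copies: int,
    tumor_alt_copies: int,
    tumor_total_copies: int,
) -> float:
    """Expected VAF in a tumor/normal mixture; NaN when no DNA is present."""
    if not 0.0 <= cellularity <= 1.0:
        raise ValueError(f"cellularity must be in [0, 1] (got {cellularity})")
    if germline_alt_copies not in (0, 1, 2):
        raise ValueError("germline_alt_copies must be 0, 1 or 2")
    if tumor_alt_copies < 0 or tumor_total_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    if tumor_alt_copies > tumor_total_copies:
        raise ValueError("tumor_alt_copies exceeds tumor_total_copies")
    p = cellularity
    numerator = (1.0 - p) * germline_alt_copies + p * tumor_alt_copies
    denominator = (1.0 - p) * 2.0 + p * tumor_total_copies
    if denominator == 0.0:
        return math.nan
    return numerator / denominator


def detect_loh(
    counts: Sequence[tuple[int, int]],
    cellularity: float,
    llr_threshold: float = 3.0,
    min_depth: int = 20,
    error_rate: float = 0.001,
    loss_models: Sequence[tuple[int, int]] = DEFAULT_LOSS_MODELS,
    keys: Optional[Sequence] = None,
) -> list[LOHCall]:
    """LOH calls for germline-het sites from tumor (alt, total) read counts.

    Each site is scored by the binomial log-likelihood ratio of the best
    loss model over the retained-het model; sequencing error pulls expected
    VAFs slightly toward 0.5 so boundary models (VAF 0 or 1) stay proper.
    """
    if cellularity is None:
        raise ValueError("cellularity is required for LOH detection")
    if keys is None:
        keys = list(range(len(counts)))

    def adjusted(v: float) -> float:
        return v * (1.0 - error_rate) + (1.0 - v) * error_rate

    retained_vaf = adjusted(expected_vaf(cellularity, 1, 1, 2))
    loss_vafs = [
        adjusted(expected_vaf(cellularity, 1, c_alt, c_tot))
        for c_alt, c_tot in loss_models
    ]
    calls = []
    for key, (alt_reads, total_reads) in zip(keys, counts):
        if alt_reads < 0 or total_reads < 0 or alt_reads > total_reads:
            raise ValueError(f"invalid read counts ({alt_reads}, {total_reads})")
        if total_reads < min_depth:
            calls.append(LOHCall(key, "indeterminate", 0.0))
            continue
        retained_ll = binom.logpmf(alt_reads, total_reads, retained_vaf)
        best_loss_ll = max(
            binom.logpmf(alt_reads, total_reads, v) for v in loss_vafs
        )
        llr = float(best_loss_ll - retained_ll)
        status = "LOH" if llr > llr_threshold else "retained"
        calls.append(LOHCall(key, status, llr))
    return calls


def cnv_candidate_filter(segments: Sequence[CNVSegment]) -> list[CNVSegment]:
    """Candidate CNV events: copy number 0 or > 6, segment length > 20 kb."""
    return [
        seg
        for seg in segments
        if (seg.copy_number == 0 or seg.copy_number > 6) and seg.length > 20_000
    ]


def _rasterize(
    segments: Sequence[CNVSegment], chrom: str, n_bins: int, bin_size: int
) -> np.ndarray:
    """Per-bin copy number; ties between overlapping segments go to the one
    covering the bin midpoint, then to the largest overlap, then to the
    leftmost segment. Uncovered bins are NaN."""
    values = np.full(n_bins, np.nan)
    chrom_segs = [s for s in segments if s.chrom == chrom]
    for b in range(n_bins):
        bin_start = b * bin_size + 1
        bin_end = bin_start + bin_size - 1
        midpoint = (bin_start + bin_end) // 2
        overlapping = [
            s for s in chrom_segs if s.start <= bin_end and s.end >= bin_start
        ]
        if not overlapping:
            continue
        covering = [s for s in overlapping if s.overlaps(midpoint)]
        if covering:
            chosen = min(covering, key=lambda s: s.start)
        else:
            chosen = max(
                overlapping,
                key=lambda s: (min(s.end, bin_end) - max(s.start, bin_start), -s.start),
            )
        values[b] = chosen.copy_number
    return values


def cnv_heterogeneity(
    profiles: Mapping[str, Sequence[CNVSegment]],
    bin_size: int = 1_000_000,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Pairwise copy-number distance matrix between region profiles.

    Profiles are rasterized to fixed bins; the distance between two regions
    is the mean absolute log2 ratio of pseudocounted copy numbers over bins
    covered in both.  The pseudocount keeps homozygous deletions (CN 0)
    finite.  Pairs with no shared covered bin get NaN.
    """
    regions = list(profiles)
    if len(regions) < 2:
        raise ValueError("at least two region profiles are required")
    chroms = sorted({s.chrom for segs in profiles.values() for s in segs})
    rasters: dict[str, np.ndarray] = {r: np.empty(0) for r in regions}
    for chrom in chroms:
        extent = max(
            s.end for segs in profiles.values() for s in segs if s.chrom == chrom
        )
        n_bins = math.ceil(extent / bin_size)
        for region in regions:
            values = _rasterize(profiles[region], chrom, n_bins, bin_size)
            rasters[region] = np.concatenate([rasters[region], values])

    matrix = pd.DataFrame(0.0, index=regions, columns=regions)
    for a, b in combinations(regions, 2):
        mask = ~np.isnan(rasters[a]) & ~np.isnan(rasters[b])
        if not mask.any():
            dist = math.nan
        else:
            log_ratio = np.log2(
                (rasters[a][mask] + pseudocount) / (rasters[b][mask] + pseudocount)
            )
            dist = float(np.mean(np.abs(log_ratio)))
        matrix.loc[a, b] = dist
        matrix.loc[b, a] = dist
    return matrix
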