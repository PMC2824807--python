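"""Comparison of two ChIP experiments (stages, antibodies, or replicates).

Covers the shared/unique target-set arithmetic, the per-site signal scatter,
and the 600 bp-bin input-normalized Pearson correlation used to show
concordance of two immunoprecipitations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BindingSite, CoverageTrack
from .peaks import LAMBDA_FLOOR

DEFAULT_BIN = 600


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class OverlapReport:
    n_targets_a: int
    n_targets_b: int
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    frac_unique_a: float
    frac_unique_b: float

    @property
    def pct_unique_a(self) -> int:
        """Display percentage, rounded half away from zero."""
        return _round_half_away(100 * self.frac_unique_a)

    @property
    def pct_unique_b(self) -> int:
        return _round_half_away(100 * self.frac_unique_b)


def compare_target_sets(genes_a: set[str], genes_b: set[str]) -> OverlapReport:
    """Exact set arithmetic between two target-gene sets."""
    genes_a, genes_b = set(genes_a), set(genes_b)
    shared = genes_a & genes_b
    unique_a = genes_a - genes_b
    unique_b = genes_b - genes_a
    return OverlapReport(
        n_targets_a=len(genes_a),
        n_targets_b=len(genes_b),
        n_shared=len(shared),
        n_unique_a=len(unique_a),
        n_unique_b=len(unique_b),
        frac_unique_a=len(unique_a) / len(genes_a) if genes_a else 0.0,
        frac_unique_b=len(unique_b) / len(genes_b) if genes_b else 0.0,
    )


def _tile_site(start: int, end: int, bin_size: int) -> list[tuple[int, int]]:
    """Tile an interval into bins; a terminal partial bin shorter than half
    the bin size is merged into the previous bin."""
    bins = []
    pos = start
    while pos < end:
        bins.append((pos, min(pos + bin_size, end)))
        pos += bin_size
    if len(bins) > 1 and bins[-1][1] - bins[-1][0] < bin_size / 2:
        last = bins.pop()
        prev = bins.pop()
        bins.append((prev[0], last[1]))
    return bins


def _normalized_bin_values(
    bins: list[tuple[str, int, int]],
    track: CoverageTrack,
    input_: CoverageTrack,
) -> np.ndarray:
    scale = track.total_mapped_reads / input_.total_mapped_reads
    values = []
    for chrom, start, end in bins:
        c = track.region_sum(chrom, start, end)
        lam = max(input_.region_sum(chrom, start, end) * scale, LAMBDA_FLOOR)
        values.append(c / lam)
    return np.array(values)


def binned_signal_correlation(
    sites: list[BindingSite],
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    input_a: CoverageTrack,
    input_b: CoverageTrack,
    bin_size: int = DEFAULT_BIN,
    mode: str = "pooled",
) -> float:
    """Pearson correlation of input-normalized binned signal across sites.

    Each site interval is tiled into ``bin_size``-bp bins; per bin the tag
    count over scaled input is computed for each sample. ``mode='pooled'``
    correlates all bins at once; ``mode='per_site'`` computes a correlation
    per site (sites with >= 2 bins) and returns the average.
    """
    if mode not in ("pooled", "per_site"):
        raise ValueError("mode must be 'pooled' or 'per_site'")
    site_bins = [
        [(s.chrom, lo, hi) for lo, hi in _tile_site(s.start, s.end, bin_size)]
        for s in sites
    ]
    all_bins = [b for bins in site_bins for b in bins]
    if len(all_bins) < 2:
        raise ValueError("need at least 2 bins to correlate")
    if mode == "pooled":
        va = _normalized_bin_values(all_bins, track_a, input_a)
        vb = _normalized_bin_values(all_bins, track_b, input_b)
        return float(stats.pearsonr(va, vb).statistic)
    rs = []
    for bins in site_bins:
        if len(bins) < 2:
            continue
        va = _normalized_bin_values(bins, track_a, input_a)
        vb = _normalized_bin_values(bins, track_b, input_b)
        if va.std() == 0 or vb.std() == 0:
            continue
        rs.append(stats.pearsonr(va, vb).statistic)
    if not rs:
        raise ValueError("no site had >= 2 bins with variable signal")
    return float(np.mean(rs))


def _merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end)))
        else:
            merged.append((chrom, start, end))
    return merged


def signal_scatter(
    sites_a: list[BindingSite],
    sites_b: list[BindingSite],
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    input_a: CoverageTrack,
    input_b: CoverageTrack,
) -> pd.DataFrame:
    """Paired input-normalized signal over the union of both site lists.

    One row per merged interval of the union, with each stage's signal —
    the table behind a cross-stage binding scatter plot.
    """
    union = _merge_intervals(
        [(s.chrom, s.start, s.end) for s in sites_a + sites_b]
    )
    scale_a = track_a.total_mapped_reads / input_a.total_mapped_reads
    scale_b = track_b.total_mapped_reads / input_b.total_mapped_reads
    in_a = {(s.chrom, s.start, s.end) for s in sites_a}
    rows = []
    for chrom, start, end in union:
        ca = track_a.region_sum(chrom, start, end)
        cb = track_b.region_sum(chrom, start, end)
        la = max(input_a.region_sum(chrom, start, end) * scale_a, LAMBDA_FLOOR)
        lb = max(input_b.region_sum(chrom, start, end) * scale_b, LAMBDA_FLOOR)
        rows.append(
            {
                "chrom": chrom, "start": start, "end": end,
                "signal_a": ca / la, "signal_b": cb / lb,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal_a", "signal_b"])
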