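"""Sliding-window peak scoring of ChIP versus input coverage.

A deliberately transparent scorer: ChIP and input counts are summed per
window, the input sum is scaled by the ratio of total mapped reads, and the
window p-value is the upper-tail Poisson probability of the ChIP sum given
the scaled input as the rate. Significant windows that overlap or abut are
merged into binding sites. No multiple-testing correction is applied to the
site calls themselves — filtering is on raw p as is conventional for this
style of analysis — but a Benjamini-Hochberg FDR column is available for
window tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BindingSite, CoverageTrack, GenomeAnnotation, derive_tss

#: Scaled-input rate floor per window, guarding against p = 0 artifacts in
#: zero-input windows.
LAMBDA_FLOOR = 0.5

WINDOW_COLUMNS = [
    "chrom", "start", "end", "chip_count", "input_scaled", "ratio", "p_value",
]


def _check_tracks(chip: CoverageTrack, input_: CoverageTrack) -> None:
    if chip.chromosomes != input_.chromosomes:
        raise ValueError(
            "chip and input tracks cover different chromosomes: "
            f"{chip.chromosomes} vs {input_.chromosomes}"
        )
    if not chip.data or all(n == 0 for n in chip.chromosomes.values()):
        raise ValueError("zero-length track")


def _window_sums(arr: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    csum = np.concatenate(([0.0], np.cumsum(arr, dtype=float)))
    ends = np.minimum(starts + window, arr.size)
    return csum[ends] - csum[starts]


def _poisson_upper_tail(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """P[X >= k] for X ~ Poisson(lam); equals 1 at k = 0.

    Floored at 1e-300: extreme enrichment underflows the survival function
    to exactly zero, which would break downstream p-value handling.
    """
    return np.maximum(stats.poisson.sf(np.asarray(k) - 1, lam), 1e-300)


def sliding_window_scores(
    chip: CoverageTrack,
    input_: CoverageTrack,
    window: int = 200,
    step: int = 50,
    input_smooth: int = 10,
) -> pd.DataFrame:
    """Score every ``window``-bp window (stepped by ``step``) genome-wide.

    Returns a frame with one row per window: ChIP sum, library-size-scaled
    input sum, enrichment ratio, and upper-tail Poisson p-value.

    The background rate for a window is estimated from the input over a span
    of ``input_smooth`` windows centered on it (rescaled to the window
    width), not from the single matching input window: with a 1:1 window the
    Poisson test compares against a rate estimate as noisy as the signal and
    the false-positive rate at a nominal cutoff roughly doubles per extra
    unit of sampling noise. ``input_smooth=1`` recovers the raw per-window
    input sum.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    if input_smooth < 1:
        raise ValueError("input_smooth must be >= 1")
    _check_tracks(chip, input_)
    scale = chip.total_mapped_reads / input_.total_mapped_reads
    frames = []
    for chrom in sorted(chip.data):
        arr_c = chip.data[chrom]
        arr_i = input_.data[chrom]
        length = arr_c.size
        if length == 0:
            continue
        starts = np.arange(0, max(length - window, 0) + 1, step)
        chip_sums = _window_sums(arr_c, starts, window)
        span = window * input_smooth
        span_lo = np.clip(starts - (span - window) // 2, 0, None)
        span_hi = np.minimum(span_lo + span, length)
        span_lo = np.maximum(span_hi - span, 0)
        csum_i = np.concatenate(([0.0], np.cumsum(arr_i, dtype=float)))
        span_sums = csum_i[span_hi] - csum_i[span_lo]
        input_scaled = span_sums * (window / (span_hi - span_lo)) * scale
        lam = np.maximum(input_scaled, LAMBDA_FLOOR)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window, length),
                    "chip_count": chip_sums,
                    "input_scaled": input_scaled,
                    "ratio": chip_sums / lam,
                    "p_value": _poisson_upper_tail(chip_sums, lam),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(p_values), method="bh")


def call_sites(
    scores: pd.DataFrame,
    p_cutoff: float,
    chip: CoverageTrack | None = None,
    input_: CoverageTrack | None = None,
) -> list[BindingSite]:
    """Merge significant windows (p < cutoff) into binding sites.

    Overlapping or abutting significant windows become one site whose
    p-value is the minimum member p-value. When the tracks are provided the
    site signal is the ChIP/scaled-input ratio recomputed over the merged
    interval; otherwise the best member window's ratio is used.
    """
    hits = scores[scores["p_value"] < p_cutoff]
    if hits.empty:
        return []
    scale = None
    if chip is not None and input_ is not None:
        scale = chip.total_mapped_reads / input_.total_mapped_reads
    sites: list[BindingSite] = []
    for chrom, group in hits.groupby("chrom", sort=True):
        group = group.sort_values(["start", "end"])
        cur_start = cur_end = None
        cur_p = 1.0
        cur_ratio = 0.0

        def flush():
            if cur_start is None:
                return
            if scale is not None:
                c = chip.region_sum(chrom, cur_start, cur_end)
                lam = max(input_.region_sum(chrom, cur_start, cur_end) * scale,
                          LAMBDA_FLOOR)
                signal = c / lam
            else:
                signal = cur_ratio
            sites.append(
                BindingSite(chrom=chrom, start=int(cur_start), end=int(cur_end),
                            p_value=float(cur_p), signal=float(signal))
            )

        for row in group.itertuples(index=False):
            if cur_start is None or row.start > cur_end:
                flush()
                cur_start, cur_end = row.start, row.end
                cur_p, cur_ratio = row.p_value, row.ratio
            else:
                cur_end = max(cur_end, row.end)
                if row.p_value < cur_p:
                    cur_p, cur_ratio = row.p_value, row.ratio
        flush()
    sites.sort(key=lambda s: (s.chrom, s.start))
    return sites


def analyze_tss_regions(
    chip: CoverageTrack,
    input_: CoverageTrack,
    annotation: GenomeAnnotation,
    pad: int = 300,
) -> pd.DataFrame:
    """Enrichment of the padded region around every transcript's TSS.

    Each transcript contributes one row for its ``[TSS - pad, TSS + pad)``
    region (truncated and flagged at chromosome edges); no merging is done.
    """
    _check_tracks(chip, input_)
    scale = chip.total_mapped_reads / input_.total_mapped_reads
    rows = []
    for tx in annotation.transcripts:
        length = chip.chromosomes[tx.chrom]
        tss = derive_tss(tx)
        lo, hi = tss - pad, tss + pad
        truncated = lo < 0 or hi > length
        lo, hi = max(lo, 0), min(hi, length)
        c = chip.region_sum(tx.chrom, lo, hi)
        lam = max(input_.region_sum(tx.chrom, lo, hi) * scale, LAMBDA_FLOOR)
        rows.append(
            {
                "transcript_id": tx.id, "gene_id": tx.gene_id,
                "chrom": tx.chrom, "region_start": lo, "region_end": hi,
                "chip_count": c, "input_scaled": lam, "ratio": c / lam,
                "p_value": float(_poisson_upper_tail(np.array([c]), np.array([lam]))[0]),
                "truncated": truncated,
            }
        )
    return pd.DataFrame(rows)


def interval_enrichment(
    chip: CoverageTrack,
    input_: CoverageTrack,
    intervals: list[tuple[str, int, int]],
) -> pd.DataFrame:
    """Poisson enrichment test of arbitrary intervals (ChIP vs scaled input)."""
    _check_tracks(chip, input_)
    scale = chip.total_mapped_reads / input_.total_mapped_reads
    rows = []
    for chrom, start, end in intervals:
        c = chip.region_sum(chrom, start, end)
        lam = max(input_.region_sum(chrom, start, end) * scale, LAMBDA_FLOOR)
        rows.append(
            {
                "chrom": chrom, "start": start, "end": end,
                "chip_count": c, "input_scaled": lam, "ratio": c / lam,
                "p_value": float(_poisson_upper_tail(np.array([c]), np.array([lam]))[0]),
            }
        )
    return pd.DataFrame(rows)
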