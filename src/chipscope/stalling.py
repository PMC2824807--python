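"""RNA polymerase II promoter-proximal stalling.

The stalling index of a transcript is the ratio of mean differential Pol II
signal (factor minus input, both scaled to counts per million mapped reads)
over the promoter (TSS +/- 300 bp) to that over the transcript body (from
600 bp downstream of the TSS to the TES, in transcription orientation).
An index strictly greater than 4 classifies the transcript as *stalled*;
otherwise it is *uniform* or *absent* depending on whether the Pol II track
shows significant enrichment over the transcript at all.

The differential map is computed as factor minus input so that enrichment of
the factor is positive. Negative differential values are retained in the
means unless clamping is requested.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_io import (
    CoverageTrack,
    GenomeAnnotation,
    SignalMap,
    Transcript,
    derive_tss,
)
from .peaks import interval_enrichment

DEFAULT_PROMOTER_PAD = 300
DEFAULT_BODY_OFFSET = 600
DEFAULT_THRESHOLD = 4.0

STALLED = "stalled"
UNIFORM = "uniform"
ABSENT = "absent"


def differential_map(
    polii: CoverageTrack, input_: CoverageTrack, clamp_negative: bool = False
) -> SignalMap:
    """Per-base factor-minus-input signal, both in counts per million."""
    if polii.chromosomes != input_.chromosomes:
        raise ValueError(
            "factor and input tracks cover different chromosomes: "
            f"{polii.chromosomes} vs {input_.chromosomes}"
        )
    factor = polii.per_million()
    background = input_.per_million()
    data = {}
    for chrom in factor:
        diff = factor[chrom] - background[chrom]
        if clamp_negative:
            diff = np.maximum(diff, 0.0)
        data[chrom] = diff
    return SignalMap(data=data)


def _promoter_interval(tx: Transcript, pad: int) -> tuple[int, int]:
    tss = derive_tss(tx)
    return tss - pad, tss + pad


def _body_interval(tx: Transcript, offset: int) -> tuple[int, int]:
    """The transcript body in genome coordinates, oriented by strand."""
    tss = derive_tss(tx)
    if tx.strand == "+":
        return tss + offset, tx.end
    return tx.start, tss - offset + 1


def stalling_index(
    diff: SignalMap,
    transcript: Transcript,
    promoter_pad: int = DEFAULT_PROMOTER_PAD,
    body_offset: int = DEFAULT_BODY_OFFSET,
) -> dict:
    """Promoter mean, body mean, and index for one transcript.

    Guards: a transcript no longer than ``body_offset`` has no body and is
    flagged ``short`` with an undefined index. A non-positive body mean with
    a positive promoter mean yields an infinite index (stalled); when both
    means are non-positive the index is undefined (NaN).
    """
    chrom_len = diff.data[transcript.chrom].size
    p_lo, p_hi = _promoter_interval(transcript, promoter_pad)
    truncated = p_lo < 0 or p_hi > chrom_len
    promoter_mean = diff.region_mean(transcript.chrom, p_lo, p_hi)
    short = transcript.length <= body_offset
    if short:
        body_mean = float("nan")
        index = float("nan")
    else:
        b_lo, b_hi = _body_interval(transcript, body_offset)
        body_mean = diff.region_mean(transcript.chrom, b_lo, b_hi)
        if body_mean > 0:
            index = promoter_mean / body_mean
        elif promoter_mean > 0:
            index = float("inf")
        else:
            index = float("nan")
    return {
        "transcript_id": transcript.id,
        "gene_id": transcript.gene_id,
        "promoter_mean": promoter_mean,
        "body_mean": body_mean,
        "index": index,
        "short": short,
        "truncated": truncated,
    }


def stalling_table(
    diff: SignalMap,
    annotation: GenomeAnnotation,
    promoter_pad: int = DEFAULT_PROMOTER_PAD,
    body_offset: int = DEFAULT_BODY_OFFSET,
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            stalling_index(diff, tx, promoter_pad, body_offset)
            for tx in annotation.transcripts
        ]
    )


def transcript_enrichment(
    polii: CoverageTrack,
    input_: CoverageTrack,
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Poisson enrichment test of the Pol II track over each transcript span."""
    intervals = [(tx.chrom, tx.start, tx.end) for tx in annotation.transcripts]
    frame = interval_enrichment(polii, input_, intervals)
    frame.insert(0, "transcript_id", [tx.id for tx in annotation.transcripts])
    return frame


def classify_transcripts(
    calls: pd.DataFrame,
    enrichment: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    enrichment_p: float = 1e-5,
) -> pd.DataFrame:
    """Attach a stalled / uniform / absent class to each stalling call.

    Index strictly above ``threshold`` (with positive promoter signal) means
    stalled regardless of body enrichment; otherwise the transcript is
    uniform when its span is significantly enriched and absent when not.
    """
    enriched = dict(
        zip(enrichment["transcript_id"], enrichment["p_value"] < enrichment_p)
    )
    classes = []
    for row in calls.to_dict("records"):
        idx = row["index"]
        if (
            not row["short"]
            and not math.isnan(idx)
            and idx > threshold
            and row["promoter_mean"] > 0
        ):
            classes.append(STALLED)
        elif enriched.get(row["transcript_id"], False):
            classes.append(UNIFORM)
        else:
            classes.append(ABSENT)
    out = calls.copy()
    out["class"] = classes
    return out


def stalled_genes(classified: pd.DataFrame) -> set[str]:
    """Genes with at least one stalled transcript."""
    mask = classified["class"] == STALLED
    return set(classified.loc[mask, "gene_id"])


def stalling_by_target_overlap(
    classified: pd.DataFrame,
    target_genes: set[str],
    all_genes: set[str],
) -> dict:
    """How often stalled genes are binding targets, vs the genome-wide rate."""
    stalled = stalled_genes(classified)
    bound_stalled = stalled & target_genes
    report = {
        "n_stalled_genes": len(stalled),
        "n_stalled_bound": len(bound_stalled),
        "frac_stalled_bound": (
            len(bound_stalled) / len(stalled) if stalled else float("nan")
        ),
        "n_genes": len(all_genes),
        "n_bound": len(target_genes & all_genes),
        "frac_genome_bound": (
            len(target_genes & all_genes) / len(all_genes) if all_genes
            else float("nan")
        ),
    }
    return report
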