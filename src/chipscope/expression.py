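"""Expression quantification (DCPM) and gene-set statistics.

DCPM — depth of coverage per million mapped reads — is the mean per-base
RNA coverage over a transcript divided by (total mapped reads / 10^6). At
two stages, the transcript is labeled up-regulated at the stage with the
larger DCPM. "Expressed" defaults to any coverage (DCPM > 0); the threshold
is configurable because no principled universal cutoff exists.

Gene-set statistics: an upper-tail hypergeometric overlap test, and an
unweighted running-sum enrichment score (ES) over a ranked gene list that
increases by 1/Nh at set members and decreases by 1/(N - Nh) otherwise, with
an optional random-set permutation null and normalized ES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CoverageTrack, GenomeAnnotation, Transcript


def dcpm(rna: CoverageTrack, transcript: Transcript) -> float:
    """Average depth of coverage per million mapped reads over a transcript."""
    if transcript.length < 1:
        raise ValueError("zero-length transcript")
    mean_depth = rna.region_sum(
        transcript.chrom, transcript.start, transcript.end
    ) / transcript.length
    return mean_depth / (rna.total_mapped_reads / 1e6)


def expression_table(
    tracks: dict[str, CoverageTrack],
    annotation: GenomeAnnotation,
    expressed_min_dcpm: float = 0.0,
) -> pd.DataFrame:
    """Per-transcript DCPM at each stage, expressed flags, and up-stage.

    ``expressed`` means DCPM strictly above ``expressed_min_dcpm`` (default:
    any coverage). ``up_stage`` is the stage with the larger DCPM, or
    ``none`` on a tie — only defined for exactly two stages.
    """
    stages = sorted(tracks)
    rows = []
    for tx in annotation.transcripts:
        row: dict = {"transcript_id": tx.id, "gene_id": tx.gene_id}
        for stage in stages:
            value = dcpm(tracks[stage], tx)
            row[f"dcpm_{stage}"] = value
            row[f"expressed_{stage}"] = value > expressed_min_dcpm
        if len(stages) == 2:
            a, b = (row[f"dcpm_{s}"] for s in stages)
            row["up_stage"] = stages[0] if a > b else stages[1] if b > a else "none"
        rows.append(row)
    return pd.DataFrame(rows)


def _gene_level(expr: pd.DataFrame, column: str) -> pd.Series:
    """Gene value = maximum over isoforms."""
    return expr.groupby("gene_id")[column].max()


def expression_vs_binding(
    expr: pd.DataFrame,
    targets_by_stage: dict[str, set[str]],
) -> dict:
    """Fractions relating binding to expression across two stages.

    Reports the fraction of genes bound at either stage that are expressed
    (at either stage), and, among each stage's exclusive targets, the
    fraction whose expression is lower at the other stage — the signature of
    a factor that promotes expression of its targets.
    """
    stages = sorted(targets_by_stage)
    if len(stages) != 2:
        raise ValueError("expression_vs_binding needs exactly two stages")
    a, b = stages
    dcpm_a = _gene_level(expr, f"dcpm_{a}")
    dcpm_b = _gene_level(expr, f"dcpm_{b}")
    expressed = _gene_level(expr, f"expressed_{a}") | _gene_level(
        expr, f"expressed_{b}"
    )
    bound_either = (targets_by_stage[a] | targets_by_stage[b]) & set(expressed.index)
    n_bound = len(bound_either)
    n_bound_expressed = int(expressed.loc[sorted(bound_either)].sum())

    def _lower_elsewhere(own: set[str], other: set[str], own_d, other_d):
        exclusive = sorted((own - other) & set(own_d.index))
        if not exclusive:
            return 0, 0
        lower = int((other_d.loc[exclusive] < own_d.loc[exclusive]).sum())
        return lower, len(exclusive)

    lower_a, n_excl_a = _lower_elsewhere(
        targets_by_stage[a], targets_by_stage[b], dcpm_a, dcpm_b
    )
    lower_b, n_excl_b = _lower_elsewhere(
        targets_by_stage[b], targets_by_stage[a], dcpm_b, dcpm_a
    )
    return {
        "n_bound_either": n_bound,
        "n_bound_expressed": n_bound_expressed,
        "frac_bound_expressed": (
            n_bound_expressed / n_bound if n_bound else float("nan")
        ),
        f"n_exclusive_{a}": n_excl_a,
        f"frac_{a}_exclusive_lower_in_{b}": (
            lower_a / n_excl_a if n_excl_a else float("nan")
        ),
        f"n_exclusive_{b}": n_excl_b,
        f"frac_{b}_exclusive_lower_in_{a}": (
            lower_b / n_excl_b if n_excl_b else float("nan")
        ),
    }


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] when drawing n from a universe of N containing K positives.

    Computed with the hypergeometric survival function (log-space stable in
    SciPy), the standard test for gene-set overlap significance.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class RunningSumResult:
    es: float
    curve: np.ndarray
    permutation_p: float | None = None
    nes: float | None = None
    null_es: np.ndarray | None = field(default=None, repr=False)


def running_sum_es(
    ranked_genes: list[str],
    target_set: set[str],
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> RunningSumResult:
    """Unweighted running-sum enrichment score over a ranked gene list.

    Walking from the top of the ranking, the sum increases by ``1/Nh`` at
    each target-set member and decreases by ``1/(N - Nh)`` otherwise; it
    therefore ends at exactly 0. The ES is the signed maximum-magnitude
    deviation. With ``n_permutations > 0`` a null of random same-size gene
    sets gives a permutation p-value (fraction of |null ES| >= |ES|) and a
    normalized ES (ES over the mean |null ES|).
    """
    n = len(ranked_genes)
    if len(set(ranked_genes)) != n:
        raise ValueError("ranked list contains duplicates")
    targets = set(target_set)
    if not targets:
        raise ValueError("target set is empty")
    if not targets <= set(ranked_genes):
        raise ValueError("target set must be a subset of the ranked list")
    nh = len(targets)
    if nh == n:
        raise ValueError("target set equals the whole ranking")
    hit = np.fromiter((g in targets for g in ranked_genes), dtype=bool, count=n)
    curve = _running_curve(hit, nh, n)
    es = _extreme(curve)
    result = RunningSumResult(es=es, curve=curve)
    if n_permutations > 0:
        rng = rng or np.random.default_rng(0)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=nh, replace=False)] = True
            null[i] = _extreme(_running_curve(perm_hit, nh, n))
        result.null_es = null
        result.permutation_p = float(
            (np.abs(null) >= abs(es)).sum() + 1
        ) / (n_permutations + 1)
        mean_abs = float(np.abs(null).mean())
        result.nes = es / mean_abs if mean_abs > 0 else float("nan")
    return result


def _running_curve(hit: np.ndarray, nh: int, n: int) -> np.ndarray:
    steps = np.where(hit, 1.0 / nh, -1.0 / (n - nh))
    return np.cumsum(steps)


def _extreme(curve: np.ndarray) -> float:
    i = int(np.abs(curve).argmax())
    return float(curve[i])
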