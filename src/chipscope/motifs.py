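"""PWM scanning with exact score-distribution p-values and motif enrichment.

Log-odds scores are discretized to a fixed resolution (0.01 bits per unit by
default) and the *exact* distribution of the discretized score of a random
background w-mer is computed by positional convolution. A window is a match
when the upper-tail probability of its score is below the match p-value
cutoff. Scanning and the null distribution use the same discretized scores,
so the p-values are exact for the scores actually assigned; the only
approximation relative to continuous log-odds is the rounding to the score
grid.

Enrichment compares the fraction of bound sequences (central windows of the
top peaks) containing at least one match to the fraction among background
windows taken upstream of the peak centers, with a two-sided Fisher exact
test on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BASES, BindingSite, Pwm

#: Score discretization: one grid unit is this many bits.
SCORE_RESOLUTION = 0.01

DEFAULT_MATCH_P = 1e-4
DEFAULT_TOP = 200
DEFAULT_SITE_P = 0.05

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class ScoreDistribution:
    """Exact distribution of the discretized log-odds score of a random
    background w-mer."""

    min_score: int
    probs: np.ndarray  # probs[i] = P[S == min_score + i]
    resolution: float = SCORE_RESOLUTION

    def __post_init__(self) -> None:
        # tail[i] = P[S >= min_score + i]
        self._tail = np.concatenate(
            (np.cumsum(self.probs[::-1])[::-1], [0.0])
        )

    def pvalue(self, score: int) -> float:
        """P[S >= score] for an integer grid score."""
        i = score - self.min_score
        if i <= 0:
            return 1.0
        if i >= self.probs.size:
            return 0.0
        return float(self._tail[i])

    def pvalues(self, scores: np.ndarray) -> np.ndarray:
        i = np.clip(scores - self.min_score, 0, self.probs.size)
        return self._tail[i]

    def threshold(self, match_p: float) -> int:
        """Smallest grid score whose tail probability is < match_p, or one
        past the maximum if no score qualifies."""
        idx = np.searchsorted(-self._tail, -match_p, side="right")
        return self.min_score + int(idx)


def _int_log_odds(pwm: Pwm, resolution: float) -> np.ndarray:
    return np.round(pwm.log_odds() / resolution).astype(np.int64)


def pwm_score_distribution(
    pwm: Pwm, resolution: float = SCORE_RESOLUTION
) -> ScoreDistribution:
    """Exact discretized score distribution by positional convolution."""
    lo = _int_log_odds(pwm, resolution)
    min_total = int(lo.min(axis=0).sum())
    max_total = int(lo.max(axis=0).sum())
    probs = np.zeros(max_total - min_total + 1)
    probs[0] = 1.0
    offset = 0  # current distribution starts at min of processed columns
    cur_len = 1
    for j in range(pwm.width):
        col = lo[:, j]
        cmin = int(col.min())
        new_len = cur_len + int(col.max()) - cmin
        new = np.zeros(new_len)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift : shift + cur_len] += pwm.background[b] * probs[:cur_len]
        probs = np.zeros(max(new_len, probs.size))
        probs[:new_len] = new
        cur_len = new_len
        offset += cmin
    assert offset == min_total
    return ScoreDistribution(
        min_score=min_total, probs=probs[:cur_len], resolution=resolution
    )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.size, -1, dtype=np.int64)
    for i, base in enumerate(BASES):
        code[arr == ord(base)] = i
    return code


def _window_scores(code: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of every window, plus a validity mask (no N)."""
    w = lo.shape[1]
    n = code.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(code >= 0, code, 0)
    for j in range(w):
        col = code[j : j + n]
        valid &= col >= 0
        scores += lo[safe[j : j + n], j]
    return scores, valid


def _rc_pwm(pwm: Pwm) -> Pwm:
    matrix = pwm.matrix[::-1, ::-1]
    return Pwm(matrix=matrix.copy(), background=pwm.background.copy(),
               name=pwm.name + "_rc")


def scan_sequences(
    sequences: dict[str, str],
    pwm: Pwm,
    match_p: float = DEFAULT_MATCH_P,
    resolution: float = SCORE_RESOLUTION,
) -> pd.DataFrame:
    """Scan both strands of each sequence for PWM matches (p < match_p).

    Windows containing N are skipped. Positions are 0-based offsets of the
    window start on the forward strand.
    """
    fwd = pwm
    rev = _rc_pwm(pwm)
    rows = []
    dists = {}
    for strand, mat in (("+", fwd), ("-", rev)):
        dists[strand] = pwm_score_distribution(mat, resolution)
    for name in sorted(sequences):
        code = _encode(sequences[name])
        for strand, mat in (("+", fwd), ("-", rev)):
            lo = _int_log_odds(mat, resolution)
            dist = dists[strand]
            threshold = dist.threshold(match_p)
            scores, valid = _window_scores(code, lo)
            hits = np.flatnonzero(valid & (scores >= threshold))
            for pos in hits:
                s = int(scores[pos])
                rows.append(
                    {
                        "sequence_id": name, "position": int(pos),
                        "strand": strand, "score_bits": s * resolution,
                        "p_value": dist.pvalue(s),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sequence_id", "position", "strand", "score_bits", "p_value"]
    )


def sequences_with_match(
    sequences: dict[str, str], pwm: Pwm, match_p: float = DEFAULT_MATCH_P
) -> set[str]:
    matches = scan_sequences(sequences, pwm, match_p)
    return set(matches["sequence_id"])


# ---------------------------------------------------------------------------
# peak sequence selection and enrichment
# ---------------------------------------------------------------------------


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice a chromosome from a dict of strings or a pyfaidx.Fasta."""
    if isinstance(genome, dict):
        return genome[chrom][start:end]
    return str(genome[chrom][start:end])


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def _sorted_sites(sites: list[BindingSite], mode: str) -> list[BindingSite]:
    if mode == "pvalue":
        return sorted(sites, key=lambda s: (s.p_value, s.chrom, s.start))
    if mode == "signal_ratio":
        return sorted(sites, key=lambda s: (-s.signal, s.chrom, s.start))
    raise ValueError("mode must be 'pvalue' or 'signal_ratio'")


def _central_window(site: BindingSite, width: int, chrom_len: int) -> tuple[int, int]:
    mid = site.midpoint
    lo = max(mid - width // 2, 0)
    hi = min(lo + width, chrom_len)
    return lo, hi


def select_peak_sequences(
    sites: list[BindingSite],
    genome,
    mode: str = "pvalue",
    top: int = DEFAULT_TOP,
    window: int | None = None,
) -> dict[str, str]:
    """Central sequences of the top-ranked peaks.

    ``mode='pvalue'`` ranks by ascending p-value and extracts central 200 bp
    windows; ``mode='signal_ratio'`` ranks by descending input-normalized
    signal and uses a more stringent 100 bp window. Ties break by
    coordinate, so output is deterministic. With fewer sites than ``top``
    all are taken.
    """
    if window is None:
        window = 200 if mode == "pvalue" else 100
    chosen = _sorted_sites(sites, mode)[:top]
    out = {}
    for site in chosen:
        lo, hi = _central_window(site, window, _chrom_length(genome, site.chrom))
        out[f"{site.chrom}:{lo}-{hi}"] = _fetch(genome, site.chrom, lo, hi)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    n_bound_with_match: int
    n_bound_total: int
    n_background_with_match: int
    n_background_total: int
    n_background_dropped: int
    enrichment: float
    fisher_p: float


def motif_enrichment(
    sites: list[BindingSite],
    genome,
    pwm: Pwm,
    match_p: float = DEFAULT_MATCH_P,
    site_p_cutoff: float = DEFAULT_SITE_P,
    top: int = DEFAULT_TOP,
    window: int = 1000,
    background_offset: int = 1000,
) -> EnrichmentResult:
    """Motif enrichment of bound regions over upstream background regions.

    Bound set: central ``window`` bp of the ``top`` sites ranked by p-value.
    Background set: ``window`` bp starting ``background_offset`` bp upstream
    of the center, for every site with p-value below ``site_p_cutoff``;
    background windows extending past a chromosome edge are dropped and
    counted. A sequence matches when it contains at least one PWM match at
    ``match_p``. The enrichment ratio is the bound match fraction over the
    background match fraction (infinite when no background window matches),
    with a two-sided Fisher exact test on the counts.
    """
    bound = select_peak_sequences(sites, genome, mode="pvalue", top=top,
                                  window=window)
    background = {}
    dropped = 0
    for site in sites:
        if site.p_value >= site_p_cutoff:
            continue
        chrom_len = _chrom_length(genome, site.chrom)
        center_lo, _ = _central_window(site, window, chrom_len)
        lo = center_lo - background_offset
        hi = lo + window
        if lo < 0 or hi > chrom_len:
            dropped += 1
            continue
        background[f"{site.chrom}:{lo}-{hi}"] = _fetch(genome, site.chrom, lo, hi)
    n_bound = len(bound)
    n_bg = len(background)
    k_bound = len(sequences_with_match(bound, pwm, match_p))
    k_bg = len(sequences_with_match(background, pwm, match_p))
    frac_bound = k_bound / n_bound if n_bound else float("nan")
    if n_bg and k_bg:
        enrichment = frac_bound / (k_bg / n_bg)
    elif n_bg:
        enrichment = float("inf") if k_bound else float("nan")
    else:
        enrichment = float("nan")
    table = [[k_bound, n_bound - k_bound], [k_bg, n_bg - k_bg]]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return EnrichmentResult(
        n_bound_with_match=k_bound,
        n_bound_total=n_bound,
        n_background_with_match=k_bg,
        n_background_total=n_bg,
        n_background_dropped=dropped,
        enrichment=enrichment,
        fisher_p=fisher_p,
    )
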