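"""Synthetic genomes, coverage tracks, and sequences with known ground truth.

The generator emulates the data model the downstream statistics consume: a
compact, gene-dense genome with multi-isoform genes on both strands, Poisson
per-base background coverage in ChIP and input tracks, rectangular enriched
sites of controlled fold and width, Pol II tracks with a controlled
promoter-to-body ratio, RNA coverage driven by per-transcript expression
levels, and planted motif occurrences on an i.i.d. base-composition
background. Coverage is simulated directly as per-base Poisson counts rather
than as reads followed by pileup, because every downstream statistic here
consumes coverage, not read alignments.

All generators are deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    BASES,
    CoverageTrack,
    GenomeAnnotation,
    Pwm,
    Transcript,
)


def default_motif_pwm() -> Pwm:
    """A sharp 12-bp motif used as the default planted motif.

    Each column puts probability 0.99 on the consensus base, so sampled
    occurrences carry at most one mismatch almost surely and remain
    detectable under a stringent match cutoff.
    """
    consensus = "TGTTTGCATCGC"
    matrix = np.full((4, len(consensus)), 0.01 / 3)
    for j, base in enumerate(consensus):
        matrix[BASES.index(base), j] = 0.99
    return Pwm(matrix=matrix, name="planted")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a 1 Mb gene-dense chromosome with 50 planted binding
    sites of fold 10 over a background of 2 counts/base — a compact stand-in
    for a deeply sequenced ChIP experiment on a small genome.
    """

    seed: int = 0
    # genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 1_000_000}
    )
    n_genes: int = 200
    mean_gene_length: int = 2000
    min_gene_length: int = 800
    max_gene_length: int = 6000
    mean_spacing: int = 1000
    min_spacing: int = 400
    isoform_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) isoforms
    # ChIP experiment
    background_depth: float = 2.0
    n_sites: int = 50
    site_width: int = 400
    site_fold: float = 10.0
    library_size: int | None = None  # None: realized coverage sum
    # Pol II
    stalled_fraction: float = 0.1
    absent_fraction: float = 0.2
    promoter_body_fold: float = 10.0
    body_depth: float = 5.0
    promoter_pad: int = 300
    # RNA expression
    expression_mean_log: float = 1.0
    expression_sigma_log: float = 1.0
    unexpressed_fraction: float = 0.2
    # motif planting
    pwm: Pwm = field(default_factory=default_motif_pwm)
    base_composition: tuple[float, ...] = (0.32, 0.18, 0.18, 0.32)
    motif_rate_bound: float = 0.6
    motif_rate_background: float = 0.2
    background_offset: int = 1000  # background window starts this far 5' of center
    # stage pairs
    shared_fraction: float = 0.55

    def __post_init__(self) -> None:
        for name in ("stalled_fraction", "absent_fraction", "shared_fraction",
                     "motif_rate_bound", "motif_rate_background",
                     "unexpressed_fraction"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.site_fold < 1:
            raise ValueError("site_fold must be >= 1")
        if self.background_depth <= 0:
            raise ValueError("background_depth must be positive")

def _stage_rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery downstream."""

    sites: list[dict] = field(default_factory=list)  # chrom,start,end,fold,gene_id
    stalled_transcripts: list[str] = field(default_factory=list)
    transcript_classes: dict[str, str] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    motif_occurrences: list[dict] = field(default_factory=list)  # chrom,pos,kind


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place stranded, non-overlapping genes with 1-3 isoforms.

    Intergenic spacing is exponential (shifted by ``min_spacing``), so with
    the default 1 kb mean a substantial share of neighbors sit closer than
    2 kb and random strands produce divergent promoter pairs — the layouts
    that exercise multi-gene assignment bins.
    """
    rng = _stage_rng(config, 1)
    chroms = sorted(config.chrom_lengths)
    needed = config.n_genes * (config.mean_gene_length + config.mean_spacing)
    available = sum(config.chrom_lengths.values())
    if needed > available:
        raise ValueError(
            f"cannot pack {config.n_genes} genes of mean length "
            f"{config.mean_gene_length} at mean spacing {config.mean_spacing} "
            f"into {available} bases; use a longer chromosome"
        )
    per_chrom = {
        c: int(round(config.n_genes * config.chrom_lengths[c] / available))
        for c in chroms
    }
    # rounding drift goes to the first chromosome
    per_chrom[chroms[0]] += config.n_genes - sum(per_chrom.values())

    transcripts: list[Transcript] = []
    gene_no = 0
    for chrom in chroms:
        length = config.chrom_lengths[chrom]
        extra = max(config.mean_spacing - config.min_spacing, 0.0)
        pos = config.min_spacing + int(rng.exponential(extra))
        placed = 0
        while placed < per_chrom[chrom]:
            glen = int(
                np.clip(
                    rng.gamma(2.0, config.mean_gene_length / 2.0),
                    config.min_gene_length,
                    config.max_gene_length,
                )
            )
            if pos + glen + 1 >= length:
                break
            gene_no += 1
            placed += 1
            gene_id = f"gene{gene_no:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_iso = int(rng.choice([1, 2, 3], p=config.isoform_probs))
            # isoform trimming never shortens below 700 bases, so every
            # isoform is long enough to carry a stalling index (body > 600)
            budget = max(glen - 700, 0)
            for k in range(n_iso):
                trim5 = 0 if k == 0 else int(rng.integers(0, min(200, budget // 2) + 1))
                trim3 = 0 if k == 0 else int(rng.integers(0, min(400, budget // 2) + 1))
                s, e = pos + trim5, pos + glen - trim3
                if strand == "+":
                    tss, tes = s, e - 1
                else:
                    tss, tes = e - 1, s
                transcripts.append(
                    Transcript(
                        id=f"{gene_id}.{k + 1}", gene_id=gene_id, chrom=chrom,
                        strand=strand, tss=tss, tes=tes,
                    )
                )
            pos += glen + config.min_spacing + int(rng.exponential(extra))
        if placed < per_chrom[chrom]:
            raise ValueError(
                f"could not place {per_chrom[chrom]} genes on {chrom} "
                f"(length {length}); use a longer chromosome"
            )
    return GenomeAnnotation(
        chromosomes=dict(config.chrom_lengths), transcripts=transcripts
    )


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------


def _poisson_track(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    lam: float,
    sites: list[dict],
    fold_extra: bool,
    label: str,
    library_size: int | None,
) -> CoverageTrack:
    data = {}
    for chrom, length in sorted(chrom_lengths.items()):
        lam_arr = np.full(length, lam)
        if fold_extra:
            for site in sites:
                if site["chrom"] == chrom:
                    lam_arr[site["start"] : site["end"]] = lam * site["fold"]
        data[chrom] = rng.poisson(lam_arr).astype(np.int64)
    total = library_size
    if total is None:
        total = int(sum(a.sum() for a in data.values()))
    return CoverageTrack(data=data, total_mapped_reads=total, label=label)


def _choose_site_genes(
    annotation: GenomeAnnotation, config: SimulationConfig,
    rng: np.random.Generator, n_sites: int, exclude: set[str] = frozenset(),
) -> list[dict]:
    """Plant one site per chosen gene, near its promoter.

    The site midpoint sits between 800 bases upstream and 300 bases into the
    gene (5' oriented), so by construction the planted gene is an internal or
    <2 kb-downstream target of the site.
    """
    candidates = [g for g in annotation.gene_ids if g not in exclude]
    if n_sites > len(candidates):
        raise ValueError("more sites requested than available genes")
    chosen = sorted(rng.choice(candidates, size=n_sites, replace=False))
    sites = []
    for gene_id in chosen:
        tx = annotation.transcript(annotation.gene_index[gene_id][0])
        from .core_io import derive_tss

        tss = derive_tss(tx)
        offset = int(rng.integers(-800, 301))
        mid = tss + offset if tx.strand == "+" else tss - offset
        half = config.site_width // 2
        start = max(mid - half, 0)
        end = min(start + config.site_width, annotation.chromosomes[tx.chrom])
        sites.append(
            {
                "chrom": tx.chrom, "start": int(start), "end": int(end),
                "fold": config.site_fold, "gene_id": gene_id,
            }
        )
    sites.sort(key=lambda s: (s["chrom"], s["start"]))
    return sites


def simulate_chip_experiment(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    sites: list[dict] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CoverageTrack, CoverageTrack, GroundTruth]:
    """ChIP and input tracks with rectangular planted enrichment.

    Input is Poisson(background_depth) everywhere; ChIP is
    Poisson(background_depth * fold) inside each planted site and background
    elsewhere.
    """
    rng = rng or _stage_rng(config, 2)
    if sites is None:
        sites = _choose_site_genes(annotation, config, rng, config.n_sites)
    for site in sites:
        if site["end"] > annotation.chromosomes[site["chrom"]]:
            raise ValueError(f"planted site beyond chromosome end: {site}")
    chip = _poisson_track(
        rng, annotation.chromosomes, config.background_depth, sites,
        fold_extra=True, label="chip", library_size=config.library_size,
    )
    inp = _poisson_track(
        rng, annotation.chromosomes, config.background_depth, sites,
        fold_extra=False, label="input", library_size=config.library_size,
    )
    truth = GroundTruth(sites=[dict(s) for s in sites])
    return chip, inp, truth


def simulate_stage_pair(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[
    tuple[CoverageTrack, CoverageTrack, GroundTruth],
    tuple[CoverageTrack, CoverageTrack, GroundTruth],
]:
    """Two ChIP experiments sharing a configured fraction of true sites.

    ``round(shared_fraction * n_sites)`` sites are placed identically in
    both stages; the remainder of each stage's ``n_sites`` are
    stage-exclusive, at distinct genes.
    """
    rng = _stage_rng(config, 3)
    n_shared = int(round(config.shared_fraction * config.n_sites))
    n_excl = config.n_sites - n_shared
    shared = _choose_site_genes(annotation, config, rng, n_shared)
    used = {s["gene_id"] for s in shared}
    excl_a = _choose_site_genes(annotation, config, rng, n_excl, exclude=used)
    used |= {s["gene_id"] for s in excl_a}
    excl_b = _choose_site_genes(annotation, config, rng, n_excl, exclude=used)
    sites_a = sorted(shared + excl_a, key=lambda s: (s["chrom"], s["start"]))
    sites_b = sorted(shared + excl_b, key=lambda s: (s["chrom"], s["start"]))
    stage_a = simulate_chip_experiment(annotation, config, sites=sites_a, rng=rng)
    stage_b = simulate_chip_experiment(annotation, config, sites=sites_b, rng=rng)
    return stage_a, stage_b


# ---------------------------------------------------------------------------
# Pol II tracks
# ---------------------------------------------------------------------------


def simulate_polii(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[CoverageTrack, CoverageTrack, GroundTruth]:
    """Pol II and input tracks with stalled / uniform / absent transcripts.

    A transcript is absent with probability ``absent_fraction``; among the
    expressed, stalled with probability ``stalled_fraction``. Uniform
    transcripts add ``body_depth`` over their whole span; stalled transcripts
    add ``promoter_body_fold * body_depth`` over TSS +/- promoter_pad and
    ``body_depth`` over the rest. Background depth is added everywhere and
    matches the input track's rate, so it cancels in the differential map.
    """
    from .core_io import derive_tss

    rng = _stage_rng(config, 4)
    lam_extra = {c: np.zeros(n) for c, n in annotation.chromosomes.items()}
    truth = GroundTruth()
    # class is drawn per gene and signal added once per locus, so isoforms of
    # one gene share a label and do not contaminate each other's truth
    for gene_id in annotation.gene_ids:
        txs = [annotation.transcript(i) for i in annotation.gene_index[gene_id]]
        if rng.random() < config.absent_fraction:
            gene_class = "absent"
        elif rng.random() < config.stalled_fraction:
            gene_class = "stalled"
        else:
            gene_class = "uniform"
        for tx in txs:
            truth.transcript_classes[tx.id] = gene_class
            if gene_class == "stalled":
                truth.stalled_transcripts.append(tx.id)
        if gene_class == "absent":
            continue
        primary = txs[0]
        lam = lam_extra[primary.chrom]
        lam[primary.start : primary.end] += config.body_depth
        if gene_class == "stalled":
            tss = derive_tss(primary)
            lo = max(tss - config.promoter_pad, 0)
            hi = min(tss + config.promoter_pad, len(lam))
            lam[lo:hi] += (config.promoter_body_fold - 1) * config.body_depth
    polii_data = {
        c: rng.poisson(lam_extra[c] + config.background_depth).astype(np.int64)
        for c in sorted(annotation.chromosomes)
    }
    input_data = {
        c: rng.poisson(
            np.full(annotation.chromosomes[c], config.background_depth)
        ).astype(np.int64)
        for c in sorted(annotation.chromosomes)
    }
    total_p = config.library_size or int(sum(a.sum() for a in polii_data.values()))
    total_i = config.library_size or int(sum(a.sum() for a in input_data.values()))
    polii = CoverageTrack(polii_data, total_mapped_reads=total_p, label="polii")
    inp = CoverageTrack(input_data, total_mapped_reads=total_i, label="input")
    return polii, inp, truth


# ---------------------------------------------------------------------------
# RNA coverage
# ---------------------------------------------------------------------------


def simulate_rna(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    levels: dict[str, float] | None = None,
    stream: int = 5,
) -> tuple[CoverageTrack, GroundTruth]:
    """RNA coverage: each transcript adds Poisson depth at its expression
    level (lognormal by default, zero for an ``unexpressed_fraction``)."""
    rng = _stage_rng(config, stream)
    if levels is None:
        levels = {}
        for tx in annotation.transcripts:
            if rng.random() < config.unexpressed_fraction:
                levels[tx.id] = 0.0
            else:
                levels[tx.id] = float(
                    rng.lognormal(config.expression_mean_log,
                                  config.expression_sigma_log)
                )
    lam = {c: np.zeros(n) for c, n in annotation.chromosomes.items()}
    for tx in annotation.transcripts:
        lam[tx.chrom][tx.start : tx.end] += levels[tx.id]
    data = {c: rng.poisson(lam[c]).astype(np.int64) for c in sorted(lam)}
    total = config.library_size or max(int(sum(a.sum() for a in data.values())), 1)
    truth = GroundTruth(expression=dict(levels))
    return CoverageTrack(data, total_mapped_reads=total, label="rna"), truth


# ---------------------------------------------------------------------------
# sequences and motifs
# ---------------------------------------------------------------------------


def _sample_motif(rng: np.random.Generator, pwm: Pwm) -> str:
    cols = [rng.choice(4, p=pwm.matrix[:, j]) for j in range(pwm.width)]
    return "".join(BASES[i] for i in cols)


def simulate_sequences(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    site_intervals: list[dict] | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Genome sequence with motif occurrences planted at site centers.

    The background is i.i.d. bases at ``base_composition``. For each
    designated site, a PWM-sampled occurrence is planted at the site center
    with probability ``motif_rate_bound``, and independently at
    ``background_offset`` bases 5' of the center with probability
    ``motif_rate_background`` (emulating motif content in the flanking
    background windows used for enrichment testing).
    """
    rng = _stage_rng(config, 6)
    comp = np.asarray(config.base_composition, dtype=float)
    comp = comp / comp.sum()
    sequences = {}
    for chrom in sorted(annotation.chromosomes):
        n = annotation.chromosomes[chrom]
        idx = rng.choice(4, size=n, p=comp)
        sequences[chrom] = np.array(list(BASES))[idx]
    truth = GroundTruth()
    for site in site_intervals or []:
        chrom = site["chrom"]
        center = (site["start"] + site["end"]) // 2
        for kind, rate, pos in (
            ("bound", config.motif_rate_bound, center),
            ("background", config.motif_rate_background,
             center - config.background_offset),
        ):
            if rng.random() >= rate:
                continue
            occ = _sample_motif(rng, config.pwm)
            start = pos - config.pwm.width // 2
            if start < 0 or start + config.pwm.width > len(sequences[chrom]):
                continue
            sequences[chrom][start : start + config.pwm.width] = list(occ)
            truth.motif_occurrences.append(
                {"chrom": chrom, "pos": int(start), "kind": kind, "seq": occ}
            )
    return {c: "".join(a) for c, a in sequences.items()}, truth


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
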