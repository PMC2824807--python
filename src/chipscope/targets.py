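"""Assignment of binding sites to candidate target genes.

The algorithm is midpoint-based throughout. For each site, every transcript
within a search radius (default 5 kb) of the site midpoint is classified by
one of three relations: the midpoint lies *within* the transcript span, the
gene lies *downstream of the site* (the midpoint is 5'-ward of the TSS), or
the gene lies *upstream of the site* (the midpoint is 3'-ward of the TES).
Isoforms are grouped into genes, each gene taking its closest isoform's
relation. Genes are then placed into four bins:

1. internal, or downstream of the site at < 2 kb;
2. downstream of the site at 2-5 kb;
3. upstream of the site at < 2 kb;
4. upstream of the site at 2-5 kb;

and the site targets *all* genes in the first non-empty bin. "Less than
2 kb" is strict (< 2000) and "within 2-5 kb" is [2000, 5000]; a midpoint
exactly at the TSS or TES counts as internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import BindingSite, GenomeAnnotation, Transcript, derive_tss

INTERNAL = "internal"
GENE_DOWNSTREAM = "gene_downstream_of_site"
GENE_UPSTREAM = "gene_upstream_of_site"

#: Ranking of relations when isoforms tie on distance, and for ordering the
#: candidate list: an internal gene is the most likely target, a gene
#: downstream of the site the next, a gene upstream the least.
_RELATION_RANK = {INTERNAL: 0, GENE_DOWNSTREAM: 1, GENE_UPSTREAM: 2}

DEFAULT_SEARCH = 5000
DEFAULT_NEAR = 2000


@dataclass(frozen=True)
class SiteGeneRelation:
    gene_id: str
    relation: str
    distance: int
    bin: int | None


@dataclass
class TargetAssignment:
    site: BindingSite
    targets: list[SiteGeneRelation]
    all_candidates: list[SiteGeneRelation]


def site_transcript_relation(
    midpoint: int, transcript: Transcript
) -> tuple[str, int]:
    """Relation and distance between a site midpoint and one transcript.

    Distance is 0 for an internal midpoint, midpoint-to-TSS when the gene is
    downstream of the site, and midpoint-to-TES when the gene is upstream.
    """
    if transcript.start <= midpoint < transcript.end:
        return INTERNAL, 0
    tss = derive_tss(transcript)
    tes = transcript.tes
    if transcript.strand == "+":
        if midpoint < tss:
            return GENE_DOWNSTREAM, tss - midpoint
        return GENE_UPSTREAM, midpoint - tes
    if midpoint > tss:
        return GENE_DOWNSTREAM, midpoint - tss
    return GENE_UPSTREAM, tes - midpoint


def _bin_for(relation: str, distance: int, near: int, search: int) -> int | None:
    if relation == INTERNAL:
        return 1
    if distance > search:
        return None
    if relation == GENE_DOWNSTREAM:
        return 1 if distance < near else 2
    return 3 if distance < near else 4


def assign_targets(
    site: BindingSite,
    annotation: GenomeAnnotation,
    search: int = DEFAULT_SEARCH,
    near: int = DEFAULT_NEAR,
) -> TargetAssignment:
    """Assign a binding site to the genes of its first non-empty bin."""
    midpoint = site.midpoint
    best: dict[str, tuple[int, int, str]] = {}  # gene -> (distance, rank, relation)
    for tx in annotation.transcripts_on(site.chrom):
        relation, distance = site_transcript_relation(midpoint, tx)
        if distance > search:
            continue
        key = (distance, _RELATION_RANK[relation])
        if tx.gene_id not in best or key < best[tx.gene_id][:2]:
            best[tx.gene_id] = (distance, _RELATION_RANK[relation], relation)
    candidates = [
        SiteGeneRelation(
            gene_id=g, relation=rel, distance=dist,
            bin=_bin_for(rel, dist, near, search),
        )
        for g, (dist, _rank, rel) in best.items()
    ]
    candidates.sort(
        key=lambda r: (_RELATION_RANK[r.relation], r.distance, r.gene_id)
    )
    bins_present = [r.bin for r in candidates if r.bin is not None]
    targets: list[SiteGeneRelation] = []
    if bins_present:
        first = min(bins_present)
        targets = [r for r in candidates if r.bin == first]
    return TargetAssignment(site=site, targets=targets, all_candidates=candidates)


def assign_all(
    sites: list[BindingSite],
    annotation: GenomeAnnotation,
    search: int = DEFAULT_SEARCH,
    near: int = DEFAULT_NEAR,
) -> list[TargetAssignment]:
    return [assign_targets(s, annotation, search=search, near=near) for s in sites]


def filter_targets_go_rule(
    assignments: list[TargetAssignment], near: int = DEFAULT_NEAR
) -> set[str]:
    """Genes with a site within the gene or < 2 kb 5' of it.

    This stricter rule (internal, or gene downstream of the site at < 2 kb —
    i.e. bin 1) yields the deduplicated gene set used for set-enrichment
    analyses.
    """
    kept: set[str] = set()
    for assignment in assignments:
        for rel in assignment.targets:
            if rel.relation == INTERNAL or (
                rel.relation == GENE_DOWNSTREAM and rel.distance < near
            ):
                kept.add(rel.gene_id)
    return kept


def target_gene_set(assignments: list[TargetAssignment]) -> set[str]:
    """All distinct target genes over a list of assignments."""
    return {r.gene_id for a in assignments for r in a.targets}


def target_gene_census(assignments: list[TargetAssignment]) -> dict:
    """Summary counts: assigned/unassigned sites, distinct target genes, and
    the site-to-gene distance distribution."""
    n_assigned = sum(1 for a in assignments if a.targets)
    distances = [r.distance for a in assignments for r in a.targets]
    return {
        "n_sites": len(assignments),
        "n_assigned": n_assigned,
        "n_unassigned": len(assignments) - n_assigned,
        "frac_assigned": n_assigned / len(assignments) if assignments else 0.0,
        "n_target_genes": len(target_gene_set(assignments)),
        "distances": distances,
    }


def assignments_to_frame(assignments: list[TargetAssignment]) -> pd.DataFrame:
    """Long-form table: one row per (site, candidate gene)."""
    rows = []
    for i, a in enumerate(assignments):
        target_ids = {r.gene_id for r in a.targets}
        for rel in a.all_candidates:
            rows.append(
                {
                    "site_index": i, "chrom": a.site.chrom,
                    "site_start": a.site.start, "site_end": a.site.end,
                    "gene_id": rel.gene_id, "relation": rel.relation,
                    "distance": rel.distance, "bin": rel.bin,
                    "is_target": rel.gene_id in target_ids,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site_index", "chrom", "site_start", "site_end", "gene_id",
            "relation", "distance", "bin", "is_target",
        ],
    )
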