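"""Independent brute-force oracles, deliberately written from first
principles rather than sharing code with the package."""

from __future__ import annotations


def brute_force_relation(midpoint, tss, tes, strand):
    """Relation and distance of a midpoint to one transcript, recomputed
    directly from the stranded base coordinates."""
    lo, hi = min(tss, tes), max(tss, tes)
    if lo <= midpoint <= hi:
        return "internal", 0
    if strand == "+":
        on_five_prime_side = midpoint < lo
    else:
        on_five_prime_side = midpoint > hi
    if on_five_prime_side:
        return "gene_downstream_of_site", abs(tss - midpoint)
    return "gene_upstream_of_site", abs(midpoint - tes)


_RANK = {"internal": 0, "gene_downstream_of_site": 1, "gene_upstream_of_site": 2}


def brute_force_targets(midpoint, transcripts, search=5000, near=2000):
    """First-non-empty-bin target genes by exhaustive enumeration.

    ``transcripts`` is an iterable of (gene_id, tss, tes, strand) tuples on
    the site's chromosome. Returns (target gene set, {gene: bin}).
    """
    per_gene = {}
    for gene_id, tss, tes, strand in transcripts:
        rel, dist = brute_force_relation(midpoint, tss, tes, strand)
        if dist > search:
            continue
        key = (dist, _RANK[rel])
        if gene_id not in per_gene or key < per_gene[gene_id][0]:
            per_gene[gene_id] = (key, rel, dist)
    bins = {}
    for gene_id, (_key, rel, dist) in per_gene.items():
        if rel == "internal":
            bins[gene_id] = 1
        elif rel == "gene_downstream_of_site":
            bins[gene_id] = 1 if dist < near else 2
        else:
            bins[gene_id] = 3 if dist < near else 4
    if not bins:
        return set(), {}
    first = min(bins.values())
    return {g for g, b in bins.items() if b == first}, bins


def brute_force_go_filter(midpoint, transcripts, search=5000, near=2000):
    """Genes targeted with an internal site or a site < near bp 5' of them."""
    targets, _bins = brute_force_targets(midpoint, transcripts, search, near)
    per_gene = {}
    for gene_id, tss, tes, strand in transcripts:
        rel, dist = brute_force_relation(midpoint, tss, tes, strand)
        key = (dist, _RANK[rel])
        if gene_id not in per_gene or key < per_gene[gene_id][0]:
            per_gene[gene_id] = (key, rel, dist)
    kept = set()
    for gene_id in targets:
        _key, rel, dist = per_gene[gene_id]
        if rel == "internal" or (rel == "gene_downstream_of_site" and dist < near):
            kept.add(gene_id)
    return kept
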