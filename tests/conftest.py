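import numpy as np
import pytest

from chipscope import CoverageTrack, GenomeAnnotation, Transcript


def make_transcript(
    tx_id="t1", gene_id=None, chrom="chrI", strand="+", tss=1000, tes=2999,
    atg=None,
):
    return Transcript(
        id=tx_id, gene_id=gene_id or tx_id.split(".")[0], chrom=chrom,
        strand=strand, tss=tss, tes=tes, atg=atg,
    )


def make_annotation(transcripts, chrom_lengths=None):
    if chrom_lengths is None:
        chrom_lengths = {}
        for t in transcripts:
            chrom_lengths[t.chrom] = max(chrom_lengths.get(t.chrom, 0), t.end + 10000)
    return GenomeAnnotation(chromosomes=chrom_lengths, transcripts=transcripts)


def uniform_track(value, length=20000, total=1_000_000, chrom="chrI", label=""):
    return CoverageTrack(
        data={chrom: np.full(length, float(value))},
        total_mapped_reads=total,
        label=label,
    )


@pytest.fixture
def toy_annotation():
    """Six genes on a 40 kb chromosome, both strands, one gene with 2 isoforms."""
    txs = [
        make_transcript("g1.1", "g1", tss=2000, tes=4999),
        make_transcript("g1.2", "g1", tss=2100, tes=4799),
        make_transcript("g2.1", "g2", strand="-", tss=8999, tes=6500),
        make_transcript("g3.1", "g3", tss=12000, tes=13999),
        make_transcript("g4.1", "g4", strand="-", tss=19999, tes=17000),
        make_transcript("g5.1", "g5", tss=26000, tes=29999),
        make_transcript("g6.1", "g6", strand="-", tss=38999, tes=35000),
    ]
    return make_annotation(txs, {"chrI": 40000})


def random_annotation(rng, n_genes=8, chrom_len=60000, chrom="chrI"):
    """A random (possibly dense) annotation for oracle comparisons."""
    txs = []
    for g in range(n_genes):
        gene_id = f"g{g}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(1, 4))
        base = int(rng.integers(0, chrom_len - 8000))
        for k in range(n_iso):
            start = base + int(rng.integers(0, 500))
            length = int(rng.integers(500, 6000))
            end = min(start + length, chrom_len - 1)
            if strand == "+":
                tss, tes = start, end - 1
            else:
                tss, tes = end - 1, start
            txs.append(
                Transcript(
                    id=f"{gene_id}.{k}", gene_id=gene_id, chrom=chrom,
                    strand=strand, tss=tss, tes=tes,
                )
            )
    return make_annotation(txs, {chrom: chrom_len})
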