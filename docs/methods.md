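# Methods

This note records the statistical procedures chipscope implements, the
defaults it ships, the choices made where the design was genuinely open, and
what the synthetic-data studies do and do not demonstrate.

## Coordinates and the TSS rule

Internal coordinates are 0-based half-open everywhere; GFF3 I/O converts
from that format's 1-based inclusive convention, BED and bedGraph are
native. A transcript is stored as stranded TSS/TES base coordinates; its
span is the closed TSS–TES interval. When a transcript has no annotated
TSS, the start site is placed 150 bp 5′-ward of the ATG — the convention
used for compact nematode-style annotations where most but not all start
sites are mapped. Peak midpoints are `floor((start+end)/2)`, making
midpoint-based rules deterministic.

## Window peak scorer

The scorer is intentionally transparent rather than a re-implementation of
any published peak caller's internals: per 200 bp window (step 50 bp,
both configurable) the ChIP sum `k` is tested against a Poisson rate
`λ = (input local mean) × (ChIP total / input total)`, p = P[X ≥ k | λ].
Two numerical choices matter:

- **Local background estimation** (`input_smooth`, default 10 windows). A
  1:1 input window makes λ exactly as noisy as the signal, and the realized
  false-positive rate at a nominal cutoff roughly doubles per unit of extra
  sampling variance (measured ≈4.5× at α = 0.01 on null simulations).
  Estimating λ from a 10-window input span — the local-background idea used
  by standard callers — restores type-I control (measured 0.9α mean, 1.7α
  max over 10 null seeds). `input_smooth=1` recovers the literal per-window
  comparison.
- **λ floor** of 0.5 per window prevents p = 0 artifacts over zero-input
  regions; the Poisson survival probability is additionally floored at
  1e-300 because extreme enrichment underflows double precision.

Windows with p below the cutoff (default 1e-5 for site definition, 1e-3 for
concordance analyses) that overlap or abut merge into one site; the site
p-value is the minimum member p-value and the signal is the ChIP/scaled-input
ratio recomputed over the merged interval. Raw p-values are filtered
directly, mirroring the practice the pipeline models; a Benjamini–Hochberg
column is available for users who want FDR control. No multi-window
multiple-testing correction is applied to site calls.

## Target assignment

The assignment is midpoint-based throughout: "within the gene" means the
site midpoint lies in the transcript's TSS–TES span (a midpoint exactly at
the TSS or TES counts as internal), not peak-interval overlap. Distance
boundaries follow the verbatim bin definitions: "less than 2 kb" is strict
(< 2000), "within 2–5 kb" is the closed interval [2000, 5000]. Isoforms
collapse to genes by minimum distance, ties broken by relation rank
(internal ≻ downstream-of-site ≻ upstream-of-site) and then gene id.
These inclusivity choices are configurable call arguments (`near`,
`search`), since the boundary conventions of the original procedure are not
documented facts. Correctness is established against an independent
brute-force enumeration (random dense annotations plus an exhaustive
one-site grid over small layouts) rather than against hand-picked cases
only.

## Pol II stalling

The differential map is **factor − input**, each scaled to counts per
million mapped reads first, so that factor enrichment is positive;
negative values are retained in the means (clamping is an option). The
promoter is TSS ± 300 bp (strand-symmetric), the body runs from 600 bp
downstream of the TSS to the TES in transcription orientation, and the
index is promoter mean over body mean with strict `> 4` for the stalled
call. Guards: body mean ≤ 0 with positive promoter mean gives an infinite
index (stalled); both non-positive gives an undefined index (classified by
enrichment, i.e. absent when the transcript span shows no significant
Pol II signal). Transcripts no longer than 600 bp cannot have a body and
are flagged `short` (classified uniform/absent only). Whether the original
procedure computed means on normalized or raw tag counts is not documented;
normalized is the default here, and the index is scale-invariant either
way.

## Stage comparison

Target-set overlap is exact set arithmetic; display percentages round half
away from zero (raw fractions are always emitted). For concordance, every
site interval is tiled into 600 bp bins — a terminal partial bin shorter
than half the bin is merged into its predecessor — and per bin the tag
count over scaled input is computed per sample; Pearson correlation is
taken over all bins pooled (default) or per site and averaged, since the
original "average correlation coefficient" wording is ambiguous between
the two.

## Motif statistics

Log-odds scores are discretized at 0.01 bits and the exact distribution of
a background w-mer's score is computed by positional convolution; match
p-values and thresholds come from that distribution, so "match p < 1e-4"
is realized exactly up to grid rounding (the only approximation relative to
continuous scores; both strands get their own distribution so asymmetric
backgrounds are handled). Multi-motif E-value machinery of full
motif-search suites is deliberately out of scope — the per-match p-value
cutoff is applied directly. Background base frequencies default to uniform
and should be set to the genome's composition for genome scans. Bound
regions are the central 1 kb of the top-200 sites by p-value; background
regions are 1 kb windows starting 1 kb upstream of the center for every
site with p < 0.05 (windows off the chromosome are dropped and counted).
Enrichment is the ratio of match fractions, with a two-sided Fisher exact
test; a zero-match background yields an infinite-ratio sentinel with the
exact test still computed.

## Expression and gene sets

DCPM is the mean per-base depth over the transcript divided by
(total mapped reads / 10⁶); it is linear in coverage and inversely linear
in library size. "Expressed" defaults to DCPM > 0 — no principled universal
threshold exists, so the cutoff is a prominent parameter
(`expressed_min_dcpm`). The running-sum enrichment score uses the classic
unweighted increments (+1/Nh at members, −1/(N−Nh) otherwise); the curve
provably ends at 0 and |ES| ≤ 1. The permutation null draws random
same-size gene sets (seed-controlled); NES divides ES by the mean |null
ES|. The hypergeometric overlap test is the upper tail P[X ≥ k] computed
via SciPy's survival function; the universe size is always an explicit
argument because overlap significance is meaningless without it.

## Synthetic-data generator: what it emulates and what it does not

Coverage is drawn directly as per-base Poisson counts — the downstream
statistics consume coverage, not reads — with rectangular site profiles
(fold × background inside the site, no shoulders; tapered profiles are not
modeled). Defaults describe the study conditions used throughout the tests:
1 Mb chromosome, 200 genes (mean length 2 kb, exponential spacing of mean
1 kb), background depth λ = 2 per base, 50 planted 400 bp sites at fold 10
near promoters, Pol II body depth 5 with promoter:body fold 10 for a 10%
stalled fraction (20% absent), lognormal expression levels, a sharp 12 bp
planted motif (97–99% consensus per column) at rates 0.6 (bound centers) /
0.2 (1 kb upstream), and a 0.55 shared-site fraction for stage pairs.

Three generator constraints exist so that truth labels mean what they
claim: intergenic gaps are at least 400 bp (a ±300 bp promoter window can
then never reach into a neighboring gene's body), isoforms are never
trimmed below 700 bp (a transcript shorter than the 600 bp body offset
cannot carry a stalling index, so it should not carry a "stalled" truth
label), and Pol II class is drawn per gene so isoforms of one locus share a
label.

The motif-recovery study uses its own conditions: a sparse-site genome
(10 Mb, 30 kb mean spacing, 220 sites) and match p = 1e-6. With the
default 1 kb windows at match p = 1e-4 the expected random-match floor is
≈0.15 per window and upstream background windows of one site frequently
contain a neighboring site's planted occurrence; both effects compress the
measured ratio well below the planted 3.0 regardless of implementation
correctness. Sparse sites remove the contamination and the stringent cutoff
removes the floor, so measured enrichment (mean of 5 seeds; single-seed
values fluctuate with binomial noise on ~200 background windows) estimates
the planted bound/background rate ratio.

What passing these studies does **not** show about real data: no fragment-
length or mappability effects, no overdispersion beyond Poisson, no
chromatin-state or GC biases, rectangular peaks, and i.i.d. background
sequence. The generator validates the statistics' correctness and
operating characteristics under their own model, not their robustness to
real-library artifacts.

## Pipeline

`run_pipeline` executes simulate → call-peaks → assign-targets → stalling →
compare-stages → motif-enrich → dcpm → enrich-sets with one flat
configuration (every printed threshold a named key: window 200, step 50,
site p 1e-5, concordance p 1e-3, search 5000, near 2000, promoter pad 300,
body offset 600, stalling threshold 4, top 200, match p 1e-4, background
site p 0.05, bin 600). Identical config + seed gives byte-identical
outputs; the manifest deliberately omits wall-clock fields for that reason
(timing goes to the log stream). A stage failure raises an error naming the
stage and preserves tables already written.

## Known limitations

- The window scorer is a transparent stand-in, not a reproduction of any
  published caller; absolute site counts on real data will differ.
- Assignment ignores long-range regulation: a 5 kb search radius by
  construction cannot attach distal enhancers.
- The stalling classifier inherits the promoter window's ±300 bp reach:
  in extremely dense genomes a neighbor's promoter signal can leak into a
  short gene's windows (the generator's spacing floor avoids this in
  simulation; real annotations may not).
- GFF3/BED12 parsing covers the gene/mRNA subset this pipeline consumes,
  with line-numbered errors, not the full feature ontology.
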