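"""Core domain model and file I/O.

Coordinates are 0-based half-open throughout the package. GFF3 input and
output converts from/to that format's 1-based inclusive convention; BED and
bedGraph files are natively 0-based. TSS and TES are single base coordinates
oriented by strand: on the forward strand ``tss <= tes``, on the reverse
strand ``tss >= tes``, and the transcript span is the closed interval
between the two, stored half-open as ``[start, end)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FORWARD = "+"
REVERSE = "-"

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Distance used when a transcript has no annotated TSS: the start site is
#: placed this many bases 5'-ward of the annotated ATG.
TSS_FROM_ATG_OFFSET = 150


class FormatError(ValueError):
    """A file did not parse under the named standard."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """One transcript isoform with stranded TSS/TES base coordinates.

    ``tss`` may be ``None`` when the start site is not annotated; it is then
    derived from the ATG via :func:`derive_tss`.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int | None
    tes: int
    atg: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"transcript {self.id}: strand must be + or -")
        if self.tss is None and self.atg is None:
            raise ValueError(
                f"transcript {self.id}: neither TSS nor ATG is annotated"
            )
        ts = derive_tss(self)
        if self.strand == FORWARD and ts > self.tes:
            raise ValueError(f"transcript {self.id}: TSS > TES on + strand")
        if self.strand == REVERSE and ts < self.tes:
            raise ValueError(f"transcript {self.id}: TSS < TES on - strand")

    @property
    def is_reverse(self) -> bool:
        return self.strand == REVERSE

    @property
    def start(self) -> int:
        """0-based start of the TSS-to-TES span (half-open)."""
        return min(derive_tss(self), self.tes)

    @property
    def end(self) -> int:
        """Exclusive end of the TSS-to-TES span."""
        return max(derive_tss(self), self.tes) + 1

    @property
    def length(self) -> int:
        return self.end - self.start


def derive_tss(transcript: Transcript) -> int:
    """Return the transcript's TSS, falling back to the ATG rule.

    An annotated TSS is returned unchanged. Otherwise the start site is set
    150 bases 5'-ward of the ATG in the transcript's orientation.
    """
    if transcript.tss is not None:
        return transcript.tss
    if transcript.atg is None:
        raise ValueError(
            f"transcript {transcript.id}: neither TSS nor ATG is annotated"
        )
    if transcript.strand == FORWARD:
        return transcript.atg - TSS_FROM_ATG_OFFSET
    return transcript.atg + TSS_FROM_ATG_OFFSET


@dataclass
class GenomeAnnotation:
    """A set of transcripts grouped into genes over named chromosomes."""

    chromosomes: dict[str, int]
    transcripts: list[Transcript]
    gene_index: dict[str, list[str]] = field(init=False, repr=False)
    _by_chrom: dict[str, list[Transcript]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.gene_index = {}
        self._by_chrom = {c: [] for c in self.chromosomes}
        by_id: dict[str, Transcript] = {}
        for t in self.transcripts:
            if t.chrom not in self.chromosomes:
                raise ValueError(f"transcript {t.id}: unknown chromosome {t.chrom}")
            if t.start < 0 or t.end > self.chromosomes[t.chrom]:
                raise ValueError(
                    f"transcript {t.id}: span [{t.start},{t.end}) outside "
                    f"chromosome {t.chrom} of length {self.chromosomes[t.chrom]}"
                )
            if t.id in by_id:
                raise ValueError(f"duplicate transcript id {t.id}")
            by_id[t.id] = t
            self.gene_index.setdefault(t.gene_id, []).append(t.id)
            self._by_chrom[t.chrom].append(t)
        for txs in self._by_chrom.values():
            txs.sort(key=lambda t: (t.start, t.id))
        self._tx_by_id = by_id

    def transcripts_on(self, chrom: str) -> list[Transcript]:
        return self._by_chrom.get(chrom, [])

    def transcript(self, tx_id: str) -> Transcript:
        return self._tx_by_id[tx_id]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_index)

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)


@dataclass
class CoverageTrack:
    """Per-base, non-negative coverage over one or more chromosomes.

    ``total_mapped_reads`` is carried explicitly: per-base sums are inflated
    by fragment length, so library size cannot be recovered from coverage.
    """

    data: dict[str, np.ndarray]
    total_mapped_reads: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: coverage must be one-dimensional")
            if arr.size and arr.min() < 0:
                raise ValueError(f"{chrom}: negative coverage values")
            self.data[chrom] = arr

    @property
    def chromosomes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        arr = self.data[chrom]
        return float(arr[max(start, 0) : min(end, len(arr))].sum())

    def per_million(self) -> dict[str, np.ndarray]:
        """Coverage scaled to counts per million mapped reads."""
        scale = self.total_mapped_reads / 1e6
        return {c: a / scale for c, a in self.data.items()}


@dataclass
class SignalMap:
    """A signed per-base signal, e.g. a ChIP-minus-input differential map."""

    data: dict[str, np.ndarray]

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        arr = self.data[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        if hi <= lo:
            return float("nan")
        return float(arr[lo:hi].mean())


@dataclass(frozen=True)
class BindingSite:
    """A called peak: an interval with a score p-value and an
    input-normalized signal (ChIP reads over scaled input in the interval)."""

    chrom: str
    start: int
    end: int
    p_value: float
    signal: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("binding site start must be < end")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")
        if self.signal < 0:
            raise ValueError("signal must be non-negative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


#: Pseudo-probability floor applied when normalizing PWM counts.
PWM_PROB_FLOOR = 1e-4


@dataclass
class Pwm:
    """Position weight matrix: per-position base probabilities (rows A,C,G,T)
    plus background base frequencies."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x w with w >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("PWM background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """4 x w log2 odds of each base vs background, with the probability
        floor applied so log odds are finite."""
        probs = np.maximum(self.matrix, PWM_PROB_FLOOR)
        return np.log2(probs / self.background[:, None])

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, background=None, name: str = "motif"
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        probs = np.maximum(probs, PWM_PROB_FLOOR)
        probs = probs / probs.sum(axis=0, keepdims=True)
        kwargs = {} if background is None else {"background": np.asarray(background)}
        return cls(matrix=probs, name=name, **kwargs)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def _tss_tes_from_interval(start: int, end: int, strand: str) -> tuple[int, int]:
    """Map a 0-based half-open span to (tss, tes) base coordinates."""
    if strand == FORWARD:
        return start, end - 1
    return end - 1, start


def read_annotation(path, chrom_sizes: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read a GFF3 (``.gff``/``.gff3``) or BED12 (``.bed``) annotation.

    GFF3 chromosome lengths come from ``##sequence-region`` pragmas; for
    BED12 they must be supplied via ``chrom_sizes`` or are inferred as the
    maximal transcript end seen per chromosome.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _read_gff3(path, chrom_sizes)
    if path.endswith(".bed"):
        return _read_bed12(path, chrom_sizes)
    raise FormatError(f"unrecognized annotation extension: {path}")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _read_gff3(path: str, chrom_sizes: dict[str, int] | None) -> GenomeAnnotation:
    sizes: dict[str, int] = dict(chrom_sizes or {})
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(f"line {lineno}: bad sequence-region pragma")
                sizes[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype not in ("mRNA", "transcript"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
                attrs = _parse_gff3_attributes(attr_s)
            except (ValueError, FormatError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if "ID" not in attrs:
                raise FormatError(f"line {lineno}: transcript record lacks ID")
            start, end = start1 - 1, end1  # to 0-based half-open
            if end <= start:
                raise FormatError(f"line {lineno}: empty interval")
            atg = int(attrs["atg"]) - 1 if "atg" in attrs else None
            if attrs.get("tss_defined", "true").lower() in ("false", "0"):
                tss, tes = None, _tss_tes_from_interval(start, end, strand)[1]
            else:
                tss, tes = _tss_tes_from_interval(start, end, strand)
            transcripts.append(
                Transcript(
                    id=attrs["ID"],
                    gene_id=attrs.get("Parent", attrs["ID"]),
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    atg=atg,
                )
            )
    if not sizes:
        sizes = _infer_sizes(transcripts)
    return GenomeAnnotation(chromosomes=sizes, transcripts=transcripts)


def _infer_sizes(transcripts: list[Transcript]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for t in transcripts:
        sizes[t.chrom] = max(sizes.get(t.chrom, 0), t.end)
    return sizes


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    """Write GFF3 (gene + mRNA records, 1-based inclusive coordinates)."""
    path = str(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chromosomes.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene_id in annotation.gene_ids:
            txs = [annotation.transcript(i) for i in annotation.gene_index[gene_id]]
            chrom = txs[0].chrom
            gstart = min(t.start for t in txs)
            gend = max(t.end for t in txs)
            strand = txs[0].strand
            fh.write(
                f"{chrom}\tchipscope\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in sorted(txs, key=lambda t: t.id):
                attrs = [f"ID={t.id}", f"Parent={t.gene_id}"]
                if t.atg is not None:
                    attrs.append(f"atg={t.atg + 1}")
                if t.tss is None:
                    attrs.append("tss_defined=false")
                fh.write(
                    f"{t.chrom}\tchipscope\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{';'.join(attrs)}\n"
                )


def _read_bed12(path: str, chrom_sizes: dict[str, int] | None) -> GenomeAnnotation:
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected >= 6 BED columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if end <= start:
                raise FormatError(f"line {lineno}: empty interval")
            if "|" in name:
                gene_id, tx_id = name.split("|", 1)
            else:
                gene_id = tx_id = name
            atg = None
            if len(fields) >= 8:
                thick_start, thick_end = int(fields[6]), int(fields[7])
                if thick_end > thick_start:
                    atg = thick_start if strand == FORWARD else thick_end - 1
            tss, tes = _tss_tes_from_interval(start, end, strand)
            transcripts.append(
                Transcript(
                    id=tx_id, gene_id=gene_id, chrom=chrom, strand=strand,
                    tss=tss, tes=tes, atg=atg,
                )
            )
    sizes = dict(chrom_sizes or {}) or _infer_sizes(transcripts)
    return GenomeAnnotation(chromosomes=sizes, transcripts=transcripts)


# ---------------------------------------------------------------------------
# coverage track I/O (bedGraph with a track header)
# ---------------------------------------------------------------------------

_TRACK_RE = re.compile(r"(\w+)=(\S+)")


def read_track(path, chrom_sizes: dict[str, int] | None = None) -> CoverageTrack:
    """Read a bedGraph into per-base arrays.

    The file must start with a ``track`` line carrying
    ``total_mapped_reads=<int>``; chromosome lengths come from a
    ``#chrom_sizes name=length ...`` comment line unless supplied.
    Intervals must be non-overlapping; uncovered bases are zero.
    """
    sizes: dict[str, int] = dict(chrom_sizes or {})
    total = None
    label = ""
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("track"):
                meta = dict(_TRACK_RE.findall(line))
                if "total_mapped_reads" in meta:
                    total = float(meta["total_mapped_reads"])
                label = meta.get("name", label)
                continue
            if line.startswith("#chrom_sizes"):
                for key, value in _TRACK_RE.findall(line.split(None, 1)[1]):
                    sizes[key] = int(value)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"line {lineno}: expected 4 bedGraph columns")
            try:
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if value < 0:
                raise FormatError(f"line {lineno}: negative coverage value")
            if end <= start:
                raise FormatError(f"line {lineno}: empty interval")
            records.append((chrom, start, end, value))
    if total is None:
        raise FormatError(f"{path}: track header lacks total_mapped_reads")
    if not sizes:
        for chrom, _start, end, _v in records:
            sizes[chrom] = max(sizes.get(chrom, 0), end)
    data = {c: np.zeros(length) for c, length in sizes.items()}
    last_end: dict[str, int] = {}
    records.sort(key=lambda r: (r[0], r[1]))
    for chrom, start, end, value in records:
        if chrom not in data:
            raise FormatError(f"interval on unknown chromosome {chrom}")
        if start < last_end.get(chrom, 0):
            raise FormatError(f"overlapping intervals on {chrom} at {start}")
        if end > len(data[chrom]):
            raise FormatError(f"interval beyond end of {chrom}")
        data[chrom][start:end] = value
        last_end[chrom] = end
    return CoverageTrack(data=data, total_mapped_reads=total, label=label)


def write_track(track: CoverageTrack, path) -> None:
    """Write a run-length encoded bedGraph with the track header."""
    with open(path, "w") as fh:
        total = track.total_mapped_reads
        total_s = str(int(total)) if float(total).is_integer() else repr(total)
        name = track.label or "track"
        fh.write(f"track type=bedGraph name={name} total_mapped_reads={total_s}\n")
        sizes = " ".join(f"{c}={n}" for c, n in sorted(track.chromosomes.items()))
        fh.write(f"#chrom_sizes {sizes}\n")
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                v_s = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{s}\t{e}\t{v_s}\n")


# ---------------------------------------------------------------------------
# binding-site tables and PWM files
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["chrom", "start", "end", "p_value", "signal"]


def sites_to_frame(sites: list[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.p_value, s.signal) for s in sites],
        columns=SITE_COLUMNS,
    )


def frame_to_sites(frame: pd.DataFrame) -> list[BindingSite]:
    return [
        BindingSite(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            p_value=float(r.p_value), signal=float(r.signal),
        )
        for r in frame.itertuples(index=False)
    ]


def read_sites(path) -> list[BindingSite]:
    """Read a peak table (TSV with header chrom/start/end/p_value/signal)."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: site table lacks columns {sorted(missing)}")
    return frame_to_sites(frame)


def write_sites(sites: list[BindingSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_pwm(path) -> Pwm:
    """Read a tab-separated PWM: 4 labeled rows (A,C,G,T) x w columns.

    Probabilities are expected; raw counts are accepted and normalized with
    a pseudo-probability floor. Background frequencies may be given on a
    ``#background A C G T`` comment line (default uniform).
    """
    background = None
    name = "motif"
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#background"):
                background = np.array([float(x) for x in line.split()[1:5]])
                continue
            if line.startswith("#name"):
                name = line.split(None, 1)[1]
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] not in BASE_INDEX:
                raise FormatError(f"line {lineno}: row label must be A/C/G/T")
            rows[fields[0]] = [float(x) for x in fields[1:]]
    if set(rows) != set(BASES):
        raise FormatError(f"{path}: PWM needs exactly the rows A, C, G, T")
    matrix = np.array([rows[b] for b in BASES])
    col_sums = matrix.sum(axis=0)
    if np.allclose(col_sums, 1.0, atol=1e-6):
        kwargs = {} if background is None else {"background": background}
        return Pwm(matrix=matrix / col_sums, name=name, **kwargs)
    return Pwm.from_counts(matrix, background=background, name=name)


def write_pwm(pwm: Pwm, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name {pwm.name}\n")
        fh.write("#background " + " ".join(repr(float(x)) for x in pwm.background) + "\n")
        for i, base in enumerate(BASES):
            fh.write(base + "\t" + "\t".join(repr(float(x)) for x in pwm.matrix[i]) + "\n")


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    """Write named sequences as FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
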