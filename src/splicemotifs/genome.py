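"""Genome sequences, exon annotations and background-exon sampling.

All internal coordinates are 0-based, half-open genomic intervals;
conversion to/from 1-based GTF happens only at the I/O boundary. Sequences
are stored on the plus (genomic) strand in uppercase DNA; RNA input (U) is
converted to T on read. ``fetch_sense_sequence`` returns the RNA-sense
strand, i.e. the reverse complement for minus-strand features — the strand
an RNA-binding protein actually sees.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import AnnotationError, GenomeError

# IUPAC nucleotide alphabet (DNA form); N and degenerate codes are legal in
# genome sequence but are never matched by a motif.
IUPAC_DNA = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: contig name -> uppercase DNA string."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = dict(sequences)

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def length(self, contig: str) -> int:
        self._require(contig)
        return len(self._seqs[contig])

    def sequence(self, contig: str) -> str:
        self._require(contig)
        return self._seqs[contig]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Plus-strand substring of ``contig`` over [start, end)."""
        self._require(contig)
        seq = self._seqs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise GenomeError(
                f"interval [{start}, {end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def _require(self, contig: str) -> None:
        if contig not in self._seqs:
            raise GenomeError(f"unknown contig {contig!r}")

    def reverse_complemented(self) -> "GenomeSequence":
        """A new genome with every contig reverse-complemented."""
        return GenomeSequence(
            {c: reverse_complement(s) for c, s in self._seqs.items()}
        )


def read_genome_fasta(path: str | Path) -> GenomeSequence:
    """Read a (possibly line-wrapped) FASTA file into memory.

    Lowercase bases are uppercased and U is converted to T. Duplicate
    headers, empty records and non-IUPAC characters are errors.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeError(f"FASTA file not found: {path}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise GenomeError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise GenomeError(f"empty FASTA record {rec.id!r}")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise GenomeError(
                f"non-IUPAC character(s) {sorted(bad)} in record {rec.id!r}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise GenomeError(f"no FASTA records in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in genome.contigs:
            fh.write(f">{contig}\n")
            seq = genome.sequence(contig)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class ExonRecord:
    """One exon, 0-based half-open genomic coordinates.

    ``exon_rank`` counts 1-based in transcript (5'→3') orientation;
    ``internal`` is True iff the exon is neither first nor last in its
    transcript, i.e. both its splice sites are defined.
    """

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    exon_rank: int = 0
    internal: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid exon interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.contig, self.start, self.end, self.strand)


class AnnotationSet:
    """Exons grouped by transcript, genomically sorted within transcript."""

    def __init__(self, exons: list[ExonRecord]):
        by_tx: dict[str, list[ExonRecord]] = defaultdict(list)
        for ex in exons:
            by_tx[ex.transcript_id].append(ex)
        self._by_tx: dict[str, list[ExonRecord]] = {}
        out: list[ExonRecord] = []
        for tid, exs in by_tx.items():
            exs = sorted(exs, key=lambda e: e.start)
            for a, b in zip(exs, exs[1:]):
                if b.start < a.end:
                    raise AnnotationError(
                        f"overlapping exons in transcript {tid!r}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
            n = len(exs)
            ranked = []
            for i, ex in enumerate(exs):
                rank = i + 1 if ex.strand == "+" else n - i
                ranked.append(
                    replace(ex, exon_rank=rank, internal=(0 < i < n - 1))
                )
            self._by_tx[tid] = ranked
            out.extend(ranked)
        self.exons: list[ExonRecord] = out

    def __len__(self) -> int:
        return len(self.exons)

    @property
    def transcripts(self) -> dict[str, list[ExonRecord]]:
        return self._by_tx

    def internal_exons(self) -> list[ExonRecord]:
        return [ex for ex in self.exons if ex.internal]

    def introns(self) -> list[tuple[str, int, int, str, str]]:
        """(contig, start, end, strand, transcript_id) between adjacent exons."""
        out = []
        for tid, exs in self._by_tx.items():
            for a, b in zip(exs, exs[1:]):
                out.append((a.contig, a.end, b.start, a.strand, tid))
        return out


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def _read_gtf(path: Path) -> list[ExonRecord]:
    exons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            contig, _, feature, start, end, _, strand, _, attr = fields[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            # GTF is 1-based inclusive
            start0, end0 = start1 - 1, end1
            if end0 <= start0:
                raise AnnotationError(
                    f"{path}:{lineno}: exon end <= start"
                )
            attrs = _parse_gtf_attributes(attr)
            gene = attrs.get("gene_id", "")
            tx = attrs.get("transcript_id", "")
            if not tx:
                raise AnnotationError(
                    f"{path}:{lineno}: exon feature without transcript_id"
                )
            exons.append(
                ExonRecord(contig, start0, end0, strand, gene, tx)
            )
    return exons


def _read_bed12(path: Path) -> list[ExonRecord]:
    exons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 12 BED12 fields, got {len(fields)}"
                )
            contig = fields[0]
            try:
                chrom_start = int(fields[1])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer BED12 field"
                ) from exc
            name, strand = fields[3], fields[5]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount does not match block lists"
                )
            for size, off in zip(sizes, starts):
                s = chrom_start + off
                if size <= 0:
                    raise AnnotationError(f"{path}:{lineno}: non-positive blockSize")
                exons.append(ExonRecord(contig, s, s + size, strand, name, name))
    return exons


def read_annotation(path: str | Path, fmt: str = "GTF") -> AnnotationSet:
    """Read exon annotation from GTF (1-based) or BED12 (0-based half-open).

    All records are converted to 0-based half-open coordinates and
    internal-exon flags are computed per transcript.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    fmt = fmt.upper()
    if fmt == "GTF":
        exons = _read_gtf(path)
    elif fmt == "BED12":
        exons = _read_bed12(path)
    else:
        raise AnnotationError(f"unknown annotation format {fmt!r}")
    return AnnotationSet(exons)


def write_gtf(ann: AnnotationSet, path: str | Path, source: str = "splicemotifs") -> None:
    with open(path, "w") as fh:
        for tid, exs in ann.transcripts.items():
            for ex in exs:
                attr = f'gene_id "{ex.gene_id}"; transcript_id "{tid}";'
                fh.write(
                    "\t".join(
                        [
                            ex.contig,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            ex.strand,
                            ".",
                            attr,
                        ]
                    )
                    + "\n"
                )


def write_bed12(ann: AnnotationSet, path: str | Path) -> None:
    """One BED12 line per transcript; name field carries the transcript id."""
    with open(path, "w") as fh:
        for tid, exs in ann.transcripts.items():
            start = exs[0].start
            end = exs[-1].end
            sizes = ",".join(str(e.length) for e in exs)
            offs = ",".join(str(e.start - start) for e in exs)
            fh.write(
                "\t".join(
                    [
                        exs[0].contig,
                        str(start),
                        str(end),
                        tid,
                        "0",
                        exs[0].strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(exs)),
                        sizes,
                        offs,
                    ]
                )
                + "\n"
            )


def sample_background_exons(
    ann: AnnotationSet,
    n: int = 150_000,
    seed: int = 0,
    min_len: int = 8,
    exclude: set | None = None,
) -> list[ExonRecord]:
    """Uniform sample of internal exons, without replacement.

    Eligible exons are internal (both splice sites defined) with length
    >= ``min_len``; ``exclude`` removes exons by (contig, start, end, strand)
    key. Reproducible for a fixed seed.
    """
    pool = [ex for ex in ann.internal_exons() if ex.length >= min_len]
    if exclude:
        pool = [ex for ex in pool if ex.key not in exclude]
    if not pool:
        raise AnnotationError(
            "no eligible internal exons in annotation "
            f"(min_len={min_len}); cannot sample a background set"
        )
    if n > len(pool):
        raise AnnotationError(
            f"requested {n} background exons but only {len(pool)} eligible "
            f"internal exons are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def fetch_sense_sequence(
    genome: GenomeSequence, contig: str, start: int, end: int, strand: str
) -> str:
    """RNA-sense sequence of [start, end): reverse complement on minus."""
    seq = genome.fetch(contig, start, end)
    if strand == "+":
        return seq
    if strand == "-":
        return reverse_complement(seq)
    raise GenomeError(f"invalid strand {strand!r}")
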