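"""Splice-site region extraction around cassette exons and background exons.

Each region spans one splice site with a configurable exonic extent ``e``
and intronic extent ``i`` (defaults 100 + 100 nt). Sequences are returned
5'→3' on the RNA sense strand, so a donor (5'ss) region reads exon-then-
intron and an acceptor (3'ss) region reads intron-then-exon regardless of
genomic strand.

Event labels follow transcript order around a cassette exon:
``5ss1`` donor of the upstream exon, ``3ss1`` acceptor of the cassette,
``5ss2`` donor of the cassette, ``3ss2`` acceptor of the downstream exon.
Background exons contribute one ``3ss`` (acceptor) and one ``5ss`` (donor)
region each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import SpliceMotifsError
from .events import SEEvent
from .genome import ExonRecord, GenomeSequence, fetch_sense_sequence

EVENT_LABELS = ("5ss1", "3ss1", "5ss2", "3ss2")
BACKGROUND_LABELS = ("5ss", "3ss")

# donor-side labels contrast against background "5ss", acceptor-side
# against background "3ss" (like-for-like splice-site context)
LABEL_SIDE = {
    "5ss1": "5ss", "5ss2": "5ss", "5ss": "5ss",
    "3ss1": "3ss", "3ss2": "3ss", "3ss": "3ss",
}


@dataclass
class SpliceSiteRegion:
    """A sense-strand window around one splice site.

    ``boundary_offset`` is the index of the splice-site boundary within
    ``sequence`` (number of nt 5' of the site on the RNA); a motif starting
    at sequence index j starts at offset j − boundary_offset relative to
    the splice site.
    """

    parent_id: str
    label: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    exon_ext: int
    intron_ext: int
    boundary_offset: int
    truncated: bool = False
    clipped: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def _make_region(
    genome: GenomeSequence,
    contig: str,
    strand: str,
    boundary: int,
    up_ext: int,
    down_ext: int,
    label: str,
    parent_id: str,
    exon_ext: int,
    intron_ext: int,
    truncated: bool,
) -> SpliceSiteRegion | None:
    """Build one region given RNA-upstream/-downstream extents at a boundary."""
    if strand == "+":
        gs, ge = boundary - up_ext, boundary + down_ext
    else:
        gs, ge = boundary - down_ext, boundary + up_ext
    clen = genome.length(contig)
    cgs, cge = max(0, gs), min(clen, ge)
    clipped = (cgs, cge) != (gs, ge)
    full_window = exon_ext + intron_ext
    if cge <= cgs or (cge - cgs) < full_window / 2:
        if clipped:
            warnings.warn(
                f"region {parent_id}|{label} clipped below half the window; dropped",
                stacklevel=3,
            )
            return None
        raise SpliceMotifsError(
            f"empty splice-site window for {parent_id}|{label} "
            f"(exon_ext={exon_ext}, intron_ext={intron_ext})"
        )
    if clipped:
        warnings.warn(
            f"region {parent_id}|{label} clipped to contig bounds", stacklevel=3
        )
    seq = fetch_sense_sequence(genome, contig, cgs, cge, strand)
    offset = (boundary - cgs) if strand == "+" else (cge - boundary)
    return SpliceSiteRegion(
        parent_id=parent_id,
        label=label,
        contig=contig,
        start=cgs,
        end=cge,
        strand=strand,
        sequence=seq,
        exon_ext=exon_ext,
        intron_ext=intron_ext,
        boundary_offset=offset,
        truncated=truncated,
        clipped=clipped,
    )


def _donor_region(genome, contig, strand, exon, e, i, label, parent_id):
    """Donor (5'ss): last min(e, exon length) exonic nt + first i intronic nt."""
    s, t = exon
    e_eff = min(e, t - s)
    truncated = e_eff < e
    boundary = t if strand == "+" else s
    return _make_region(
        genome, contig, strand, boundary, e_eff, i, label, parent_id, e, i, truncated
    )


def _acceptor_region(genome, contig, strand, exon, e, i, label, parent_id):
    """Acceptor (3'ss): last i intronic nt + first min(e, exon length) exonic nt."""
    s, t = exon
    e_eff = min(e, t - s)
    truncated = e_eff < e
    boundary = s if strand == "+" else t
    return _make_region(
        genome, contig, strand, boundary, i, e_eff, label, parent_id, e, i, truncated
    )


def _check_window(e: int, i: int) -> None:
    if e < 0 or i < 0 or (e == 0 and i == 0):
        raise SpliceMotifsError(
            f"degenerate window: exon_ext={e}, intron_ext={i}"
        )


def extract_event_regions(
    event: SEEvent, genome: GenomeSequence, e: int = 100, i: int = 100
) -> list[SpliceSiteRegion]:
    """The four splice-site regions of one skipped-exon event.

    Regions dropped by contig-boundary clipping are omitted (with a
    warning); exons shorter than ``e`` get a truncated exonic extent and
    the region is flagged.
    """
    _check_window(e, i)
    out = []
    spec = [
        ("5ss1", _donor_region, event.upstream),
        ("3ss1", _acceptor_region, event.cassette),
        ("5ss2", _donor_region, event.cassette),
        ("3ss2", _acceptor_region, event.downstream),
    ]
    for label, fn, exon in spec:
        region = fn(genome, event.contig, event.strand, exon, e, i, label, event.event_id)
        if region is not None:
            out.append(region)
    return out


def extract_background_regions(
    exons: list[ExonRecord], genome: GenomeSequence, e: int = 100, i: int = 100
) -> list[SpliceSiteRegion]:
    """One acceptor (``3ss``) and one donor (``5ss``) region per exon."""
    _check_window(e, i)
    out = []
    for ex in exons:
        pid = f"{ex.contig}:{ex.start}-{ex.end}({ex.strand})"
        interval = (ex.start, ex.end)
        for label, fn in (("3ss", _acceptor_region), ("5ss", _donor_region)):
            region = fn(genome, ex.contig, ex.strand, interval, e, i, label, pid)
            if region is not None:
                out.append(region)
    return out


def write_regions_bed(regions: list[SpliceSiteRegion], path) -> None:
    """BED6 of region intervals; name = parent_id|label."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.parent_id}|{r.label}\t0\t{r.strand}\n"
            )


def write_regions_fasta(regions: list[SpliceSiteRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.parent_id}|{r.label}\n{r.sequence}\n")
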