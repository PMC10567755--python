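"""Synthetic genomes, events, motif plantings and reads with known truth.

Every pipeline stage gets a ground-truth recovery test without external
downloads: an i.i.d. genome with a regular gene structure, skipped-exon
events with beta-binomial junction counts at controllable true PSI,
motif occurrences planted in-place at controllable per-region rates
(regulated set vs background), and gapped/contiguous SAM reads mixing at a
controllable true splicing efficiency.

Default scale is 1,000 regulated events against 10,000 background exons
with a 20-motif catalog — large enough for stable Fisher tests, small
enough to run in minutes. All generators are deterministic per seed, and
downstream recovery tests read the truth only from
:class:`SimulationTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import AnnotationError, SpliceMotifsError
from .events import SEEvent, assign_das_stats
from .genome import AnnotationSet, ExonRecord, GenomeSequence, reverse_complement
from .motifs import IUPAC_CLASSES, MotifCatalog, MotifRecord, normalize_consensus
from .regions import SpliceSiteRegion, extract_background_regions, extract_event_regions

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationTruth:
    """Ground truth of one simulation; the only source recovery tests read."""

    seed: int
    background_rate: float = 0.0  # expected planted motif starts per 100 nt
    planted_motif_id: str | None = None
    target_label: str | None = None
    rate_multiplier: float = 1.0
    realized_counts: dict = field(default_factory=dict)  # label -> planted count
    background_pool_size: int = 0  # internal exons planted at background rate
    true_psi: dict = field(default_factory=dict)  # event id -> [psi_g1, psi_g2]
    true_theta: dict = field(default_factory=dict)  # site id -> theta
    regulated_event_ids: list = field(default_factory=list)
    background_exon_keys: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, val in vars(self).items():
                fh.write(f"{key}={json.dumps(val)}\n")

    @classmethod
    def read(cls, path: str | Path) -> "SimulationTruth":
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                key, _, val = line.rstrip("\n").partition("=")
                kwargs[key] = json.loads(val)
        return cls(**kwargs)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Stable sub-seeds below 2**31 derived from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. DNA of the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def generate_genome_annotation(
    n_genes: int,
    exons_per_gene: int,
    exon_len: int = 250,
    intron_len: int = 300,
    gc: float = 0.5,
    seed: int = 0,
    spacer: int = 200,
    contig: str = "chr1",
) -> tuple[GenomeSequence, AnnotationSet]:
    """A single-contig genome with regularly spaced multi-exon genes.

    Bases are i.i.d. at the requested GC; gene strands are random. Exon
    and intron lengths are uniform so splice-site windows up to
    exon_len − intron-window overlap constraints never collide.
    """
    if n_genes < 1 or exons_per_gene < 2:
        raise SpliceMotifsError("need at least 1 gene with 2 exons")
    if exon_len < 1 or intron_len < 1 or gc < 0 or gc > 1:
        raise SpliceMotifsError("invalid genome parameters")
    rng = np.random.default_rng(seed)
    gene_len = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    total = spacer + n_genes * (gene_len + spacer)
    seq = random_sequence(total, gc, rng)
    exons = []
    for g in range(n_genes):
        gene_id = f"g{g:05d}"
        tx_id = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = spacer + g * (gene_len + spacer)
        for e in range(exons_per_gene):
            s = gstart + e * (exon_len + intron_len)
            exons.append(
                ExonRecord(contig, s, s + exon_len, strand, gene_id, tx_id)
            )
    return GenomeSequence({contig: seq}), AnnotationSet(exons)


# 20-motif demo catalog: real RBP names with synthetic consensus choices.
# Consensus strings are all 6 nt and chosen so that (a) no non-planted
# motif IUPAC-matches the planted RBFOX2 UGCAUG hexamer and (b) no
# non-planted motif shares a >=3 nt end-overlap with it (both asserted by
# tests) — otherwise windows spanning a planted instance and its random
# flank would systematically inflate the other motif and break its null.
_DEMO_MOTIFS = [
    ("RBFOX2", "M01", "UGCAUG"),
    ("SRSF6", "M02", "UCGCGG"),
    ("HNRNPC", "M03", "UUUUUK"),
    ("PTBP1", "M04", "UUCUCU"),
    ("SRSF1", "M05", "GGAGGA"),
    ("HNRNPA1", "M06", "UUAGGG"),
    ("U2AF2", "M07", "CUUUCC"),
    ("TIA1", "M08", "AUUUUA"),
    ("QKI", "M09", "ACUAAC"),
    ("NOVA1", "M10", "UCAUUC"),
    ("MBNL1", "M11", "CUGCUU"),
    ("CELF1", "M12", "UGUGUG"),
    ("SRSF7", "M13", "ACGACG"),
    ("KHDRBS1", "M14", "AUAAAC"),
    ("ESRP2", "M15", "UGGGGA"),
    ("PCBP1", "M16", "CCCUCC"),
    ("IGF2BP1", "M17", "CAUCAC"),
    ("FUS", "M18", "GGUGGU"),
    ("ELAVL1", "M19", "UUUAUU"),
    ("SRSF5", "M20", "ACGCGA"),
]

PLANTED_MOTIF_ID = "M01"


def demo_catalog(organism: str = "Homo_sapiens") -> MotifCatalog:
    """The default synthetic 20-motif catalog (ATtRACT dialect on disk)."""
    return MotifCatalog(
        [
            MotifRecord(rbp=r, motif_id=m, consensus=c, organism=organism)
            for r, m, c in _DEMO_MOTIFS
        ],
        organism=organism,
    )


def define_cassette_events(
    ann: AnnotationSet, n_events: int, seed: int = 0
) -> list[SEEvent]:
    """Pick one internal exon per gene as a cassette, at most ``n_events``.

    Flanking exons are the transcript neighbours; intervals are stored in
    transcript orientation.
    """
    eligible = [
        (tid, exs) for tid, exs in sorted(ann.transcripts.items()) if len(exs) >= 3
    ]
    if n_events > len(eligible):
        raise AnnotationError(
            f"requested {n_events} cassette events but only {len(eligible)} "
            f"transcripts have an internal exon"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_events, replace=False)
    events = []
    for idx in sorted(chosen):
        tid, exs = eligible[idx]
        by_rank = {e.exon_rank: e for e in exs}
        rank = int(rng.integers(2, len(exs)))  # internal rank in [2, n-1]
        cas, up, down = by_rank[rank], by_rank[rank - 1], by_rank[rank + 1]
        events.append(
            SEEvent(
                event_id=f"ev_{tid}",
                gene_id=cas.gene_id,
                contig=cas.contig,
                strand=cas.strand,
                cassette=(cas.start, cas.end),
                upstream=(up.start, up.end),
                downstream=(down.start, down.end),
            )
        )
    return events


def event_exon_keys(events: list[SEEvent]) -> set:
    """(contig, start, end, strand) keys of every exon touched by events."""
    keys = set()
    for ev in events:
        for s, t in (ev.cassette, ev.upstream, ev.downstream):
            keys.add((ev.contig, s, t, ev.strand))
    return keys


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """One concrete A/C/G/T instance of an IUPAC consensus."""
    return "".join(
        c if len(IUPAC_CLASSES[c]) == 1 else IUPAC_CLASSES[c][rng.integers(len(IUPAC_CLASSES[c]))]
        for c in consensus
    )


def plant_motifs(
    genome: GenomeSequence,
    regions: list[SpliceSiteRegion],
    motif: MotifRecord,
    target_label: str | None,
    rate_regulated: float,
    rate_background: float,
    seed: int = 0,
) -> tuple[GenomeSequence, dict]:
    """Plant motif occurrences in-place at per-region Poisson rates.

    Regions whose label equals ``target_label`` receive
    ``rate_regulated`` expected motif starts per 100 nt; all other regions
    receive ``rate_background``. Planting replaces bases (coordinates are
    preserved) at non-overlapping sense-strand offsets; for minus-strand
    regions the reverse complement is written into the genome. Realized
    counts per label are returned alongside the modified genome.
    """
    cons = normalize_consensus(motif.consensus)
    m = len(cons)
    buffers = {c: bytearray(genome.sequence(c), "ascii") for c in genome.contigs}
    rng = np.random.default_rng(seed)
    realized: dict[str, int] = {}
    for region in regions:
        L = region.length
        if L < m:
            continue
        rate = rate_regulated if region.label == target_label else rate_background
        n = int(rng.poisson(rate * L / 100.0))
        if n == 0:
            realized.setdefault(region.label, 0)
            continue
        max_fit = (L // m)
        if n > max_fit:
            raise SpliceMotifsError(
                f"rate {rate}/100nt asks for {n} non-overlapping {m}-mers in a "
                f"{L} nt window (max {max_fit})"
            )
        starts = rng.permutation(L - m + 1)
        placed: list[int] = []
        for s in starts:
            if len(placed) == n:
                break
            if all(abs(s - q) >= m for q in placed):
                placed.append(int(s))
        buf = buffers[region.contig]
        for s in sorted(placed):
            inst = _realize_consensus(cons, rng)
            if region.strand == "+":
                g0 = region.start + s
                buf[g0 : g0 + m] = inst.encode("ascii")
            else:
                g0 = region.end - s - m
                buf[g0 : g0 + m] = reverse_complement(inst).encode("ascii")
        realized[region.label] = realized.get(region.label, 0) + len(placed)
    planted = GenomeSequence({c: b.decode("ascii") for c, b in buffers.items()})
    return planted, realized


def simulate_junction_counts(
    events: list[SEEvent],
    psi_group1,
    psi_group2,
    coverage: int = 100,
    overdispersion: float = 0.01,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict:
    """Fill beta-binomial junction counts and DAS statistics on events.

    Per replicate, inclusion counts are beta-binomial(coverage, PSI, ρ)
    with ICC-parameterised overdispersion ρ (ρ = 0 is plain binomial) and
    skip = coverage − inclusion. Effective lengths are written equal so
    PSI recovery inverts the count model exactly. p and adjusted p come
    from the internal pooled Fisher test with BH across events. Returns
    the true-PSI truth mapping.
    """
    psi1 = np.broadcast_to(np.asarray(psi_group1, dtype=float), (len(events),))
    psi2 = np.broadcast_to(np.asarray(psi_group2, dtype=float), (len(events),))
    if np.any((psi1 < 0) | (psi1 > 1) | (psi2 < 0) | (psi2 > 1)):
        raise SpliceMotifsError("true PSI must lie in [0, 1]")
    if coverage <= 0:
        raise SpliceMotifsError("coverage must be positive")
    rng = np.random.default_rng(seed)
    true_psi = {}

    def draw(psi: float) -> int:
        if overdispersion <= 0 or psi in (0.0, 1.0):
            return int(rng.binomial(coverage, psi))
        conc = (1.0 - overdispersion) / overdispersion
        return int(
            stats.betabinom.rvs(
                coverage, psi * conc, (1.0 - psi) * conc, random_state=rng
            )
        )

    for ev, p1, p2 in zip(events, psi1, psi2):
        ev.inc_len = ev.skip_len = 100.0
        ev.ijc1 = [draw(p1) for _ in range(n_replicates)]
        ev.sjc1 = [coverage - i for i in ev.ijc1]
        ev.ijc2 = [draw(p2) for _ in range(n_replicates)]
        ev.sjc2 = [coverage - i for i in ev.ijc2]
        true_psi[ev.event_id] = [float(p1), float(p2)]
    assign_das_stats(events)
    return true_psi


@dataclass
class EnrichmentDataset:
    """A complete planted-motif study: genome, events, regions, truth."""

    genome: GenomeSequence
    annotation: AnnotationSet
    events: list[SEEvent]
    background_exons: list[ExonRecord]
    regulated_regions: list[SpliceSiteRegion]
    background_regions: list[SpliceSiteRegion]
    catalog: MotifCatalog
    truth: SimulationTruth


def build_enrichment_dataset(
    n_events: int = 1000,
    n_background: int = 10_000,
    exons_per_gene: int = 16,
    exon_len: int = 250,
    intron_len: int = 300,
    gc: float = 0.5,
    catalog: MotifCatalog | None = None,
    planted_motif_id: str | None = PLANTED_MOTIF_ID,
    target_label: str | None = "3ss1",
    rate_multiplier: float = 5.0,
    background_rate: float = 0.2,
    exon_ext: int = 100,
    intron_ext: int = 100,
    n_genes: int | None = None,
    seed: int = 0,
) -> EnrichmentDataset:
    """Generate a full planted-motif enrichment study with known truth.

    One cassette event per selected gene; background exons are internal
    exons not touched by any event. The planted motif is written at
    ``background_rate × rate_multiplier`` starts per 100 nt into regulated
    regions with ``target_label`` and at ``background_rate`` into every
    other event region and into the splice-site windows of *all* eligible
    internal exons outside the event set — so any background sample drawn
    from the annotation afterwards sees the same base rate (a multiplier
    of 1 or a null ``target_label`` gives a null dataset).
    """
    if catalog is None:
        catalog = demo_catalog()
    if n_genes is None:
        n_genes = n_events + max(10, n_events // 10)
    s_genome, s_events, s_bg, s_plant = _child_seeds(seed, 4)
    genome, ann = generate_genome_annotation(
        n_genes, exons_per_gene, exon_len, intron_len, gc, seed=s_genome
    )
    events = define_cassette_events(ann, n_events, seed=s_events)
    from .genome import sample_background_exons

    event_keys = event_exon_keys(events)
    background = sample_background_exons(
        ann, n=n_background, seed=s_bg, exclude=event_keys
    )
    # region coordinates from the pristine genome; sequences re-fetched
    # after planting
    reg_regions = [
        r for ev in events for r in extract_event_regions(ev, genome, exon_ext, intron_ext)
    ]
    realized: dict[str, int] = {}
    pool_exons = [
        ex
        for ex in ann.internal_exons()
        if ex.length >= 8 and ex.key not in event_keys
    ]
    if planted_motif_id is not None and background_rate > 0:
        motif = catalog.get(planted_motif_id)
        # plant the base rate into every eligible internal-exon window so
        # any background sample drawn later is representative
        pool_regions = extract_background_regions(
            pool_exons, genome, exon_ext, intron_ext
        )
        genome, realized = plant_motifs(
            genome,
            reg_regions + pool_regions,
            motif,
            target_label,
            rate_regulated=background_rate * rate_multiplier,
            rate_background=background_rate,
            seed=s_plant,
        )
        reg_regions = [
            r
            for ev in events
            for r in extract_event_regions(ev, genome, exon_ext, intron_ext)
        ]
    bg_regions = extract_background_regions(background, genome, exon_ext, intron_ext)
    truth = SimulationTruth(
        seed=seed,
        background_rate=background_rate,
        planted_motif_id=planted_motif_id,
        target_label=target_label,
        rate_multiplier=rate_multiplier,
        realized_counts=realized,
        background_pool_size=len(pool_exons),
        regulated_event_ids=[ev.event_id for ev in events],
        background_exon_keys=[
            f"{e.contig}:{e.start}-{e.end}({e.strand})" for e in background
        ],
    )
    return EnrichmentDataset(
        genome, ann, events, background, reg_regions, bg_regions, catalog, truth
    )


@dataclass(frozen=True)
class SiteSpec:
    """One designated splice site for the efficiency simulator."""

    site_id: str
    contig: str
    pos: int
    strand: str
    kind: str
    intron: tuple[int, int]


def make_splice_site_annotation(
    n_sites: int = 500,
    exon_len: int = 150,
    intron_len: int = 200,
    spacer: int = 100,
    contig: str = "chr1",
) -> tuple[AnnotationSet, list[SiteSpec], dict[str, int]]:
    """Two-exon genes, one designated splice site per intron.

    Designated kinds alternate 5'ss / 3'ss so both kinds are represented;
    the companion boundary of each intron is deliberately not a designated
    site (its counts are a side effect of shared spliced reads).
    """
    exons, sites = [], []
    unit = 2 * exon_len + intron_len
    for j in range(n_sites):
        gene = f"s{j:05d}"
        tid = f"{gene}.t1"
        gstart = spacer + j * (unit + spacer)
        e1 = (gstart, gstart + exon_len)
        e2 = (gstart + exon_len + intron_len, gstart + unit)
        exons.append(ExonRecord(contig, e1[0], e1[1], "+", gene, tid))
        exons.append(ExonRecord(contig, e2[0], e2[1], "+", gene, tid))
        intron = (e1[1], e2[0])
        if j % 2 == 0:
            pos, kind = intron[0], "5ss"
        else:
            pos, kind = intron[1], "3ss"
        sid = f"{contig}:{pos}:+:{kind}"
        sites.append(SiteSpec(sid, contig, pos, "+", kind, intron))
    total_len = spacer + n_sites * (unit + spacer)
    return AnnotationSet(exons), sites, {contig: total_len}


def simulate_splice_site_reads(
    sites: list[SiteSpec],
    theta_true,
    contig_lengths: dict[str, int],
    depth: int = 200,
    read_len: int = 100,
    k: int = 6,
    seed: int = 0,
) -> tuple[str, dict]:
    """SAM text mixing gapped and contiguous reads at true efficiency θ.

    Per site, spliced reads (gap exactly the site's intron) number
    Binomial(depth, θ) and the remainder are contiguous reads centred on
    the boundary. Returns (SAM text, site id -> true θ).
    """
    if read_len < 2 * k:
        raise SpliceMotifsError(f"read_len {read_len} < 2k = {2 * k}")
    theta = np.broadcast_to(np.asarray(theta_true, dtype=float), (len(sites),))
    if np.any((theta < 0) | (theta > 1)):
        raise SpliceMotifsError("true efficiency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for contig, ln in contig_lengths.items():
        lines.append(f"@SQ\tSN:{contig}\tLN:{ln}")
    half = read_len // 2
    truth = {}
    for site, th in zip(sites, theta):
        truth[site.site_id] = float(th)
        n_spliced = int(rng.binomial(depth, th))
        istart, iend = site.intron
        gap_cigar = f"{half}M{iend - istart}N{half}M"
        for r in range(n_spliced):
            pos1 = istart - half + 1  # SAM is 1-based
            lines.append(
                f"{site.site_id}/spl{r}\t0\t{site.contig}\t{pos1}\t60\t{gap_cigar}\t*\t0\t0\t*\t*"
            )
        for r in range(depth - n_spliced):
            pos1 = site.pos - half + 1
            lines.append(
                f"{site.site_id}/uns{r}\t0\t{site.contig}\t{pos1}\t60\t{read_len}M\t*\t0\t0\t*\t*"
            )
    return "\n".join(lines) + "\n", truth
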