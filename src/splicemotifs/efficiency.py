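"""Per-splice-site splicing efficiency from gapped alignments.

For every annotated intron boundary, reads are classified as *spliced*
(the alignment gap matches the intron coordinates exactly; such a read
supports both boundaries of that intron) or *unspliced* (the read is
aligned contiguously across the boundary with at least ``k`` aligned nt on
each side). Splicing efficiency at a site is then

    θ = n_spliced / (n_spliced + n_unspliced)

with sites below a minimum informative coverage excluded. Group
comparisons use a paired Wilcoxon signed-rank test per site kind (5'ss and
3'ss separately).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .genome import AnnotationSet


@dataclass
class SpliceSiteCounts:
    """Spliced/unspliced read support at one exon–intron boundary."""

    site_id: str
    contig: str
    pos: int
    strand: str
    kind: str  # "5ss" (donor) or "3ss" (acceptor)
    n_spliced: int = 0
    n_unspliced: int = 0


def site_id(contig: str, pos: int, strand: str, kind: str) -> str:
    return f"{contig}:{pos}:{strand}:{kind}"


def annotation_splice_sites(
    ann: AnnotationSet,
) -> tuple[dict, dict]:
    """Derive splice sites from introns between adjacent exons.

    Returns ``(by_intron, by_pos)``: intron coordinates -> site ids, and
    (contig, pos) -> site ids, with one :class:`SpliceSiteCounts` per
    unique site shared through both indexes.
    """
    sites: dict[str, SpliceSiteCounts] = {}
    by_intron: dict[tuple, list[SpliceSiteCounts]] = defaultdict(list)
    by_pos: dict[tuple, list[SpliceSiteCounts]] = defaultdict(list)
    for contig, istart, iend, strand, _tid in ann.introns():
        if strand == "+":
            pairs = [(istart, "5ss"), (iend, "3ss")]
        else:
            pairs = [(iend, "5ss"), (istart, "3ss")]
        intron_sites = []
        for pos, kind in pairs:
            sid = site_id(contig, pos, strand, kind)
            if sid not in sites:
                site = SpliceSiteCounts(sid, contig, pos, strand, kind)
                sites[sid] = site
                by_pos[(contig, pos)].append(site)
            intron_sites.append(sites[sid])
        key = (contig, istart, iend)
        for s in intron_sites:
            if s not in by_intron[key]:
                by_intron[key].append(s)
    return dict(by_intron), dict(by_pos)


def _walk_cigar(read) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Aligned blocks (M/=/X runs, merged across insertions) and N gaps."""
    blocks, gaps = [], []
    ref = read.reference_start
    cur_start = None
    for op, ln in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            if cur_start is None:
                cur_start = ref
            ref += ln
        elif op == 1 or op == 4 or op == 5:  # I, S, H: no reference advance
            continue
        elif op == 2:  # D: advances reference but breaks contiguity
            if cur_start is not None:
                blocks.append((cur_start, ref))
                cur_start = None
            ref += ln
        elif op == 3:  # N: splice gap
            if cur_start is not None:
                blocks.append((cur_start, ref))
                cur_start = None
            gaps.append((ref, ref + ln))
            ref += ln
        else:  # P and friends: ignore
            continue
    if cur_start is not None:
        blocks.append((cur_start, ref))
    return blocks, gaps


def count_splice_site_reads(
    alignments: str | Path,
    ann: AnnotationSet,
    k: int = 6,
) -> list[SpliceSiteCounts]:
    """Count spliced/unspliced reads at every annotated splice site.

    ``alignments`` is a SAM/BAM path. A read's gap must equal an annotated
    intron exactly (both coordinates) to count as spliced; it then
    supports both boundary sites of that intron. A read counts as
    unspliced at a site when one contiguous aligned block covers
    [pos − k, pos + k). Multi-gap reads contribute each gap independently.
    Unmapped and gapless-degenerate records are skipped (counted).
    """
    by_intron, by_pos = annotation_splice_sites(ann)
    # sorted boundary positions per contig for fast block -> site lookup
    pos_per_contig: dict[str, np.ndarray] = {}
    for (contig, pos) in by_pos:
        pos_per_contig.setdefault(contig, []).append(pos)
    pos_per_contig = {c: np.sort(np.array(v)) for c, v in pos_per_contig.items()}

    n_skipped = 0
    with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or not read.cigartuples:
                n_skipped += 1
                continue
            contig = read.reference_name
            blocks, gaps = _walk_cigar(read)
            if not blocks and not gaps:
                n_skipped += 1
                continue
            for gap in gaps:
                for site in by_intron.get((contig, gap[0], gap[1]), ()):
                    site.n_spliced += 1
            positions = pos_per_contig.get(contig)
            if positions is None:
                continue
            for bs, be in blocks:
                lo = np.searchsorted(positions, bs + k, side="left")
                hi = np.searchsorted(positions, be - k, side="right")
                for p in positions[lo:hi]:
                    for site in by_pos[(contig, int(p))]:
                        site.n_unspliced += 1
    sites = [s for sites_ in by_pos.values() for s in sites_]
    return sorted(sites, key=lambda s: (s.contig, s.pos, s.kind))


@dataclass
class EfficiencyResult:
    """θ estimate at one site, with the coverage gate applied."""

    site_id: str
    kind: str
    theta: float
    total: int
    included: bool


def compute_efficiency(
    counts: SpliceSiteCounts, min_total: int = 10
) -> EfficiencyResult:
    total = counts.n_spliced + counts.n_unspliced
    theta = counts.n_spliced / total if total > 0 else math.nan
    return EfficiencyResult(
        site_id=counts.site_id,
        kind=counts.kind,
        theta=theta,
        total=total,
        included=total >= min_total,
    )


def compute_efficiencies(
    counts: list[SpliceSiteCounts], min_total: int = 10
) -> list[EfficiencyResult]:
    return [compute_efficiency(c, min_total) for c in counts]


def efficiency_table(results: list[EfficiencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "kind": r.kind,
                "theta": r.theta,
                "total": r.total,
                "included": r.included,
            }
            for r in results
        ],
        columns=["site_id", "kind", "theta", "total", "included"],
    )


def compare_efficiency(
    group_a: list[EfficiencyResult],
    group_b: list[EfficiencyResult],
    min_sites: int = 10,
) -> dict[str, dict]:
    """Per-kind paired comparison of θ between two groups.

    Sites are matched by site id; only sites included in both groups are
    used. Δθ = θ(b) − θ(a). With fewer than ``min_sites`` matched sites a
    summary without a test is returned (p = NaN); otherwise a paired
    Wilcoxon signed-rank test is run per kind.
    """
    index_a = {r.site_id: r for r in group_a if r.included}
    out: dict[str, dict] = {}
    for kind in ("5ss", "3ss"):
        deltas = []
        for rb in group_b:
            ra = index_a.get(rb.site_id)
            if rb.included and ra is not None and ra.kind == kind:
                deltas.append(rb.theta - ra.theta)
        deltas = np.array(deltas, dtype=float)
        summary = {
            "n_sites": int(deltas.size),
            "median_delta": float(np.median(deltas)) if deltas.size else math.nan,
            "mean_delta": float(np.mean(deltas)) if deltas.size else math.nan,
            "pvalue": math.nan,
        }
        if deltas.size >= min_sites and np.any(deltas != 0):
            summary["pvalue"] = float(stats.wilcoxon(deltas).pvalue)
        out[kind] = summary
    return out
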