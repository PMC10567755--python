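"""Skipped-exon (cassette) events: PSI, ΔPSI, DAS filtering and contrasts.

PSI (percent spliced in) is estimated per sample from inclusion- and
skip-junction read counts with rMATS-style effective-length normalization:

    PSI = (I / L_I) / (I / L_I + S / L_S)

ΔPSI is the difference of group-mean PSI, group 2 minus group 1
(treatment minus control). The differential-splicing filter retains events
with |ΔPSI| > 0.1 and adjusted p < 0.05 (both strict).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EventTableError

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")


def compute_psi(inc: int, skip: int, inc_len: float, skip_len: float) -> float:
    """Length-normalized percent spliced in; NaN when I + S == 0."""
    if inc < 0 or skip < 0:
        raise EventTableError("negative junction counts")
    if inc_len <= 0 or skip_len <= 0:
        raise EventTableError("effective lengths must be positive")
    if inc + skip == 0:
        return math.nan
    ni = inc / inc_len
    ns = skip / skip_len
    return ni / (ni + ns)


@dataclass
class SEEvent:
    """One skipped-exon event with per-sample junction counts.

    Exon intervals are 0-based half-open genomic coordinates; ``upstream``
    and ``downstream`` are the flanking constitutive exons in *transcript*
    orientation (upstream = 5' of the cassette on the RNA).
    """

    event_id: str
    gene_id: str
    contig: str
    strand: str
    cassette: tuple[int, int]
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    ijc1: list[int] = field(default_factory=list)
    sjc1: list[int] = field(default_factory=list)
    ijc2: list[int] = field(default_factory=list)
    sjc2: list[int] = field(default_factory=list)
    inc_len: float = 1.0
    skip_len: float = 1.0
    groups: tuple[str, str] = ("group1", "group2")
    dpsi: float = math.nan
    pvalue: float = math.nan
    padj: float = math.nan
    event_type: str = "SE"

    def psi_samples(self, group: int) -> list[float]:
        inc = self.ijc1 if group == 1 else self.ijc2
        skip = self.sjc1 if group == 1 else self.sjc2
        return [
            compute_psi(i, s, self.inc_len, self.skip_len)
            for i, s in zip(inc, skip)
        ]

    def psi_mean(self, group: int) -> float:
        vals = [p for p in self.psi_samples(group) if not math.isnan(p)]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def match_key(self) -> tuple:
        return (self.gene_id, self.contig, self.cassette, self.strand)


_RMATS_COLS = [
    "ID", "GeneID", "chr", "strand",
    "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen", "PValue", "FDR", "IncLevelDifference",
]


def _split_counts(text, col: str, row: int) -> list[int]:
    try:
        return [int(x) for x in str(text).split(",") if x != ""]
    except ValueError as exc:
        raise EventTableError(
            f"row {row}: non-numeric counts in column {col!r}: {text!r}"
        ) from exc


def read_rmats_se(path: str | Path) -> list[SEEvent]:
    """Read an rMATS-dialect skipped-exon table (tab-delimited, header).

    Comma-separated IJC/SJC lists become per-sample counts. The
    IncLevelDifference column is taken as written and interpreted as mean
    PSI(group 2) − mean PSI(group 1); FDR is the adjusted p-value.
    """
    path = Path(path)
    if not path.exists():
        raise EventTableError(f"event table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _RMATS_COLS if c not in df.columns]
    if missing:
        raise EventTableError(f"event table missing required column(s): {missing}")
    events = []
    for i, row in enumerate(df.itertuples(), 1):
        try:
            cassette = (int(row.exonStart_0base), int(row.exonEnd))
            upstream = (int(row.upstreamES), int(row.upstreamEE))
            downstream = (int(row.downstreamES), int(row.downstreamEE))
            inc_len = float(row.IncFormLen)
            skip_len = float(row.SkipFormLen)
        except ValueError as exc:
            raise EventTableError(f"row {i}: non-numeric coordinate field") from exc

        def _f(x):
            return float(x) if str(x) not in ("nan", "NA", "", "None") else math.nan

        events.append(
            SEEvent(
                event_id=str(row.ID),
                gene_id=str(row.GeneID),
                contig=str(getattr(row, "chr")),
                strand=str(row.strand),
                cassette=cassette,
                upstream=upstream,
                downstream=downstream,
                ijc1=_split_counts(row.IJC_SAMPLE_1, "IJC_SAMPLE_1", i),
                sjc1=_split_counts(row.SJC_SAMPLE_1, "SJC_SAMPLE_1", i),
                ijc2=_split_counts(row.IJC_SAMPLE_2, "IJC_SAMPLE_2", i),
                sjc2=_split_counts(row.SJC_SAMPLE_2, "SJC_SAMPLE_2", i),
                inc_len=inc_len,
                skip_len=skip_len,
                dpsi=_f(row.IncLevelDifference),
                pvalue=_f(row.PValue),
                padj=_f(row.FDR),
            )
        )
    return events


def write_rmats_se(events: list[SEEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "ID": ev.event_id,
                "GeneID": ev.gene_id,
                "chr": ev.contig,
                "strand": ev.strand,
                "exonStart_0base": ev.cassette[0],
                "exonEnd": ev.cassette[1],
                "upstreamES": ev.upstream[0],
                "upstreamEE": ev.upstream[1],
                "downstreamES": ev.downstream[0],
                "downstreamEE": ev.downstream[1],
                "IJC_SAMPLE_1": ",".join(map(str, ev.ijc1)),
                "SJC_SAMPLE_1": ",".join(map(str, ev.sjc1)),
                "IJC_SAMPLE_2": ",".join(map(str, ev.ijc2)),
                "SJC_SAMPLE_2": ",".join(map(str, ev.sjc2)),
                "IncFormLen": ev.inc_len,
                "SkipFormLen": ev.skip_len,
                "PValue": ev.pvalue,
                "FDR": ev.padj,
                "IncLevelDifference": ev.dpsi,
            }
        )
    pd.DataFrame(rows, columns=_RMATS_COLS).to_csv(path, sep="\t", index=False)


def filter_das(
    events: list[SEEvent], dpsi_min: float = 0.1, padj_max: float = 0.05
) -> list[SEEvent]:
    """Differential-splicing filter: |ΔPSI| > dpsi_min and padj < padj_max.

    Both inequalities are strict. Events with an undefined adjusted p are
    excluded with a warning.
    """
    kept = []
    n_missing = 0
    for ev in events:
        if math.isnan(ev.padj) or math.isnan(ev.dpsi):
            n_missing += 1
            continue
        if abs(ev.dpsi) > dpsi_min and ev.padj < padj_max:
            kept.append(ev)
    if n_missing:
        warnings.warn(
            f"{n_missing} event(s) without ΔPSI/adjusted p excluded from the filter",
            stacklevel=2,
        )
    return kept


@dataclass
class ContrastOverlap:
    """Events shared by two contrasts, with ΔPSI concordance."""

    pairs: list[tuple[SEEvent, SEEvent]]
    pearson_r: float
    n_pairs: int
    type_counts: dict[str, int]


def overlap_contrasts(events_a: list[SEEvent], events_b: list[SEEvent]) -> ContrastOverlap:
    """Match events across contrasts by (gene, cassette interval, strand).

    Pearson r is computed over the matched ΔPSI pairs; fewer than 3 matched
    pairs yields r = NaN.
    """
    index_b = {}
    for ev in events_b:
        index_b.setdefault(ev.match_key, ev)
    pairs = []
    for ev in events_a:
        other = index_b.get(ev.match_key)
        if other is not None:
            pairs.append((ev, other))
    xs = np.array([a.dpsi for a, _ in pairs], dtype=float)
    ys = np.array([b.dpsi for _, b in pairs], dtype=float)
    ok = ~(np.isnan(xs) | np.isnan(ys))
    if ok.sum() >= 3 and np.std(xs[ok]) > 0 and np.std(ys[ok]) > 0:
        r = float(stats.pearsonr(xs[ok], ys[ok]).statistic)
    else:
        r = math.nan
    counts = Counter(a.event_type for a, _ in pairs)
    return ContrastOverlap(pairs, r, len(pairs), dict(counts))


def test_das(i1: int, s1: int, i2: int, s2: int) -> float:
    """Two-sided Fisher exact p on pooled per-group inclusion/skip counts.

    A simple internal test for synthetic data; returns NaN when either
    group has zero total counts.
    """
    if min(i1, s1, i2, s2) < 0:
        raise EventTableError("negative pooled counts")
    if i1 + s1 == 0 or i2 + s2 == 0:
        return math.nan
    return float(stats.fisher_exact([[i1, s1], [i2, s2]]).pvalue)


def assign_das_stats(events: list[SEEvent]) -> list[SEEvent]:
    """Fill ΔPSI, raw p (pooled Fisher) and BH-adjusted p on each event."""
    from .enrichment import bh_adjust  # local import to avoid a cycle

    pvals, idx = [], []
    for ev in events:
        ev.dpsi = ev.psi_mean(2) - ev.psi_mean(1)
        ev.pvalue = test_das(sum(ev.ijc1), sum(ev.sjc1), sum(ev.ijc2), sum(ev.sjc2))
        if not math.isnan(ev.pvalue):
            pvals.append(ev.pvalue)
            idx.append(ev)
    if pvals:
        adj = bh_adjust(np.array(pvals))
        for ev, a in zip(idx, adj):
            ev.padj = float(a)
    return events


def event_type_proportions(events: list[SEEvent]) -> dict[str, float]:
    """Fractions of events per type over {SE, A5SS, A3SS, MXE, RI}."""
    if not events:
        return {}
    counts = Counter(ev.event_type for ev in events)
    total = sum(counts.values())
    return {t: counts.get(t, 0) / total for t in EVENT_TYPES if counts.get(t, 0)}
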