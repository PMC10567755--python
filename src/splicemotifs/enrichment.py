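"""Motif enrichment at splice sites: Fisher tests, BH control, RNA maps.

For every motif × region label, occurrences in the regulated region set are
contrasted against occurrences in the matched background splice-site
regions (donor labels vs background donors, acceptor labels vs background
acceptors) in a 2×2 table:

    a = occurrences in regulated regions
    b = scanned start positions in regulated regions − a
    c = occurrences in background regions
    d = scanned positions in background − c

with scanned positions = Σ max(region length − motif length + 1, 0). A
right-sided Fisher exact test calls enrichment, a left-sided test calls
depletion, and p-values are Benjamini–Hochberg adjusted across motifs
within each region label and side. An optional per-region presence/absence
table model (a = regions containing ≥1 occurrence) is available.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import SpliceMotifsError
from .motifs import (
    MotifCatalog,
    MotifRecord,
    count_matrix,
    encode_sequences,
    match_start_matrix,
    scan_positions,
)
from .regions import LABEL_SIDE, SpliceSiteRegion


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 occurrence-vs-opportunity table (regulated on the top row)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise SpliceMotifsError(f"negative contingency cell in {self}")

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.nan
        return (self.a * self.d) / (self.b * self.c)


def fisher_one_sided(table: ContingencyTable, side: str) -> float:
    """One-sided Fisher exact p conditioning on both table margins.

    ``side='enriched'`` is the right-sided test P(X ≥ a); ``side='depleted'``
    the left-sided test P(X ≤ a), where X is hypergeometric with the
    table's margins.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    total = a + b + c + d
    dist = stats.hypergeom(total, a + c, a + b)
    if side == "enriched":
        p = dist.sf(a - 1)
    elif side == "depleted":
        p = dist.cdf(a)
    else:
        raise SpliceMotifsError(f"unknown test side {side!r}")
    # the exact tail is never 0; guard against float underflow on extreme
    # tables so downstream (0, 1] checks hold
    return float(min(1.0, max(p, np.finfo(float).tiny)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise SpliceMotifsError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Per motif × region outcome of the enrichment/depletion tests."""

    motif_id: str
    rbp: str
    region: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_enriched: float
    p_depleted: float
    padj_enriched: float = math.nan
    padj_depleted: float = math.nan
    call: str = "ns"


def _group_regions(regions: list[SpliceSiteRegion]) -> dict[str, list[str]]:
    grouped: dict[str, list[str]] = defaultdict(list)
    for r in regions:
        grouped[r.label].append(r.sequence)
    return grouped


def run_enrichment(
    regulated: list[SpliceSiteRegion],
    background: list[SpliceSiteRegion],
    catalog: MotifCatalog,
    alpha: float = 0.05,
    table_model: str = "positions",
) -> list[EnrichmentResult]:
    """Fisher enrichment/depletion calls for every motif × region label.

    BH adjustment runs across motifs within each (region label, side)
    family. Motifs longer than every region in a label are omitted with a
    warning. ``table_model='presence'`` switches to a per-region
    presence/absence table.
    """
    if table_model not in ("positions", "presence"):
        raise SpliceMotifsError(f"unknown table model {table_model!r}")
    reg_groups = _group_regions(regulated)
    bg_groups = _group_regions(background)
    # encode each group once; reuse across motifs
    enc = {
        ("reg", lab): encode_sequences(seqs) for lab, seqs in reg_groups.items()
    }
    enc.update(
        {("bg", lab): encode_sequences(seqs) for lab, seqs in bg_groups.items()}
    )

    results: list[EnrichmentResult] = []
    for label in sorted(reg_groups):
        side_label = LABEL_SIDE.get(label)
        if side_label is None or side_label not in bg_groups:
            raise SpliceMotifsError(
                f"no background regions match regulated label {label!r}"
            )
        arr_r, len_r = enc[("reg", label)]
        arr_b, len_b = enc[("bg", side_label)]
        label_results = []
        for motif in catalog:
            m = motif.length
            pos_r = scan_positions(len_r, m)
            pos_b = scan_positions(len_b, m)
            if pos_r == 0 or pos_b == 0:
                warnings.warn(
                    f"motif {motif.motif_id} longer than every region in "
                    f"{label!r}; omitted",
                    stacklevel=2,
                )
                continue
            if table_model == "positions":
                a = int(count_matrix(arr_r, len_r, motif.consensus).sum())
                c = int(count_matrix(arr_b, len_b, motif.consensus).sum())
                table = ContingencyTable(a, pos_r - a, c, pos_b - c)
            else:
                a = int((count_matrix(arr_r, len_r, motif.consensus) > 0).sum())
                c = int((count_matrix(arr_b, len_b, motif.consensus) > 0).sum())
                table = ContingencyTable(
                    a, arr_r.shape[0] - a, c, arr_b.shape[0] - c
                )
            label_results.append(
                EnrichmentResult(
                    motif_id=motif.motif_id,
                    rbp=motif.rbp,
                    region=label,
                    a=table.a,
                    b=table.b,
                    c=table.c,
                    d=table.d,
                    odds_ratio=table.odds_ratio,
                    p_enriched=fisher_one_sided(table, "enriched"),
                    p_depleted=fisher_one_sided(table, "depleted"),
                )
            )
        if label_results:
            adj_e = bh_adjust([r.p_enriched for r in label_results])
            adj_d = bh_adjust([r.p_depleted for r in label_results])
            for r, pe, pd_ in zip(label_results, adj_e, adj_d):
                r.padj_enriched = float(pe)
                r.padj_depleted = float(pd_)
                if r.padj_enriched < alpha:
                    r.call = "enriched"
                elif r.padj_depleted < alpha:
                    r.call = "depleted"
        results.extend(label_results)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "rbp": r.rbp,
                "region": r.region,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p_enr": r.p_enriched,
                "p_dep": r.p_depleted,
                "padj_enr": r.padj_enriched,
                "padj_dep": r.padj_depleted,
                "call": r.call,
            }
            for r in results
        ]
    )
    if not df.empty:
        df = df.sort_values(["region", "motif_id"]).reset_index(drop=True)
    return df


@dataclass
class PositionalProfile:
    """RNA map: motif start frequency by offset from the splice site.

    Offsets are in nt relative to the splice-site boundary; negative
    offsets lie 5' of the site on the RNA (exonic for donors, intronic for
    acceptors).
    """

    motif_id: str
    region: str
    offsets: np.ndarray
    frequency: np.ndarray
    n_regions: int


def positional_profile(
    motif: MotifRecord, regions: list[SpliceSiteRegion]
) -> PositionalProfile:
    """Start-position frequencies of one motif across same-label regions.

    Only full-window (unclipped, untruncated) regions enter the profile so
    all offsets are defined for every region.
    """
    if not regions:
        raise SpliceMotifsError("empty region set for positional profile")
    labels = {r.label for r in regions}
    if len(labels) > 1:
        raise SpliceMotifsError(f"mixed region labels in profile: {sorted(labels)}")
    full = [r for r in regions if not (r.clipped or r.truncated)]
    if not full:
        raise SpliceMotifsError("no full-window regions for positional profile")
    window = {(r.length, r.boundary_offset) for r in full}
    if len(window) > 1:
        raise SpliceMotifsError("regions share a label but not window parameters")
    (length, boundary) = window.pop()
    arr, lens = encode_sequences([r.sequence for r in full])
    hits = match_start_matrix(arr, lens, motif.consensus)
    freq = hits.mean(axis=0) if hits.shape[1] else np.zeros(0)
    offsets = np.arange(hits.shape[1]) - boundary
    return PositionalProfile(
        motif_id=motif.motif_id,
        region=next(iter(labels)),
        offsets=offsets,
        frequency=freq,
        n_regions=len(full),
    )


def profile_table(profiles: list[PositionalProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for off, f in zip(p.offsets, p.frequency):
            rows.append(
                {
                    "motif_id": p.motif_id,
                    "region": p.region,
                    "offset": int(off),
                    "frequency": float(f),
                }
            )
    return pd.DataFrame(rows, columns=["motif_id", "region", "offset", "frequency"])
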