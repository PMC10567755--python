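"""RBP motif catalogs and degenerate-consensus scanning.

Motifs are short IUPAC RNA consensus strings (ATtRACT-style catalog rows).
Scanning is exact degenerate matching on the sense strand only — RBPs bind
the RNA, so the antisense strand is never scanned — with every overlapping
occurrence counted. An N in the *sequence* never matches any consensus
position, while N in the *consensus* matches any of A/C/G/T.

Two scan paths are provided: a per-sequence regex scan
(:func:`count_occurrences`) and a vectorized numpy scan over many regions
(:func:`match_start_matrix` / :func:`count_matrix`) used by the enrichment
stage; they implement identical semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MotifError

# IUPAC codes -> the set of concrete DNA bases they stand for. The sequence
# side is restricted to A/C/G/T; anything else (N, degenerate codes) in the
# sequence matches nothing.
IUPAC_CLASSES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# byte-code encoding: A/C/G/T -> 0..3, everything else -> 4 (unmatched)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# per-IUPAC-letter boolean lookup over the 5 sequence codes
_CLASS_LUT: dict[str, np.ndarray] = {}
for _code, _bases in IUPAC_CLASSES.items():
    lut = np.zeros(5, dtype=bool)
    for _b in _bases:
        lut["ACGT".index(_b)] = True
    _CLASS_LUT[_code] = lut


def normalize_consensus(consensus: str) -> str:
    """Uppercase, RNA->DNA (U->T), and validate against the IUPAC alphabet."""
    cons = consensus.strip().upper().replace("U", "T")
    bad = set(cons) - set(IUPAC_CLASSES)
    if bad or not cons:
        raise MotifError(
            f"non-IUPAC character(s) {sorted(bad)} in consensus {consensus!r}"
        )
    return cons


@dataclass(frozen=True)
class MotifRecord:
    """One catalog row: an RBP and one of its consensus binding motifs."""

    rbp: str
    motif_id: str
    consensus: str  # stored DNA-normalized (T, not U)
    organism: str = ""
    score: str = ""

    def __post_init__(self):
        cons = normalize_consensus(self.consensus)
        object.__setattr__(self, "consensus", cons)
        if len(cons) < 3:
            raise MotifError(
                f"motif {self.motif_id!r}: consensus shorter than 3 nt"
            )

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class MotifCatalog:
    """A set of motifs with unique ids, optionally organism-filtered."""

    motifs: list[MotifRecord]
    organism: str | None = None
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_id = {}
        for m in self.motifs:
            if m.motif_id in self._by_id:
                raise MotifError(f"duplicate motif id {m.motif_id!r}")
            self._by_id[m.motif_id] = m

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def get(self, motif_id: str) -> MotifRecord:
        if motif_id not in self._by_id:
            raise MotifError(f"unknown motif id {motif_id!r}")
        return self._by_id[motif_id]

    def by_rbp(self, rbp: str) -> list[MotifRecord]:
        return [m for m in self.motifs if m.rbp == rbp]


_REQUIRED_COLS = ["Gene_name", "Motif", "Organism", "Matrix_id", "Len"]


def read_attract(path: str | Path, organism: str) -> MotifCatalog:
    """Read an ATtRACT-style tab-delimited motif catalog.

    Rows are filtered to ``organism``; U and T are equivalent on read.
    """
    path = Path(path)
    if not path.exists():
        raise MotifError(f"motif catalog not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise MotifError(f"motif catalog missing required column(s): {missing}")
    sub = df[df["Organism"] == organism]
    if sub.empty:
        raise MotifError(
            f"no motifs for organism {organism!r} in {path} "
            f"(organisms present: {sorted(df['Organism'].unique())})"
        )
    motifs = [
        MotifRecord(
            rbp=row.Gene_name,
            motif_id=row.Matrix_id,
            consensus=row.Motif,
            organism=row.Organism,
            score=getattr(row, "Score", "") or "",
        )
        for row in sub.itertuples()
    ]
    return MotifCatalog(motifs, organism=organism)


def write_attract(catalog: MotifCatalog, path: str | Path) -> None:
    """Write a catalog back out in the ATtRACT dialect (RNA alphabet)."""
    rows = [
        {
            "Gene_name": m.rbp,
            "Motif": m.consensus.replace("T", "U"),
            "Organism": m.organism,
            "Matrix_id": m.motif_id,
            "Len": m.length,
            "Score": m.score,
        }
        for m in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _consensus_regex(consensus: str) -> re.Pattern:
    cons = normalize_consensus(consensus)
    body = "".join(f"[{IUPAC_CLASSES[c]}]" for c in cons)
    # lookahead so overlapping occurrences are all counted
    return re.compile(f"(?={body})")


def iupac_match(consensus: str, window: str) -> bool:
    """True iff ``window`` matches ``consensus`` position by position."""
    cons = normalize_consensus(consensus)
    win = window.upper().replace("U", "T")
    if len(win) != len(cons):
        raise MotifError(
            f"window length {len(win)} != consensus length {len(cons)}"
        )
    return all(b in IUPAC_CLASSES[c] for c, b in zip(cons, win))


def count_occurrences(sequence: str, consensus: str) -> int:
    """Number of (overlapping) consensus matches on the sense strand."""
    seq = sequence.upper().replace("U", "T")
    cons = normalize_consensus(consensus)
    if len(seq) < len(cons):
        return 0
    return sum(1 for _ in _consensus_regex(cons).finditer(seq))


def match_starts(sequence: str, consensus: str) -> list[int]:
    """Start offsets of every (overlapping) match on the sense strand."""
    seq = sequence.upper().replace("U", "T")
    cons = normalize_consensus(consensus)
    return [m.start() for m in _consensus_regex(cons).finditer(seq)]


def encode_sequences(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into a padded (n, max_len) uint8 matrix.

    Codes: A/C/G/T -> 0..3; any other character (including N and padding)
    -> 4, which no consensus position matches.
    """
    n = len(sequences)
    max_len = max((len(s) for s in sequences), default=0)
    arr = np.full((n, max_len), 4, dtype=np.uint8)
    lengths = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(sequences):
        b = np.frombuffer(s.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)
        arr[i, : len(b)] = _ENCODE[b]
        lengths[i] = len(b)
    return arr, lengths


def match_start_matrix(
    encoded: np.ndarray, lengths: np.ndarray, consensus: str
) -> np.ndarray:
    """Boolean (n, max_len - m + 1) matrix of match starts per sequence.

    Padding beyond each sequence's length can never match because padding
    codes to 4.
    """
    cons = normalize_consensus(consensus)
    m = len(cons)
    n, width = encoded.shape
    if width < m:
        return np.zeros((n, 0), dtype=bool)
    w = width - m + 1
    hits = np.ones((n, w), dtype=bool)
    for k, c in enumerate(cons):
        hits &= _CLASS_LUT[c][encoded[:, k : k + w]]
    return hits


def count_matrix(
    encoded: np.ndarray, lengths: np.ndarray, consensus: str
) -> np.ndarray:
    """Per-sequence occurrence counts (overlapping, sense strand)."""
    return match_start_matrix(encoded, lengths, consensus).sum(axis=1)


def scan_positions(lengths: np.ndarray, motif_len: int) -> int:
    """Total scanned start positions: sum of max(len - m + 1, 0)."""
    return int(np.maximum(lengths - motif_len + 1, 0).sum())
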