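"""Degenerate gapped RBP-motif scanning and window-restricted enrichment.

Patterns are ordered IUPAC parts separated by bounded N-gaps, written in a
compact syntax: ``YGCY`` (single part), ``YGCY(N)0-5YGCY`` (two parts with a
0-5 nt gap), ``TGCT(N)3TGCT(N)13-18TGC[TC]`` (fixed gap of 3, bounded gap of
13-18, trailing single-position alternative).  Scanning is on the sense
strand of normalized DNA (U -> T); Y = {C, T}.

Field motifs used throughout: the MBNL high-affinity elements YGCY /
YGCY(N)0-5YGCY and the RBFOX element GCAYG.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import pandas as pd

from .enrich import ContingencyTable2x2, EnrichmentResult, fisher_or, _result
from .events import GeneSet, SpliceEvent

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC.items() if k != "U"}

# canonical pattern strings
MBNL_YGCY = "YGCY"
MBNL_GAPPED = "YGCY(N)0-5YGCY"
RBFOX_GCAYG = "GCAYG"
ANK2_TRIPARTITE = "TGCT(N)3TGCT(N)13-18TGC[TC]"


@dataclass(frozen=True)
class MotifPattern:
    """Ordered IUPAC parts with bounded gaps between consecutive parts."""

    parts: tuple[str, ...]
    gaps: tuple[tuple[int, int], ...]
    spec: str = ""

    def __post_init__(self) -> None:
        if len(self.parts) < 1:
            raise ValueError("pattern needs at least one part")
        if len(self.gaps) != len(self.parts) - 1:
            raise ValueError("need exactly len(parts)-1 gaps")
        for lo, hi in self.gaps:
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid gap bounds ({lo}, {hi})")

    @property
    def min_span(self) -> int:
        return sum(map(len, self.parts)) + sum(lo for lo, _ in self.gaps)

    @property
    def max_span(self) -> int:
        return sum(map(len, self.parts)) + sum(hi for _, hi in self.gaps)


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    start: int
    end: int  # 0-based half-open in the scanned sequence
    part_starts: tuple[int, ...]


_GAP_RE = re.compile(r"\(N\)(\d+)(?:[-–](\d+))?")
_ALT_RE = re.compile(r"\[([A-Za-z]+)\]")


def compile_pattern(spec: str) -> MotifPattern:
    """Parse a pattern spec string into a :class:`MotifPattern`.

    ``(N)k`` is a fixed gap (k, k); ``(N)a-b`` a bounded gap; ``[XY]``
    a single-position alternative folded into an IUPAC code.
    """
    s = spec.strip().upper()
    parts: list[str] = []
    gaps: list[tuple[int, int]] = []
    cur: list[str] = []
    i = 0
    while i < len(s):
        if s[i] == "(":
            m = _GAP_RE.match(s, i)
            if not m:
                raise ValueError(f"pattern {spec!r}: malformed gap at column {i + 1}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if lo > hi:
                raise ValueError(f"pattern {spec!r}: gap min > max at column {i + 1}")
            if not cur:
                raise ValueError(f"pattern {spec!r}: gap with no preceding part at column {i + 1}")
            parts.append("".join(cur))
            cur = []
            gaps.append((lo, hi))
            i = m.end()
        elif s[i] == "[":
            m = _ALT_RE.match(s, i)
            if not m:
                raise ValueError(f"pattern {spec!r}: malformed alternative at column {i + 1}")
            letters = frozenset()
            for ch in m.group(1):
                if ch not in IUPAC:
                    raise ValueError(f"pattern {spec!r}: unknown letter {ch!r} at column {i + 1}")
                letters |= IUPAC[ch]
            cur.append(_SET_TO_CODE[letters])
            i = m.end()
        elif s[i] in IUPAC:
            cur.append("T" if s[i] == "U" else s[i])
            i += 1
        else:
            raise ValueError(f"pattern {spec!r}: unexpected character {s[i]!r} at column {i + 1}")
    if not cur:
        raise ValueError(f"pattern {spec!r}: trailing gap with no final part")
    parts.append("".join(cur))
    return MotifPattern(tuple(parts), tuple(gaps), spec=spec)


def _part_positions(seq: str, part: str) -> set[int]:
    n, m = len(seq), len(part)
    allowed = [IUPAC[c] for c in part]
    return {
        i
        for i in range(n - m + 1)
        if all(seq[i + j] in allowed[j] for j in range(m))
    }


def scan(sequence: str, pattern: MotifPattern, pattern_id: Optional[str] = None) -> list[MotifHit]:
    """All matches of ``pattern`` in ``sequence``, one hit per distinct start.

    When several gap choices share a start, the smallest total span is
    reported.  Overlapping hits are allowed.
    """
    seq = sequence.upper().replace("U", "T")
    pid = pattern_id if pattern_id is not None else (pattern.spec or "/".join(pattern.parts))
    pos = [_part_positions(seq, p) for p in pattern.parts]
    plens = [len(p) for p in pattern.parts]

    def best_chain(idx: int, start: int) -> Optional[tuple[int, ...]]:
        # minimal-end chain of part starts from part idx placed at `start`
        if idx == len(pattern.parts) - 1:
            return (start,)
        prev_end = start + plens[idx]
        lo, hi = pattern.gaps[idx]
        for s2 in range(prev_end + lo, prev_end + hi + 1):
            if s2 in pos[idx + 1]:
                rest = best_chain(idx + 1, s2)
                if rest is not None:
                    return (start,) + rest
        return None

    hits = []
    for start in sorted(pos[0]):
        chain = best_chain(0, start)
        if chain is not None:
            end = chain[-1] + plens[-1]
            hits.append(MotifHit(pid, start, end, chain))
    return hits


@dataclass(frozen=True)
class WindowAssignment:
    event_id: str
    has_hit_within_window: bool
    min_distance: Optional[int]  # nt from exon boundary; 0 if a hit overlaps the exon


def assign_window(
    event: SpliceEvent,
    hits: Sequence[MotifHit],
    motif_window: int,
    scan_region: tuple[int, int],
) -> WindowAssignment:
    """Distance from the exon to the nearest hit, and the within-window flag.

    ``scan_region`` is the genomic interval whose (sense-strand) sequence was
    scanned; hit coordinates are local to that region.  Minus-strand regions
    are assumed reverse-complemented, so local coordinates are mirrored.
    """
    rs, re_ = scan_region
    if rs > event.exon_start or re_ < event.exon_end:
        raise ValueError(f"{event.event_id}: scan_region does not cover the exon")
    if event.strand == "+":
        ex_lo = event.exon_start - rs
    else:
        ex_lo = re_ - event.exon_end
    ex_hi = ex_lo + event.exon_length
    best: Optional[int] = None
    for h in hits:
        if h.start < ex_hi and h.end > ex_lo:
            d = 0
        elif h.end <= ex_lo:
            d = ex_lo - h.end
        else:
            d = h.start - ex_hi
        best = d if best is None else min(best, d)
    return WindowAssignment(event.event_id, best is not None and best <= motif_window, best)


def assignments_frame(assignments: Iterable[WindowAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": a.event_id,
                "has_hit_within_window": a.has_hit_within_window,
                "min_distance": a.min_distance,
            }
            for a in assignments
        ],
        columns=["event_id", "has_hit_within_window", "min_distance"],
    )


def motif_enrichment(
    differential: pd.DataFrame,
    assignments: pd.DataFrame,
    gene_set: GeneSet,
    mode: str = "event",
) -> EnrichmentResult:
    """Motif-proximity enrichment among mis-spliced SE events.

    ``event`` mode: over mis-spliced SE events, gene-set membership x
    has-a-motif-within-window.  ``gene`` mode: over genes owning >= 1
    mis-spliced SE event, membership x gene-has-a-proximal-motif.
    """
    se_called = differential[
        (differential["event_type"] == "SE") & differential["is_missplicing"].astype(bool)
    ]
    merged = se_called.merge(assignments, on="event_id", how="left")
    if merged["has_hit_within_window"].isna().any():
        missing = merged.loc[merged["has_hit_within_window"].isna(), "event_id"].tolist()
        raise ValueError(f"assignments missing for mis-spliced SE events: {missing[:5]}")
    if mode == "event":
        in_set = merged["gene_id"].isin(gene_set.gene_ids)
        hit = merged["has_hit_within_window"].astype(bool)
        a = int((in_set & hit).sum())
        b = int((in_set & ~hit).sum())
        c = int((~in_set & hit).sum())
        d = int((~in_set & ~hit).sum())
    elif mode == "gene":
        per_gene = merged.groupby("gene_id")["has_hit_within_window"].any()
        genes = per_gene.index
        in_set = genes.isin(gene_set.gene_ids)
        hit = per_gene.to_numpy(dtype=bool)
        a = int((in_set & hit).sum())
        b = int((in_set & ~hit).sum())
        c = int((~in_set & hit).sum())
        d = int((~in_set & ~hit).sum())
    else:
        raise ValueError(f"unknown motif enrichment mode {mode!r}")
    return _result(gene_set.name, a, b, c, d)


def clip_support(
    event: SpliceEvent,
    clip_intervals: Sequence[tuple[str, int, int]],
    motif_window: int = 250,
) -> tuple[bool, list[tuple[str, int, int]]]:
    """True if any CLIP cluster interval intersects the event's scan region
    (exon +/- ``motif_window``); returns the matching intervals too."""
    lo = event.exon_start - motif_window
    hi = event.exon_end + motif_window
    matched = []
    for chrom, start, end in clip_intervals:
        if end <= start:
            raise ValueError(f"malformed CLIP interval {chrom}:{start}-{end}")
        if chrom == event.chrom and start < hi and end > lo:
            matched.append((chrom, start, end))
    return bool(matched), matched
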