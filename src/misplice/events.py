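"""Domain model for alternative-splicing events, gene sets and sample designs.

Coordinates are 0-based half-open throughout (BED convention), so the length
of the alternative segment is simply ``exon_end - exon_start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd


class EventType(str, Enum):
    """The five alternative-splicing event classes.

    SE: skipped (cassette) exon; MXE: mutually exclusive exons;
    A5SS/A3SS: alternative 5'/3' splice site; RI: retained intron.
    """

    SE = "SE"
    MXE = "MXE"
    A5SS = "A5SS"
    A3SS = "A3SS"
    RI = "RI"


#: Effective lengths under the junction-count-only model: number of distinct
#: informative junctions supporting inclusion (lI) and skipping (lS).
EFFECTIVE_JUNCTIONS: dict[EventType, tuple[int, int]] = {
    EventType.SE: (2, 1),
    EventType.MXE: (2, 2),
    EventType.A5SS: (1, 1),
    EventType.A3SS: (1, 1),
    EventType.RI: (2, 1),
}


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    ``exon_start``/``exon_end`` delimit the alternative segment (cassette
    exon for SE/MXE, the alternative extension for A5SS/A3SS, the retained
    intron for RI).  Flank coordinates delimit the constitutive anchor exons.
    """

    event_id: str
    gene_id: str
    event_type: EventType
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    flank_up_start: int
    flank_up_end: int
    flank_down_start: int
    flank_down_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.event_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exon_start < self.exon_end:
            raise ValueError(
                f"{self.event_id}: exon_start ({self.exon_start}) must be < exon_end ({self.exon_end})"
            )
        for name, (s, e) in (
            ("flank_up", (self.flank_up_start, self.flank_up_end)),
            ("flank_down", (self.flank_down_start, self.flank_down_end)),
        ):
            if not s < e:
                raise ValueError(f"{self.event_id}: {name} coordinates must satisfy start < end")
            if s < self.exon_end and e > self.exon_start:
                raise ValueError(f"{self.event_id}: {name} overlaps the alternative segment")

    @property
    def exon_length(self) -> int:
        return self.exon_end - self.exon_start

    @property
    def effective_lengths(self) -> tuple[int, int]:
        """(lI, lS) for this event's type."""
        return EFFECTIVE_JUNCTIONS[self.event_type]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g., an ASD-risk gene list)."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, gene_ids=frozenset(genes))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


DESIGN_COLUMNS = ["sample_id", "group", "repeat_length", "sex", "age"]


def validate_design(design: pd.DataFrame, min_samples_per_group: int = 2) -> pd.DataFrame:
    """Validate a sample design table.

    Requires columns ``sample_id`` and ``group`` (values 'case'/'control');
    optional ``repeat_length`` (CTG units), ``sex``, ``age``.
    """
    for col in ("sample_id", "group"):
        if col not in design.columns:
            raise ValueError(f"design table missing required column {col!r}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in design table")
    bad = set(design["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected 'case'/'control'")
    counts = design["group"].value_counts()
    for grp in ("case", "control"):
        if counts.get(grp, 0) < min_samples_per_group:
            raise ValueError(
                f"min_samples_per_group violated: group {grp!r} has "
                f"{counts.get(grp, 0)} samples, need >= {min_samples_per_group}"
            )
    if "repeat_length" in design.columns:
        rl = design.loc[design["group"] == "case", "repeat_length"]
        if (rl.dropna() <= 0).any():
            raise ValueError("repeat_length must be positive where present")
    return design


def events_to_frame(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": e.event_id,
            "gene_id": e.gene_id,
            "event_type": e.event_type.value,
            "chrom": e.chrom,
            "strand": e.strand,
            "exon_start": e.exon_start,
            "exon_end": e.exon_end,
            "flank_up_start": e.flank_up_start,
            "flank_up_end": e.flank_up_end,
            "flank_down_start": e.flank_down_start,
            "flank_down_end": e.flank_down_end,
            "exon_length": e.exon_length,
        }
        for e in events
    ]
    return pd.DataFrame(rows)
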