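"""Readers and writers for the package's tabular and sequence formats.

All tables are plain TSV.  The event table dialect stores 0-based half-open
coordinates; ``read_events(..., coords="gtf")`` accepts 1-based inclusive
input and converts on read.  FASTA goes through Bio.SeqIO; sequences are
normalized to uppercase DNA (U -> T).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .events import EFFECTIVE_JUNCTIONS, EventType, GeneSet, SpliceEvent, events_to_frame

EVENT_COLUMNS = [
    "event_id",
    "gene_id",
    "event_type",
    "chrom",
    "strand",
    "exon_start",
    "exon_end",
    "flank_up_start",
    "flank_up_end",
    "flank_down_start",
    "flank_down_end",
]

_VALID_NT = set("ACGTN")


def read_events(path: str | Path, coords: str = "bed") -> list[SpliceEvent]:
    """Read an event annotation TSV into validated :class:`SpliceEvent` objects.

    ``coords="bed"`` (default): columns already 0-based half-open.
    ``coords="gtf"``: 1-based inclusive starts are shifted down by one.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"event table {path}: missing column {col!r}")
    if df["event_id"].duplicated().any():
        dup = df.loc[df["event_id"].duplicated(), "event_id"].iloc[0]
        raise ValueError(f"event table {path}: duplicate event_id {dup!r}")
    shift = 1 if coords == "gtf" else 0
    if coords not in ("bed", "gtf"):
        raise ValueError(f"unknown coords dialect {coords!r}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(
                SpliceEvent(
                    event_id=row.event_id,
                    gene_id=row.gene_id,
                    event_type=EventType(row.event_type),
                    chrom=row.chrom,
                    strand=row.strand,
                    exon_start=int(row.exon_start) - shift,
                    exon_end=int(row.exon_end),
                    flank_up_start=int(row.flank_up_start) - shift,
                    flank_up_end=int(row.flank_up_end),
                    flank_down_start=int(row.flank_down_start) - shift,
                    flank_down_end=int(row.flank_down_end),
                )
            )
        except ValueError as exc:
            raise ValueError(f"event table {path}, row {i + 2}: {exc}") from exc
    return events


def import_rmats_se(path: str | Path) -> list[SpliceEvent]:
    """Thin importer for rMATS-style SE tables (ID, GeneID, chr, strand,
    exonStart_0base, exonEnd, upstreamES/EE, downstreamES/EE).

    Only the SE layout is mapped; the native event-table dialect is the
    supported interchange format.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {
        "ID": "event_id",
        "GeneID": "gene_id",
        "chr": "chrom",
        "strand": "strand",
        "exonStart_0base": "exon_start",
        "exonEnd": "exon_end",
        "upstreamES": "flank_up_start",
        "upstreamEE": "flank_up_end",
        "downstreamES": "flank_down_start",
        "downstreamEE": "flank_down_end",
    }
    missing = set(colmap) - set(df.columns)
    if missing:
        raise ValueError(f"rMATS SE table {path}: missing column(s) {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SpliceEvent(
                event_id=str(getattr(row, "ID")),
                gene_id=str(getattr(row, "GeneID")).strip('"'),
                event_type=EventType.SE,
                chrom=str(getattr(row, "chr")),
                strand=getattr(row, "strand"),
                exon_start=int(getattr(row, "exonStart_0base")),
                exon_end=int(getattr(row, "exonEnd")),
                flank_up_start=int(getattr(row, "upstreamES")),
                flank_up_end=int(getattr(row, "upstreamEE")),
                flank_down_start=int(getattr(row, "downstreamES")),
                flank_down_end=int(getattr(row, "downstreamEE")),
            )
        )
    return events


def write_events(events: Iterable[SpliceEvent], path: str | Path) -> None:
    df = events_to_frame(events)[EVENT_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (one set per line: name, description,
    genes, tab-separated) or a one-gene-per-line list named after the file."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
                    raise ValueError(f"{path}:{lineno}: GMT set {fields[0]!r} has no genes")
                genes = {g.strip() for g in fields[2:] if g.strip()}
                sets.append(GeneSet.from_iterable(fields[0], genes))
        return sets
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return [GeneSet.from_iterable(path.stem, genes)]


def write_gene_sets(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.gene_ids)]) + "\n")


def read_counts(path: str | Path, events: Iterable[SpliceEvent]) -> pd.DataFrame:
    """Read a junction-count TSV (event_id, sample_id, inclusion, skipping)
    and attach effective lengths (inc_len, skp_len) from each event's type."""
    by_id = {e.event_id: e for e in events}
    df = pd.read_csv(path, sep="\t")
    for col in ("event_id", "sample_id", "inclusion", "skipping"):
        if col not in df.columns:
            raise ValueError(f"count table {path}: missing column {col!r}")
    unknown = set(df["event_id"]) - set(by_id)
    if unknown:
        raise ValueError(f"count table {path}: unknown event_id(s) {sorted(unknown)[:5]}")
    if (df[["inclusion", "skipping"]] < 0).any().any():
        raise ValueError(f"count table {path}: negative counts")
    lens = df["event_id"].map(lambda eid: by_id[eid].effective_lengths)
    df["inc_len"] = [l[0] for l in lens]
    df["skp_len"] = [l[1] for l in lens]
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[["event_id", "sample_id", "inclusion", "skipping"]].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def normalize_sequence(seq: str, name: str = "?") -> str:
    """Uppercase, U->T; reject non-nucleotide characters (1-based position)."""
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s, 1):
        if ch not in _VALID_NT:
            raise ValueError(f"sequence {name!r}: non-nucleotide character {ch!r} at position {pos}")
    return s


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into a name -> normalized-DNA-sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_sequence(str(rec.seq), rec.id)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (chrom, start, end; 0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: malformed interval end <= start")
            intervals.append((chrom, start, end))
    return intervals


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end
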