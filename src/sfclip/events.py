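"""Splicing events and the splicing regions CLIP peaks are mapped against.

A splicing event is a local alternative-splicing choice in a gene: two
alternative paths, p1 and p2 (e.g. a cassette exon with its flanking
junctions versus the junction that skips it), plus a reference path pref
shared by both isoform groups. Events are consumed as an annotation table;
detecting them from a transcriptome is out of scope.

The *splicing region* of an event is the genomic neighborhood where
regulatory RBP binding is expected: every interval of the alternative paths
extended by a window (default 400 nt) on each side, then merged. The
reference path does not contribute to the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

EVENT_TYPES = {
    "cassette",
    "alt5",
    "alt3",
    "retained_intron",
    "mutually_exclusive",
    "complex",
}

#: default half-window, in nt, around the alternative paths
DEFAULT_WINDOW_NT = 400

EVENT_TABLE_COLUMNS = [
    "event_id",
    "gene_id",
    "event_type",
    "path",
    "chrom",
    "start",
    "end",
    "strand",
    "transcripts",
]


@dataclass
class SplicingEvent:
    """One alternative-splicing event: paths p1/p2 plus a reference path."""

    event_id: str
    gene_id: str
    event_type: str
    p1_intervals: list[GenomicInterval]
    p2_intervals: list[GenomicInterval]
    pref_intervals: list[GenomicInterval] = field(default_factory=list)
    p1_transcripts: set[str] = field(default_factory=set)
    p2_transcripts: set[str] = field(default_factory=set)
    pref_transcripts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"{self.event_id}: unknown event_type {self.event_type!r}"
            )
        if not self.p1_intervals or not self.p2_intervals:
            raise ValueError(f"{self.event_id}: p1 and p2 must be non-empty")
        shared = self.p1_transcripts & self.p2_transcripts
        if shared:
            raise ValueError(
                f"{self.event_id}: transcripts on both alternative paths: "
                f"{sorted(shared)}"
            )
        chroms = {
            iv.chrom
            for iv in (*self.p1_intervals, *self.p2_intervals, *self.pref_intervals)
        }
        if len(chroms) != 1:
            raise ValueError(
                f"{self.event_id}: intervals span multiple chromosomes {sorted(chroms)}"
            )

    @property
    def chrom(self) -> str:
        return self.p1_intervals[0].chrom


@dataclass
class SplicingRegion:
    """Merged, disjoint genomic windows around one event's alternative paths."""

    event_id: str
    windows: list[GenomicInterval]


def derive_splicing_region(
    event: SplicingEvent, window_nt: int = DEFAULT_WINDOW_NT
) -> SplicingRegion:
    """Extend every p1/p2 interval by ``window_nt`` each side and merge.

    Windows are clipped at position 0; pref intervals are excluded.
    With ``window_nt=0`` this is exactly the merged union of p1 ∪ p2.
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    padded = [
        iv.pad(window_nt) for iv in (*event.p1_intervals, *event.p2_intervals)
    ]
    return SplicingRegion(event.event_id, merge_intervals(padded))


def _parse_transcripts(cell: object) -> set[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return set()
    text = str(cell).strip()
    if not text:
        return set()
    return {t for t in (s.strip() for s in text.split(",")) if t}


def load_event_table(path: str | Path) -> list[SplicingEvent]:
    """Read a splicing-event annotation table (TSV, one row per interval).

    Columns: event_id, gene_id, event_type, path (p1|p2|pref), chrom,
    start, end, strand, transcripts (comma-separated; empty for pref).
    Coordinates are 0-based half-open. Rows sharing an event_id form one
    event and must agree on gene_id and event_type.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing = set(EVENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    events: list[SplicingEvent] = []
    seen_order: list[str] = []
    groups: dict[str, list[tuple[int, pd.Series]]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        eid = row.event_id
        if eid not in groups:
            groups[eid] = []
            seen_order.append(eid)
        elif groups[eid] and seen_order[-1] != eid:
            # non-contiguous reuse of an event_id is a duplicate definition
            raise ValueError(f"{path}: duplicate event_id {eid!r} (line {idx})")
        groups[eid].append((idx, row))

    for eid in seen_order:
        rows = groups[eid]
        gene_ids = {r.gene_id for _, r in rows}
        etypes = {r.event_type for _, r in rows}
        if len(gene_ids) != 1 or len(etypes) != 1:
            raise ValueError(
                f"{path}: event {eid!r} has conflicting gene_id/event_type"
            )
        paths: dict[str, list[GenomicInterval]] = {"p1": [], "p2": [], "pref": []}
        txs: dict[str, set[str]] = {"p1": set(), "p2": set(), "pref": set()}
        for line_no, r in rows:
            if r.path not in paths:
                raise ValueError(
                    f"{path} line {line_no}: path must be p1|p2|pref, got {r.path!r}"
                )
            try:
                start, end = int(r.start), int(r.end)
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {line_no}: malformed coordinates "
                    f"({r.start!r}, {r.end!r})"
                ) from exc
            try:
                iv = GenomicInterval(r.chrom, start, end, r.strand or ".")
            except ValueError as exc:
                raise ValueError(f"{path} line {line_no}: {exc}") from exc
            paths[r.path].append(iv)
            txs[r.path] |= _parse_transcripts(r.transcripts)
        events.append(
            SplicingEvent(
                event_id=eid,
                gene_id=gene_ids.pop(),
                event_type=etypes.pop(),
                p1_intervals=paths["p1"],
                p2_intervals=paths["p2"],
                pref_intervals=paths["pref"],
                p1_transcripts=txs["p1"],
                p2_transcripts=txs["p2"],
                pref_transcripts=txs["pref"],
            )
        )
    return events


def write_event_table(events: Iterable[SplicingEvent], path: str | Path) -> None:
    """Write events in the TSV layout read by :func:`load_event_table`."""
    rows = []
    for ev in events:
        for pname, ivs, txs in (
            ("p1", ev.p1_intervals, ev.p1_transcripts),
            ("p2", ev.p2_intervals, ev.p2_transcripts),
            ("pref", ev.pref_intervals, ev.pref_transcripts),
        ):
            for iv in ivs:
                rows.append(
                    (
                        ev.event_id,
                        ev.gene_id,
                        ev.event_type,
                        pname,
                        iv.chrom,
                        iv.start,
                        iv.end,
                        iv.strand,
                        ",".join(sorted(txs)),
                    )
                )
    pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV (chrom, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def clip_region_to_chrom(
    region: SplicingRegion, chrom_sizes: Mapping[str, int]
) -> SplicingRegion:
    """Clip region windows at chromosome ends when sizes are known."""
    windows = []
    for iv in region.windows:
        limit = chrom_sizes.get(iv.chrom)
        if limit is None or iv.end <= limit:
            windows.append(iv)
        elif iv.start < limit:
            windows.append(GenomicInterval(iv.chrom, iv.start, limit, iv.strand))
        # windows entirely past the end are dropped
    return SplicingRegion(region.event_id, windows)
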