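"""CLIP peak ingestion and per-RBP consolidation.

CLIP-seq experiments (HITS-CLIP, PAR-CLIP, iCLIP, eCLIP) report the binding
sites of a single RNA-binding protein as genomic peaks. Public databases
(POSTAR2, CLIPdb, DoRiNA, StarBase) collect many such experiments per RBP.
Consolidation follows an inclusive criterion — a site annotated by any
experiment counts as putative regulation — with one priority rule: if an
RBP is present in the reference database (POSTAR2 by default), only that
database's peaks are used for it; otherwise the union over the remaining
databases is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

DATABASES = {"POSTAR2", "CLIPdb", "DoRiNA", "StarBase", "other"}
TECHNOLOGIES = {"HITS-CLIP", "PAR-CLIP", "iCLIP", "eCLIP", "other"}
DIALECTS = {"bed3", "bed6", "narrowPeak"}

#: minimum column count per dialect
_MIN_COLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


@dataclass(frozen=True)
class ClipPeak:
    """One CLIP peak attributed to an RBP, experiment and source database."""

    rbp: str
    experiment_id: str
    database: str
    technology: str
    interval: GenomicInterval
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.rbp:
            raise ValueError("rbp symbol must be non-empty")
        if self.database not in DATABASES:
            raise ValueError(f"unknown database {self.database!r}")
        if self.technology not in TECHNOLOGIES:
            raise ValueError(f"unknown technology {self.technology!r}")


@dataclass
class RbpPeakSet:
    """Consolidated binding sites of one RBP: merged disjoint intervals."""

    rbp: str
    source_databases: set[str]
    intervals: list[GenomicInterval]

    def covered_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def read_peak_file(
    path: str | Path,
    rbp: str,
    database: str,
    dialect: str = "bed6",
    technology: str = "other",
    experiment_id: str | None = None,
) -> list[ClipPeak]:
    """Parse a BED3/BED6/narrowPeak file into :class:`ClipPeak` records.

    Strand is taken from column 6 when the dialect carries one, else
    recorded as unknown ("."); the score column (5) is kept when present
    and numeric.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {sorted(DIALECTS)}")
    path = Path(path)
    experiment_id = experiment_id or path.stem
    peaks: list[ClipPeak] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < _MIN_COLS[dialect]:
                raise ValueError(
                    f"{path} line {line_no}: expected >= {_MIN_COLS[dialect]} "
                    f"columns for {dialect}, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {line_no}: non-numeric coordinates"
                ) from exc
            strand = "."
            score: float | None = None
            if dialect in ("bed6", "narrowPeak"):
                if fields[5] in ("+", "-"):
                    strand = fields[5]
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path} line {line_no}: {exc}") from exc
            peaks.append(
                ClipPeak(
                    rbp=rbp.upper(),
                    experiment_id=experiment_id,
                    database=database,
                    technology=technology,
                    interval=iv,
                    score=score,
                )
            )
    if not peaks:
        logger.warning("%s: empty peak file for %s", path, rbp)
    return peaks


METADATA_COLUMNS = [
    "file",
    "rbp",
    "database",
    "technology",
    "experiment_id",
    "dialect",
    "excluded",
]


def load_peak_metadata(path: str | Path) -> pd.DataFrame:
    """Read the peak-file metadata TSV.

    Columns: file, rbp, database, technology, experiment_id, dialect,
    excluded (0/1; e.g. experiments on mutated RBPs). Paths are resolved
    relative to the metadata file's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    df["excluded"] = df["excluded"].astype(int).astype(bool)
    return df


def load_peak_collection(
    metadata_path: str | Path, base_dir: str | Path | None = None
) -> list[ClipPeak]:
    """Read every non-excluded peak file listed in a metadata table."""
    meta = load_peak_metadata(metadata_path)
    base = Path(base_dir) if base_dir is not None else Path(metadata_path).parent
    peaks: list[ClipPeak] = []
    for row in meta.itertuples(index=False):
        if row.excluded:
            logger.info("skipping excluded experiment %s", row.experiment_id)
            continue
        peaks.extend(
            read_peak_file(
                base / row.file,
                rbp=row.rbp,
                database=row.database,
                dialect=row.dialect,
                technology=row.technology,
                experiment_id=row.experiment_id,
            )
        )
    return peaks


def consolidate_rbp_peaks(
    peaks: Iterable[ClipPeak], priority_database: str = "POSTAR2"
) -> dict[str, RbpPeakSet]:
    """Consolidate peaks into one merged binding-site set per RBP.

    Per RBP: if any peak originates from ``priority_database``, only that
    database's peaks are kept; otherwise the union over all other databases
    is kept. Kept intervals are merged per (chrom, strand); the result is
    independent of input order.
    """
    by_rbp: dict[str, list[ClipPeak]] = {}
    for pk in peaks:
        by_rbp.setdefault(pk.rbp.upper(), []).append(pk)

    out: dict[str, RbpPeakSet] = {}
    for rbp in sorted(by_rbp):
        group = by_rbp[rbp]
        if any(pk.database == priority_database for pk in group):
            kept = [pk for pk in group if pk.database == priority_database]
        else:
            kept = group
        out[rbp] = RbpPeakSet(
            rbp=rbp,
            source_databases={pk.database for pk in kept},
            intervals=merge_intervals(pk.interval for pk in kept),
        )
    return out
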