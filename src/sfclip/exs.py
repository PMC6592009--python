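"""The ExS (Events x Splicing factors) binary incidence matrix.

Entry (i, j) is 1 iff at least one consolidated CLIP peak of RBP j overlaps
the splicing region of event i by >= 1 nt. The matrix is the bridge between
the CLIP side of the method (where do RBPs bind?) and the expression side
(which events changed?): column j restricted to a set of events gives the
counts that feed the enrichment test, and pairs of columns give the
binding-similarity network.

Storage is an open, language-neutral trio: a MatrixMarket pattern file plus
two one-column label files for event and RBP identifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

from .clip import RbpPeakSet
from .events import SplicingRegion

logger = logging.getLogger(__name__)

STRAND_POLICIES = {"ignore", "require_match_when_known"}


@dataclass
class ExSMatrix:
    """Sparse binary events x RBPs matrix with row/column labels."""

    event_ids: list[str]
    rbp_ids: list[str]
    matrix: sp.csr_matrix  # int8 0/1

    def __post_init__(self) -> None:
        if len(set(self.event_ids)) != len(self.event_ids):
            raise ValueError("duplicate event ids")
        if len(set(self.rbp_ids)) != len(self.rbp_ids):
            raise ValueError("duplicate RBP ids")
        if self.matrix.shape != (len(self.event_ids), len(self.rbp_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match labels "
                f"({len(self.event_ids)}, {len(self.rbp_ids)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column_sums(self) -> dict[str, int]:
        """Events bound per RBP (the per-RBP binding breadth)."""
        sums = np.asarray(self.matrix.sum(axis=0)).ravel()
        return dict(zip(self.rbp_ids, (int(s) for s in sums)))

    def column(self, rbp: str) -> np.ndarray:
        j = self.rbp_ids.index(rbp)
        return np.asarray(self.matrix[:, j].todense()).ravel()

    def row_index(self, event_ids: Iterable[str]) -> np.ndarray:
        pos = {e: i for i, e in enumerate(self.event_ids)}
        try:
            return np.array([pos[e] for e in event_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown event id {exc.args[0]!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExSMatrix):
            return NotImplemented
        return (
            self.event_ids == other.event_ids
            and self.rbp_ids == other.rbp_ids
            and (self.matrix != other.matrix).nnz == 0
        )


def _strands_compatible(a: str, b: str) -> bool:
    return "." in (a, b) or a == b


def build_exs(
    regions: Sequence[SplicingRegion],
    peak_sets: Mapping[str, RbpPeakSet],
    strand_policy: str = "ignore",
) -> ExSMatrix:
    """Overlap consolidated peaks with splicing regions via interval trees.

    One tree per chromosome indexes the region windows; each peak interval
    is queried against its chromosome's tree. An entry is set as soon as a
    single >= 1 nt intersection is found. With
    ``strand_policy="require_match_when_known"`` a peak and window on
    explicitly opposite strands do not match.
    """
    if strand_policy not in STRAND_POLICIES:
        raise ValueError(f"strand_policy must be one of {sorted(STRAND_POLICIES)}")
    if not regions or not peak_sets:
        warnings.warn("building ExS with empty regions or peak sets")

    event_ids = [r.event_id for r in regions]
    rbp_ids = sorted(peak_sets)
    stranded = strand_policy == "require_match_when_known"

    trees: dict[str, IntervalTree] = {}
    for i, region in enumerate(regions):
        for win in region.windows:
            trees.setdefault(win.chrom, IntervalTree()).addi(
                win.start, win.end, (i, win.strand)
            )

    rows: list[int] = []
    cols: list[int] = []
    for j, rbp in enumerate(rbp_ids):
        hit: set[int] = set()
        for iv in peak_sets[rbp].intervals:
            tree = trees.get(iv.chrom)
            if tree is None:
                continue
            for node in tree.overlap(iv.start, iv.end):
                i, win_strand = node.data
                if stranded and not _strands_compatible(iv.strand, win_strand):
                    continue
                hit.add(i)
        rows.extend(hit)
        cols.extend([j] * len(hit))

    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(event_ids), len(rbp_ids)),
    )
    return ExSMatrix(event_ids, rbp_ids, matrix)


def write_exs(m: ExSMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` (pattern) + ``.events.txt`` + ``.rbps.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(prefix) + ".mtx", m.matrix.tocoo(), field="pattern", symmetry="general"
    )
    Path(str(prefix) + ".events.txt").write_text(
        "".join(f"{e}\n" for e in m.event_ids)
    )
    Path(str(prefix) + ".rbps.txt").write_text(
        "".join(f"{r}\n" for r in m.rbp_ids)
    )


def read_exs(prefix: str | Path) -> ExSMatrix:
    """Read a matrix written by :func:`write_exs`; validates label counts."""
    prefix = str(prefix)
    try:
        mat = scipy.io.mmread(prefix + ".mtx").tocsr().astype(np.int8)
    except Exception as exc:
        raise ValueError(f"{prefix}.mtx: cannot read MatrixMarket file: {exc}")
    event_ids = Path(prefix + ".events.txt").read_text().splitlines()
    rbp_ids = Path(prefix + ".rbps.txt").read_text().splitlines()
    if mat.shape != (len(event_ids), len(rbp_ids)):
        raise ValueError(
            f"{prefix}: matrix shape {mat.shape} does not match label files "
            f"({len(event_ids)} events, {len(rbp_ids)} RBPs)"
        )
    return ExSMatrix(event_ids, rbp_ids, mat)


def exs_to_frame(m: ExSMatrix):
    """Dense pandas view (small matrices only)."""
    import pandas as pd

    return pd.DataFrame(
        m.matrix.toarray(), index=m.event_ids, columns=m.rbp_ids
    )
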