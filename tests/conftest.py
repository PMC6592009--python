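"""Shared fixtures: random generators for events, peaks and small matrices."""

from __future__ import annotations

import numpy as np
import pytest

from sfclip import ClipPeak, GenomicInterval, SplicingEvent

DATABASES = ["POSTAR2", "CLIPdb", "DoRiNA", "StarBase"]


def random_event(rng: np.random.Generator, event_id: str) -> SplicingEvent:
    """A random valid splicing event on a small two-chromosome genome."""
    chrom = rng.choice(["chr1", "chr2"])
    strand = rng.choice(["+", "-"])
    base = int(rng.integers(0, 50_000))

    def intervals(offset: int) -> list[GenomicInterval]:
        out = []
        pos = base + offset
        for _ in range(int(rng.integers(1, 4))):
            start = pos + int(rng.integers(0, 300))
            end = start + int(rng.integers(50, 400))
            out.append(GenomicInterval(chrom, start, end, strand))
            pos = end
        return out

    n1, n2 = int(rng.integers(1, 3)), int(rng.integers(1, 3))
    return SplicingEvent(
        event_id=event_id,
        gene_id=f"G_{event_id}",
        event_type=str(
            rng.choice(["cassette", "alt5", "alt3", "retained_intron"])
        ),
        p1_intervals=intervals(0),
        p2_intervals=intervals(1500),
        pref_intervals=intervals(3000) if rng.random() < 0.5 else [],
        p1_transcripts={f"{event_id}.a{i}" for i in range(n1)},
        p2_transcripts={f"{event_id}.b{i}" for i in range(n2)},
    )


def random_peaks(
    rng: np.random.Generator, rbp: str, n: int, database: str | None = None
) -> list[ClipPeak]:
    peaks = []
    for i in range(n):
        chrom = rng.choice(["chr1", "chr2"])
        start = int(rng.integers(0, 55_000))
        peaks.append(
            ClipPeak(
                rbp=rbp,
                experiment_id=f"exp_{rbp}_{i}",
                database=database or str(rng.choice(DATABASES)),
                technology="HITS-CLIP",
                interval=GenomicInterval(
                    chrom, start, start + int(rng.integers(20, 200)),
                    str(rng.choice(["+", "-", "."])),
                ),
            )
        )
    return peaks


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
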