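"""Core domain types shared by every stage of the pipeline.

All coordinates are 0-based, half-open ``[start, end)``.  Conversion from
external conventions (1-based inclusive caller tables, GFF3) happens once,
at read time, in :mod:`cnvdosage.io_formats`; no other module converts.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CnvType",
    "Caller",
    "CnvCall",
    "GapTrack",
    "TranscriptModel",
    "TranscriptSet",
    "ExpressionMatrix",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span on one chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Share >= 1 bp.  Half-open adjacency is not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class CnvType(str, Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class Caller(str, Enum):
    READ_DEPTH = "read_depth"
    SPLIT_READ = "split_read"


@dataclass(frozen=True)
class CnvCall:
    """One deletion or duplication call for one animal from one caller."""

    interval: GenomicInterval
    cnv_type: CnvType
    animal_id: str
    caller: Caller
    validated: bool = False

    @property
    def length(self) -> int:
        return self.interval.length

    def with_validated(self, flag: bool) -> "CnvCall":
        return replace(self, validated=flag)


class GapTrack:
    """Assembly gaps: disjoint, per-chromosome sorted intervals.

    Supports O(log n) "does this interval overlap any gap" queries via
    binary search on the sorted start positions.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._intervals: dict[str, list[GenomicInterval]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(f"gap intervals overlap on {chrom}: {a} / {b}")
            self._intervals[chrom] = ivs
            self._starts[chrom] = [iv.start for iv in ivs]
            self._ends[chrom] = [iv.end for iv in ivs]

    def __len__(self) -> int:
        return sum(len(v) for v in self._intervals.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._intervals):
            yield from self._intervals[chrom]

    def overlaps(self, interval: GenomicInterval) -> bool:
        starts = self._starts.get(interval.chrom)
        if not starts:
            return False
        ends = self._ends[interval.chrom]
        # rightmost gap starting before interval.end
        i = bisect.bisect_left(starts, interval.end) - 1
        return i >= 0 and ends[i] > interval.start


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon structure of one transcript.

    ``exons`` are sorted, disjoint, 0-based half-open intervals on
    ``chrom``.  Introns are the gaps between consecutive exons.  The TSS
    is the low-coordinate end of the span on ``+`` and the high end on
    ``-``; flanks are derived from it downstream, in the annotation layer.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if a.chrom != self.chrom or a.end > b.start:
                raise ValueError(
                    f"exons of {self.transcript_id} must be disjoint, sorted, on {self.chrom}"
                )
        if exons[0].chrom != self.chrom:
            raise ValueError(f"exon chromosome mismatch in {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def body_length(self) -> int:
        """Genomic TSS-TTS extent (exons + introns)."""
        return self.end - self.start

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return tuple(out)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


class TranscriptSet:
    """An ordered collection of transcripts with id lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._transcripts = list(transcripts)
        self._by_id = {t.transcript_id: t for t in self._transcripts}
        if len(self._by_id) != len(self._transcripts):
            raise ValueError("duplicate transcript_id in TranscriptSet")

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts)

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [t.transcript_id for t in self._transcripts]

    def body_lengths(self) -> pd.Series:
        return pd.Series(
            {t.transcript_id: t.body_length for t in self._transcripts}, name="body_length"
        )


TPM_TOTAL = 1_000_000.0


class ExpressionMatrix:
    """Transcript x sample TPM values, backed by a pandas DataFrame."""

    def __init__(self, tpm: pd.DataFrame):
        if tpm.index.has_duplicates:
            raise ValueError("duplicate transcript_id in expression matrix")
        if tpm.columns.has_duplicates:
            raise ValueError("duplicate sample_id in expression matrix")
        values = tpm.to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("TPM values must be finite and non-negative")
        self.tpm = tpm.astype(float)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tpm.shape

    def mean_per_transcript(self) -> pd.Series:
        return self.tpm.mean(axis=1)

    def is_tpm_normalized(self, rtol: float = 1e-6) -> bool:
        sums = self.tpm.sum(axis=0).to_numpy()
        return bool(np.allclose(sums, TPM_TOTAL, rtol=rtol))

    @staticmethod
    def from_abundance(abundance: pd.DataFrame) -> "ExpressionMatrix":
        """Scale each sample column to sum to one million (TPM)."""
        sums = abundance.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("cannot TPM-normalize a sample with zero total abundance")
        return ExpressionMatrix(abundance.div(sums, axis=1) * TPM_TOTAL)
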