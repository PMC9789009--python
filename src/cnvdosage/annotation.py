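"""Classify validated CNVs against transcript models.

Region vocabulary per transcript: ``coding`` (exonic sequence),
``intronic`` (gaps between exons), and 5000-bp strand-aware ``upstream`` /
``downstream`` flanks anchored at the TSS and TTS.  For statistics the two
flanks are pooled into one ``updown`` class; tallies keep them separate.

A CNV is assigned a region class for a transcript only if it intersects
exactly one of {coding, intronic, updown} for that transcript.  A CNV
touching two or more classes of the same transcript (e.g. an exon and an
intron, or a flank and the body) is discarded *for that transcript only* —
it may still classify cleanly against a neighbouring transcript.  A CNV
touching no transcript and no flank is intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import CnvCall, CnvType, GenomicInterval, TranscriptModel, TranscriptSet

__all__ = [
    "REGION_CLASSES",
    "MULTI_REGION",
    "build_regions",
    "classify",
    "percent_covered",
    "annotate",
    "AnnotationResult",
    "tally_regions",
]

REGION_CLASSES = ("coding", "intronic", "upstream", "downstream")

#: sentinel returned by :func:`classify` for the multi-region discard rule
MULTI_REGION = "multi_region"

DEFAULT_FLANK_BP = 5000


def build_regions(
    transcript: TranscriptModel,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_length: Optional[int] = None,
) -> dict[str, list[GenomicInterval]]:
    """Labelled interval sets {coding, intronic, upstream, downstream}.

    Flanks are strand-aware (upstream borders the TSS) and clipped at
    position 0 and, when known, the chromosome end.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    chrom = transcript.chrom
    left_lo = max(0, transcript.start - flank_bp)
    right_hi = transcript.end + flank_bp
    if chrom_length is not None:
        right_hi = min(right_hi, chrom_length)
    left = (
        [GenomicInterval(chrom, left_lo, transcript.start)]
        if left_lo < transcript.start
        else []
    )
    right = (
        [GenomicInterval(chrom, transcript.end, right_hi)]
        if right_hi > transcript.end
        else []
    )
    if transcript.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left
    return {
        "coding": list(transcript.exons),
        "intronic": list(transcript.introns),
        "upstream": upstream,
        "downstream": downstream,
    }


def _overlap_bp(interval: GenomicInterval, regions: Iterable[GenomicInterval]) -> int:
    return sum(interval.overlap_bp(r) for r in regions)


def classify(
    cnv: GenomicInterval,
    transcript: TranscriptModel,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_length: Optional[int] = None,
) -> Optional[str]:
    """Region class of ``cnv`` w.r.t. one transcript.

    Returns one of :data:`REGION_CLASSES`, :data:`MULTI_REGION` when the
    CNV intersects more than one of {coding, intronic, updown}, or ``None``
    when it does not touch the transcript or its flanks.
    """
    if cnv.chrom != transcript.chrom:
        return None
    regions = build_regions(transcript, flank_bp, chrom_length)
    coding = _overlap_bp(cnv, regions["coding"]) > 0
    intronic = _overlap_bp(cnv, regions["intronic"]) > 0
    up = _overlap_bp(cnv, regions["upstream"]) > 0
    down = _overlap_bp(cnv, regions["downstream"]) > 0
    pooled_hits = sum((coding, intronic, up or down))
    if pooled_hits == 0:
        return None
    if pooled_hits > 1:
        return MULTI_REGION
    if coding:
        return "coding"
    if intronic:
        return "intronic"
    return "upstream" if up else "downstream"


def percent_covered(
    cnvs: Sequence[GenomicInterval], transcript: TranscriptModel
) -> float:
    """Fraction of the transcript body (TSS-TTS extent) covered by the
    union of the given CNV intervals.  Flank-only overlap contributes 0."""
    body = transcript.span
    clipped = sorted(
        (max(c.start, body.start), min(c.end, body.end))
        for c in cnvs
        if c.chrom == body.chrom and c.start < body.end and c.end > body.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / transcript.body_length


@dataclass
class AnnotationResult:
    """Overlap table plus the bookkeeping the tallies need."""

    overlaps: pd.DataFrame  # one row per (CNV, transcript, class, animal)
    intergenic: pd.DataFrame  # per (animal_id, cnv_type) orphan-CNV counts
    n_discarded: int  # (CNV, transcript) pairs removed by the multi-region rule


_OVERLAP_COLUMNS = [
    "animal_id",
    "cnv_type",
    "chrom",
    "cnv_start",
    "cnv_end",
    "transcript_id",
    "region_class",
    "overlap_bp",
    "percent_covered",
]


def annotate(
    validated_calls: Mapping[str, Sequence[CnvCall]],
    transcripts: TranscriptSet,
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> AnnotationResult:
    """Classify every validated CNV against every transcript it touches.

    ``percent_covered`` on each row is the union coverage of the transcript
    body by *all* classified calls of that (animal, cnv_type, transcript)
    group, the quantity the coverage-correlation analysis ranks.
    """
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        lo = max(0, t.start - flank_bp)
        hi = t.end + flank_bp
        if chrom_lengths is not None and t.chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[t.chrom])
        trees.setdefault(t.chrom, IntervalTree()).addi(lo, hi, t.transcript_id)

    rows = []
    intergenic_rows = []
    n_discarded = 0
    for animal in sorted(validated_calls):
        orphan = {CnvType.DELETION: 0, CnvType.DUPLICATION: 0}
        for call in validated_calls[animal]:
            iv = call.interval
            tree = trees.get(iv.chrom)
            hits = tree[iv.start : iv.end] if tree is not None else set()
            if not hits:
                orphan[call.cnv_type] += 1
                continue
            any_record = False
            for hit in sorted(hits, key=lambda h: h.data):
                t = transcripts[hit.data]
                chrom_len = (
                    chrom_lengths.get(t.chrom) if chrom_lengths is not None else None
                )
                cls = classify(iv, t, flank_bp, chrom_len)
                if cls is None:
                    continue
                if cls == MULTI_REGION:
                    n_discarded += 1
                    continue
                any_record = True
                rows.append(
                    {
                        "animal_id": animal,
                        "cnv_type": call.cnv_type.value,
                        "chrom": iv.chrom,
                        "cnv_start": iv.start,
                        "cnv_end": iv.end,
                        "transcript_id": t.transcript_id,
                        "region_class": cls,
                        "overlap_bp": iv.overlap_bp(t.span),
                    }
                )
            # a CNV whose every touched transcript discarded it is *not*
            # intergenic: it did touch annotation
            del any_record
        for cnv_type, n in orphan.items():
            intergenic_rows.append(
                {"animal_id": animal, "cnv_type": cnv_type.value, "count": n}
            )

    overlaps = pd.DataFrame(rows, columns=_OVERLAP_COLUMNS[:-1])
    if len(overlaps):
        pct = {}
        for (animal, cnv_type, tid), grp in overlaps.groupby(
            ["animal_id", "cnv_type", "transcript_id"], sort=False
        ):
            t = transcripts[tid]
            ivs = [
                GenomicInterval(r.chrom, r.cnv_start, r.cnv_end)
                for r in grp.itertuples()
            ]
            pct[(animal, cnv_type, tid)] = percent_covered(ivs, t)
        overlaps["percent_covered"] = [
            pct[(r.animal_id, r.cnv_type, r.transcript_id)] for r in overlaps.itertuples()
        ]
    else:
        overlaps = pd.DataFrame(columns=_OVERLAP_COLUMNS)
    intergenic = pd.DataFrame(
        intergenic_rows, columns=["animal_id", "cnv_type", "count"]
    )
    return AnnotationResult(overlaps=overlaps, intergenic=intergenic, n_discarded=n_discarded)


def tally_regions(result: AnnotationResult) -> pd.DataFrame:
    """Per-animal, per-type counts by region class plus the intergenic bucket.

    A CNV contributes one count per (transcript, class) record, so class
    columns may sum to more than the number of CNVs.
    """
    classes = list(REGION_CLASSES)
    if len(result.overlaps):
        counts = (
            result.overlaps.groupby(["animal_id", "cnv_type", "region_class"])
            .size()
            .unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame()
    inter = result.intergenic.set_index(["animal_id", "cnv_type"])["count"] if len(
        result.intergenic
    ) else pd.Series(dtype=int)
    index = sorted(set(counts.index) | set(inter.index))
    out = pd.DataFrame(0, index=pd.MultiIndex.from_tuples(index, names=["animal_id", "cnv_type"]) if index else pd.MultiIndex.from_arrays([[], []], names=["animal_id", "cnv_type"]), columns=classes + ["intergenic"], dtype=int)
    for cls in classes:
        if cls in counts.columns:
            out.loc[counts.index, cls] = counts[cls]
    for idx, n in inter.items():
        out.loc[idx, "intergenic"] = n
    return out
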