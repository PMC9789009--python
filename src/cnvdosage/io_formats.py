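"""Readers and writers for every external representation the pipeline touches.

External conventions supported:

* ``read_depth_table`` — whitespace-delimited lines in the style of a
  post-processed read-depth caller: ``cnv_type  chrom:start-end  [extra...]``
  with **1-based inclusive** coordinates.
* ``split_read_table`` — tab-delimited ``cnv_type  chrom  start  end`` with
  **1-based inclusive** coordinates (split-read callers report base-pair
  breakpoints in 1-based convention).
* ``bed`` — ``chrom  start  end  cnv_type`` with 0-based half-open
  coordinates (standard BED).
* GFF3 (1-based inclusive) for transcript models, parsed with gffutils.
* TSV for TPM matrices: first column ``transcript_id``, one column per sample.

Everything is normalized on read to the internal 0-based half-open
convention; chromosome names are matched exactly (no "chr" stripping).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .core import (
    Caller,
    CnvCall,
    CnvType,
    ExpressionMatrix,
    GapTrack,
    GenomicInterval,
    TranscriptModel,
    TranscriptSet,
)

__all__ = [
    "parse_cnv_type",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_bed_gaps",
    "write_bed_gaps",
    "read_gff3_transcripts",
    "write_gff3_transcripts",
    "read_tpm_table",
    "write_tpm_table",
    "write_validated_cnvs",
    "read_validated_cnvs",
]

_TYPE_TOKENS = {
    "deletion": CnvType.DELETION,
    "del": CnvType.DELETION,
    "duplication": CnvType.DUPLICATION,
    "dup": CnvType.DUPLICATION,
}

_DIALECT_CALLER = {
    "read_depth_table": Caller.READ_DEPTH,
    "split_read_table": Caller.SPLIT_READ,
    "bed": Caller.READ_DEPTH,
}


def parse_cnv_type(token: str) -> CnvType:
    try:
        return _TYPE_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown cnv_type token {token!r}") from None


def _err(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_cnv_calls(
    path,
    dialect: str,
    animal_id: str,
    caller: Caller | None = None,
) -> list[CnvCall]:
    """Read one animal's call set in the given dialect.

    Coordinates are converted to 0-based half-open.  Malformed lines raise
    ``ValueError`` naming the line number.
    """
    if dialect not in _DIALECT_CALLER:
        raise ValueError(f"unknown dialect {dialect!r}")
    caller = caller if caller is not None else _DIALECT_CALLER[dialect]
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "read_depth_table":
                    if len(fields) < 2 or ":" not in fields[1] or "-" not in fields[1]:
                        raise ValueError("expected 'cnv_type chrom:start-end'")
                    cnv_type = parse_cnv_type(fields[0])
                    chrom, span = fields[1].split(":", 1)
                    s, e = span.split("-", 1)
                    start, end = int(s) - 1, int(e)  # 1-based incl -> 0-based half-open
                elif dialect == "split_read_table":
                    if len(fields) < 4:
                        raise ValueError("expected 'cnv_type chrom start end'")
                    cnv_type = parse_cnv_type(fields[0])
                    chrom = fields[1]
                    start, end = int(fields[2]) - 1, int(fields[3])
                else:  # bed
                    if len(fields) < 4:
                        raise ValueError("expected 'chrom start end cnv_type'")
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    cnv_type = parse_cnv_type(fields[3])
                if end <= start:
                    raise ValueError(f"end <= start after conversion ({start}, {end})")
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from None
            calls.append(CnvCall(interval, cnv_type, animal_id, caller))
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path, dialect: str) -> None:
    """Write calls in a caller dialect (inverse of :func:`read_cnv_calls`)."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            if dialect == "read_depth_table":
                fh.write(f"{c.cnv_type.value}\t{iv.chrom}:{iv.start + 1}-{iv.end}\t{iv.length}\n")
            elif dialect == "split_read_table":
                fh.write(f"{c.cnv_type.value}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}\n")
            elif dialect == "bed":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cnv_type.value}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_bed_gaps(path) -> GapTrack:
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise _err(path, lineno, "expected at least 3 BED columns")
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from None
    return GapTrack(intervals)


def write_bed_gaps(gaps: GapTrack, path) -> None:
    with open(path, "w") as fh:
        for iv in gaps:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gff3_transcripts(path) -> TranscriptSet:
    """Parse transcript + exon features from GFF3 (1-based inclusive).

    Exons are linked to transcripts through their ``Parent`` attribute.
    A transcript with no exons, or an exon outside its transcript span,
    is an error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts: list[TranscriptModel] = []
    t_features = [
        f
        for f in db.all_features()
        if f.featuretype in ("transcript", "mRNA")
    ]
    t_features.sort(key=lambda f: (f.seqid, f.start, f.id))
    for tf in t_features:
        exons = []
        for ex in db.children(tf.id, featuretype="exon", order_by="start"):
            if ex.start < tf.start or ex.end > tf.end:
                raise ValueError(
                    f"exon [{ex.start},{ex.end}] outside transcript {tf.id} span"
                )
            exons.append(GenomicInterval(ex.seqid, ex.start - 1, ex.end))
        if not exons:
            raise ValueError(f"transcript {tf.id} has no exons")
        if tf.strand not in ("+", "-"):
            raise ValueError(f"transcript {tf.id} has no strand")
        transcripts.append(
            TranscriptModel(
                transcript_id=tf.id, chrom=tf.seqid, strand=tf.strand, exons=tuple(exons)
            )
        )
    return TranscriptSet(transcripts)


def write_gff3_transcripts(transcripts: TranscriptSet, path, source: str = "cnvdosage") -> None:
    """Write transcript/exon features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            attrs = f"ID={t.transcript_id}"
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                )


def read_tpm_table(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript_id in {path}: {dups[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression value in {path}")
    return ExpressionMatrix(df)


def write_tpm_table(matrix: ExpressionMatrix, path) -> None:
    df = matrix.tpm.copy()
    df.index.name = "transcript_id"
    # repr-precision floats so that read(write(m)) is lossless
    df.to_csv(path, sep="\t", float_format="%.12g")


_VALIDATED_COLUMNS = ["chrom", "start", "end", "cnv_type", "animal_id", "validated"]


def write_validated_cnvs(calls: Iterable[CnvCall], path) -> None:
    """BED-like table sorted by (chrom, start, end, animal_id)."""
    rows = sorted(
        calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.animal_id)
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_VALIDATED_COLUMNS) + "\n")
        for c in rows:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cnv_type.value}\t"
                f"{c.animal_id}\t{int(c.validated)}\n"
            )


def read_validated_cnvs(path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise _err(path, lineno, "expected 6 columns")
            calls.append(
                CnvCall(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    parse_cnv_type(f[3]),
                    f[4],
                    Caller.READ_DEPTH,
                    validated=bool(int(f[5])),
                )
            )
    return calls
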