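"""Cross-caller consensus validation of CNV calls.

The read-depth call set is the baseline; a baseline call is *validated*
when a single split-read call of the same type, in the same animal, fully
covers it allowing a slack deficit (default 100 bp) at each end
independently:

    v.start <= b.start + slack   and   v.end >= b.end - slack

Three filters compose, in order: length window (default 50-1,000,000 bp,
inclusive), coverage validation, and removal of calls overlapping
reference-assembly gaps by >= 1 bp.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CnvCall, CnvType, GapTrack

__all__ = [
    "ValidationConfig",
    "filter_by_length",
    "validate_by_coverage",
    "filter_gaps",
    "run_consensus",
]


@dataclass(frozen=True)
class ValidationConfig:
    min_length: int = 50
    max_length: int = 1_000_000
    slack: int = 100
    union_coverage: bool = False  # non-default: allow a union of validator calls

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("require 0 < min_length <= max_length")
        if self.slack < 0:
            raise ValueError("slack must be >= 0")


def filter_by_length(
    calls: Sequence[CnvCall], config: ValidationConfig = ValidationConfig()
) -> list[CnvCall]:
    """Keep calls with min_length <= length <= max_length (inclusive bounds)."""
    return [c for c in calls if config.min_length <= c.length <= config.max_length]


def _covered_single(baseline, starts, ends_prefix_max, slack) -> bool:
    # validators sorted by start; among those with start <= b.start + slack,
    # is there one with end >= b.end - slack?
    i = bisect_right(starts, baseline.interval.start + slack)
    if i == 0:
        return False
    return ends_prefix_max[i - 1] >= baseline.interval.end - slack


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def validate_by_coverage(
    baseline_calls: Sequence[CnvCall],
    validator_calls: Sequence[CnvCall],
    config: ValidationConfig = ValidationConfig(),
) -> list[CnvCall]:
    """Set the ``validated`` flag on each baseline call.

    Validation is type-matched (deletions against deletions, duplications
    against duplications) and per-chromosome.  All calls must belong to one
    animal.  Non-validated calls are retained with ``validated=False``.
    """
    animals = {c.animal_id for c in baseline_calls} | {c.animal_id for c in validator_calls}
    if len(animals) > 1:
        raise ValueError(f"mixed-animal input to validate_by_coverage: {sorted(animals)}")

    by_key: dict[tuple[str, CnvType], list[CnvCall]] = {}
    for v in validator_calls:
        by_key.setdefault((v.interval.chrom, v.cnv_type), []).append(v)

    index: dict[tuple[str, CnvType], tuple[list[int], list[int], list[tuple[int, int]]]] = {}
    for key, vs in by_key.items():
        vs.sort(key=lambda c: (c.interval.start, c.interval.end))
        starts = [v.interval.start for v in vs]
        ends = [v.interval.end for v in vs]
        prefix_max = list(np.maximum.accumulate(ends))
        merged = _merge([(v.interval.start, v.interval.end) for v in vs])
        index[key] = (starts, prefix_max, merged)

    out = []
    for b in baseline_calls:
        key = (b.interval.chrom, b.cnv_type)
        ok = False
        if key in index:
            starts, prefix_max, merged = index[key]
            if config.union_coverage:
                lo = b.interval.start + config.slack
                hi = b.interval.end - config.slack
                if hi <= lo:
                    ok = bool(merged)  # slack swallows the whole call
                else:
                    ok = any(s <= lo and e >= hi for s, e in merged)
            else:
                ok = _covered_single(b, starts, prefix_max, config.slack)
        out.append(b.with_validated(ok))
    return out


def filter_gaps(calls: Sequence[CnvCall], gap_track: GapTrack) -> list[CnvCall]:
    """Remove calls sharing >= 1 bp with any reference-assembly gap."""
    return [c for c in calls if not gap_track.overlaps(c.interval)]


def run_consensus(
    per_animal_baseline: Mapping[str, Sequence[CnvCall]],
    per_animal_validator: Mapping[str, Sequence[CnvCall]],
    gap_track: GapTrack,
    config: ValidationConfig = ValidationConfig(),
) -> tuple[dict[str, list[CnvCall]], pd.DataFrame]:
    """Length filter -> coverage validation -> gap filter, per animal.

    Returns the validated call set per animal (only calls with
    ``validated=True`` that survived the gap filter) and an audit table of
    counts entering/surviving each stage, per animal and CNV type.
    """
    missing = sorted(set(per_animal_baseline) - set(per_animal_validator))
    if missing:
        raise ValueError(f"animal(s) present in baseline but absent in validator: {missing}")

    validated: dict[str, list[CnvCall]] = {}
    audit_rows = []
    for animal in sorted(per_animal_baseline):
        baseline = list(per_animal_baseline[animal])
        validator = list(per_animal_validator[animal])
        b_len = filter_by_length(baseline, config)
        v_len = filter_by_length(validator, config)
        flagged = validate_by_coverage(b_len, v_len, config)
        confirmed = [c for c in flagged if c.validated]
        survivors = filter_gaps(confirmed, gap_track)
        validated[animal] = survivors
        for cnv_type in (CnvType.DELETION, CnvType.DUPLICATION):
            sel = lambda calls: [c for c in calls if c.cnv_type == cnv_type]
            audit_rows.append(
                {
                    "animal_id": animal,
                    "cnv_type": cnv_type.value,
                    "input": len(sel(baseline)),
                    "after_length": len(sel(b_len)),
                    "validated": len(sel(confirmed)),
                    "after_gap": len(sel(survivors)),
                }
            )
    audit = pd.DataFrame(audit_rows)
    return validated, audit
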