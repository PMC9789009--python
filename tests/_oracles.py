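"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive each rule from its plain definition (all-pairs
scans, base-by-base genome labelling, full enumeration of sign patterns)
and share no code with the package internals they check.
"""

import itertools

import numpy as np

from cnvdosage.annotation import MULTI_REGION
from cnvdosage.core import GenomicInterval, TranscriptModel


def brute_force_coverage(baseline, validators, slack):
    """All-pairs evaluation of the single-call coverage inequality.

    Returns the list of validated flags for ``baseline`` (same order).
    """
    flags = []
    for b in baseline:
        ok = False
        for v in validators:
            if v.animal_id != b.animal_id or v.cnv_type != b.cnv_type:
                continue
            if v.interval.chrom != b.interval.chrom:
                continue
            if (
                v.interval.start <= b.interval.start + slack
                and v.interval.end >= b.interval.end - slack
            ):
                ok = True
                break
        flags.append(ok)
    return flags


def brute_force_classify(cnv, transcript, flank_bp, chrom_length=None):
    """Base-by-base labelling of the extended transcript span.

    Every base of the span-plus-flanks is labelled exon / intron /
    upstream / downstream; the classification is read off the set of
    labels the CNV touches, pooling the two flanks for the discard rule.
    """
    if cnv.chrom != transcript.chrom:
        return None
    lo = max(0, transcript.start - flank_bp)
    hi = transcript.end + flank_bp
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if cnv.end <= lo or cnv.start >= hi:
        return None
    labels = np.empty(hi - lo, dtype="U10")
    left = "upstream" if transcript.strand == "+" else "downstream"
    right = "downstream" if transcript.strand == "+" else "upstream"
    labels[: transcript.start - lo] = left
    labels[transcript.end - lo :] = right
    labels[transcript.start - lo : transcript.end - lo] = "intronic"
    for ex in transcript.exons:
        labels[ex.start - lo : ex.end - lo] = "coding"
    s = max(cnv.start, lo) - lo
    e = min(cnv.end, hi) - lo
    touched = set(labels[s:e])
    if not touched:
        return None
    pooled = {"updown" if t in ("upstream", "downstream") else t for t in touched}
    if len(pooled) > 1:
        return MULTI_REGION
    if pooled == {"updown"}:
        return touched.pop()
    return pooled.pop()


def enumerate_signed_rank_null(n):
    """Exact null distribution of the sum of positive ranks by full 2^n
    enumeration of sign patterns.  Returns (values, probabilities)."""
    ranks = np.arange(1, n + 1)
    ws = {}
    for signs in itertools.product((0, 1), repeat=n):
        w = int(np.dot(signs, ranks))
        ws[w] = ws.get(w, 0) + 1
    total = 2**n
    values = sorted(ws)
    probs = [ws[v] / total for v in values]
    return np.array(values), np.array(probs)


def enumerate_signed_rank_p(d, alternative):
    """Exact p for tie-free differences by enumerating all sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    values, probs = enumerate_signed_rank_null(n)
    p_ge = probs[values >= w_obs].sum()
    p_le = probs[values <= w_obs].sum()
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2 * min(p_ge, p_le))


def random_interval(rng, chrom, max_pos, min_len=1, max_len=None):
    max_len = max_len or max_pos // 2
    length = int(rng.integers(min_len, max_len + 1))
    start = int(rng.integers(0, max_pos - length))
    return GenomicInterval(chrom, start, start + length)


def random_transcript(rng, tid="tx", chrom="1", max_span=10_000, offset=20_000):
    """A random multi-exon transcript with span <= max_span, for the
    base-by-base annotation oracle."""
    k = int(rng.integers(1, 6))
    pieces = rng.integers(50, 400, size=2 * k - 1)
    span = int(pieces.sum())
    while span > max_span:
        pieces = np.maximum(50, pieces // 2)
        span = int(pieces.sum())
    start = offset + int(rng.integers(0, 5000))
    exons = []
    pos = start
    for j in range(k):
        exons.append(GenomicInterval(chrom, pos, pos + int(pieces[2 * j])))
        pos += int(pieces[2 * j])
        if j < k - 1:
            pos += int(pieces[2 * j + 1])
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(tid, chrom, strand, tuple(exons))
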