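"""Rank-based statistics for CNV dosage effects on expression.

The central quantity is the Wilcoxon signed-rank statistic in the form

    W = 1/2 * sum_i r(D_i) + n(n+1)/4,

where r(D_i) is the rank of |D_i| carrying the sign of D_i, D_i = Y_i - X_i,
X_i the mean TPM of carrier animals and Y_i of non-carrier animals for
transcript i.  Algebraically W equals the sum of the ranks of the positive
differences, which is how the exact null distribution is enumerated.

Also here: the Spearman rank correlation R_S with its t(n-2) approximation
T = R_S * sqrt((n-2)/(1-R_S^2)), a Monte-Carlo Lilliefors normality test,
the carrier/non-carrier paired contrast (1-5 carriers out of 6), the
random-split animal-effect control, and the per-animal coverage-expression
correlation surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ExpressionMatrix, TranscriptSet

__all__ = [
    "TestResult",
    "PairedContrast",
    "signed_rank_W",
    "wilcoxon_test",
    "lilliefors_test",
    "spearman_RS",
    "spearman_test",
    "build_contrast",
    "test_contrast",
    "animal_effect_control",
    "coverage_expression_correlation",
    "length_expression_correlation",
]

ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: Optional[float]
    n: int
    alternative: str = "two_sided"
    method: str = ""

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def signed_rank_W(differences: Sequence[float]) -> tuple[float, int]:
    """W = 1/2 * sum of signed ranks + n(n+1)/4, zero differences dropped.

    Ties in |D| receive mid-ranks.  Returns (W, n) with n the number of
    non-zero differences; for an all-zero input W = 0 and n = 0.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 0
    ranks = sps.rankdata(np.abs(d))
    signed_sum = float(np.sum(np.sign(d) * ranks))
    return 0.5 * signed_sum + n * (n + 1) / 4.0, n


@lru_cache(maxsize=64)
def _exact_null_pmf(n: int) -> np.ndarray:
    """P(W = w) for w = 0..n(n+1)/2 under the tie-free signed-rank null.

    Convolution of the generating function prod_k (1 + z^k) / 2^n.
    """
    pmf = np.zeros(n * (n + 1) // 2 + 1)
    pmf[0] = 1.0
    for k in range(1, n + 1):
        shifted = np.zeros_like(pmf)
        shifted[k:] = pmf[:-k]
        pmf = pmf + shifted
    return pmf / 2.0**n


def _exact_p(w: float, n: int, alternative: str) -> float:
    pmf = _exact_null_pmf(n)
    wi = int(round(w))
    p_le = float(pmf[: wi + 1].sum())
    p_ge = float(pmf[wi:].sum())
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_approx_p(
    w: float, n: int, tie_counts: np.ndarray, alternative: str
) -> float:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    # continuity correction, applied toward the null mean
    z_greater = (w - mean - 0.5) / sd
    z_less = (w - mean + 0.5) / sd
    if alternative == "greater":
        return float(sps.norm.sf(z_greater))
    if alternative == "less":
        return float(sps.norm.cdf(z_less))
    return float(min(1.0, 2.0 * min(sps.norm.sf(z_greater), sps.norm.cdf(z_less))))


EXACT_N_MAX = 25


def wilcoxon_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Paired signed-rank test of D = Y - X.

    Exact p by full enumeration of the 2^n sign assignments when n <= 25
    and |D| is tie-free; otherwise the normal approximation with
    tie-corrected variance and continuity correction.  ``greater`` means
    Y tends to exceed X (positive differences).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, alternative, method="degenerate")
    abs_d = np.abs(d)
    ranks = sps.rankdata(abs_d)
    w = float(ranks[d > 0].sum())
    _, tie_counts = np.unique(abs_d, return_counts=True)
    tie_free = bool(np.all(tie_counts == 1))
    if tie_free and n <= EXACT_N_MAX:
        p = _exact_p(w, n, alternative)
        method = "exact"
    else:
        p = _normal_approx_p(w, n, tie_counts, alternative)
        method = "normal_approx"
    return TestResult(w, p, int(n), alternative, method)


def _ks_distance_from_normal(x: np.ndarray) -> float:
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    z = np.sort((x - mean) / sd)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors_test(
    x: Sequence[float],
    n_sims: int = 10_000,
    rng: np.random.Generator | int | None = 0,
) -> TestResult:
    """Kolmogorov-Lilliefors normality test with a Monte-Carlo null.

    The KS distance is computed against the normal CDF with mean and sd
    estimated from the sample; because that distance is parameter-free
    under the null, the p-value is simulated from standard-normal samples
    of the same size.  p = (#{D_sim >= D} + 1) / (n_sims + 1).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("lilliefors_test requires n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance sample")
    d_obs = _ks_distance_from_normal(x)
    rng = np.random.default_rng(rng)
    count = 0
    chunk = max(1, min(n_sims, 50_000_000 // max(n, 1) // 8))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        sims = rng.standard_normal((m, n))
        means = sims.mean(axis=1, keepdims=True)
        sds = sims.std(axis=1, ddof=1, keepdims=True)
        z = np.sort((sims - means) / sds, axis=1)
        cdf = sps.norm.cdf(z)
        i = np.arange(1, n + 1)
        d_plus = np.max(i / n - cdf, axis=1)
        d_minus = np.max(cdf - (i - 1) / n, axis=1)
        d_sim = np.maximum(d_plus, d_minus)
        count += int(np.sum(d_sim >= d_obs))
        done += m
    p = (count + 1) / (n_sims + 1)
    return TestResult(d_obs, p, int(n), "two_sided", method=f"lilliefors_mc{n_sims}")


def spearman_RS(r_ranks: Sequence[float], s_ranks: Sequence[float]) -> float:
    """R_S = 1 - 6*sum(d^2) / (n(n^2-1)) on two rank vectors (tie-free)."""
    r = np.asarray(r_ranks, dtype=float)
    s = np.asarray(s_ranks, dtype=float)
    if r.shape != s.shape:
        raise ValueError("rank vectors differ in length")
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 ranks")
    d2 = float(np.sum((r - s) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def spearman_test(
    a: Sequence[float], b: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Spearman correlation with the t(n-2) approximation for T.

    Mid-ranks for ties; when ties are present the rank-difference formula
    is replaced by the product-moment correlation of the rank vectors (the
    two are identical for tie-free data).  |R_S| = 1 is reported at the
    permutation-enumeration limit, the smallest attainable p.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    n = a.size
    if n < 3:
        raise ValueError("spearman_test requires n >= 3")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    ties = len(np.unique(a)) < n or len(np.unique(b)) < n
    if ra.std() == 0 or rb.std() == 0:
        raise ValueError("zero rank variance (constant input)")
    if ties:
        rs = float(np.corrcoef(ra, rb)[0, 1])
    else:
        rs = spearman_RS(ra, rb)
    rs = float(np.clip(rs, -1.0, 1.0))
    if abs(rs) >= 1.0:
        limit = 1.0 / math.factorial(n)
        if alternative == "two_sided":
            p = min(1.0, 2.0 * limit)
        elif alternative == "greater":
            p = limit if rs > 0 else 1.0
        else:
            p = limit if rs < 0 else 1.0
        return TestResult(rs, p, int(n), alternative, method="enumeration_limit")
    t = rs * math.sqrt((n - 2) / (1.0 - rs**2))
    if alternative == "greater":
        p = float(sps.t.sf(t, df=n - 2))
    elif alternative == "less":
        p = float(sps.t.cdf(t, df=n - 2))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(rs, min(1.0, p), int(n), alternative, method="t_approx")


UPDOWN = "updown"
STAT_REGION_CLASSES = ("coding", "intronic", UPDOWN)


def _stat_class_mask(region_class: str, classes: pd.Series) -> pd.Series:
    if region_class == UPDOWN:
        return classes.isin(("upstream", "downstream"))
    return classes == region_class


@dataclass
class PairedContrast:
    """Per-transcript (X_i, Y_i) pairs: carrier vs non-carrier mean TPM."""

    region_class: str
    cnv_type: str
    transcript_ids: list[str]
    x_carrier: np.ndarray
    y_noncarrier: np.ndarray
    carrier_counts: np.ndarray

    @property
    def n(self) -> int:
        return len(self.transcript_ids)


def carriers_by_transcript(
    overlap_table: pd.DataFrame, region_class: str, cnv_type: str
) -> dict[str, set[str]]:
    """transcript_id -> set of carrier animal ids for one (class, type) cell."""
    mask = (overlap_table["cnv_type"] == cnv_type) & _stat_class_mask(
        region_class, overlap_table["region_class"]
    )
    sub = overlap_table.loc[mask, ["transcript_id", "animal_id"]]
    out: dict[str, set[str]] = {}
    for tid, animal in sub.itertuples(index=False):
        out.setdefault(tid, set()).add(animal)
    return out


def build_contrast(
    expression: ExpressionMatrix,
    overlap_table: pd.DataFrame,
    region_class: str,
    cnv_type: str,
    min_carriers: int = 1,
    max_carriers: int = 5,
) -> PairedContrast:
    """Carrier/non-carrier paired means for one (region class, CNV type).

    A carrier is an animal with >= 1 validated CNV of ``cnv_type``
    classified to the transcript in ``region_class``.  Transcripts whose
    carrier count falls outside [min_carriers, max_carriers] (default 1-5
    of the 6 animals) are excluded, as are transcripts absent from the
    expression matrix.
    """
    samples = list(expression.sample_ids)
    carr = carriers_by_transcript(overlap_table, region_class, cnv_type)
    tids, xs, ys, ks = [], [], [], []
    tpm = expression.tpm
    for tid in sorted(carr):
        if tid not in tpm.index:
            continue
        carriers = sorted(carr[tid] & set(samples))
        k = len(carriers)
        if not (min_carriers <= k <= min(max_carriers, len(samples) - 1)):
            continue
        noncarriers = [s for s in samples if s not in carr[tid]]
        row = tpm.loc[tid]
        tids.append(tid)
        xs.append(float(row[carriers].mean()))
        ys.append(float(row[noncarriers].mean()))
        ks.append(k)
    return PairedContrast(
        region_class=region_class,
        cnv_type=cnv_type,
        transcript_ids=tids,
        x_carrier=np.asarray(xs),
        y_noncarrier=np.asarray(ys),
        carrier_counts=np.asarray(ks, dtype=int),
    )


def test_contrast(contrast: PairedContrast, alternative: str = "two_sided") -> dict:
    """Signed-rank test of the paired contrast, with direction reporting.

    Returns a JSON-ready dict; with n = 0 the test is refused and
    ``p_value`` is None.
    """
    if contrast.n == 0:
        return {
            "region_class": contrast.region_class,
            "cnv_type": contrast.cnv_type,
            "n": 0,
            "statistic": None,
            "p_value": None,
            "direction": None,
            "message": "no eligible transcripts (n=0); test refused",
        }
    res = wilcoxon_test(contrast.x_carrier, contrast.y_noncarrier, alternative)
    med = float(np.median(contrast.y_noncarrier - contrast.x_carrier))
    direction = (
        "lower_in_carriers" if med > 0 else "higher_in_carriers" if med < 0 else "none"
    )
    return {
        "region_class": contrast.region_class,
        "cnv_type": contrast.cnv_type,
        "n": contrast.n,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "direction": direction,
        "method": res.method,
    }


def animal_effect_control(
    expression: ExpressionMatrix,
    overlap_table: pd.DataFrame,
    n_reps: int = 500,
    n_transcripts_per_rep: int = 100,
    rng: np.random.Generator | int | None = 0,
    alpha: float = 0.05,
) -> dict:
    """Random-split control for a shared animal effect.

    From the pool of transcripts overlapping no CNV in any animal, each
    repetition samples ``n_transcripts_per_rep`` transcripts, divides the
    six animals at random into two groups of three (one division per
    repetition, shared by all its transcripts, so a genuine animal effect
    shifts every pair the same way), pairs the per-transcript group means,
    and applies the signed-rank test.  The summary reports the fraction of
    repetitions significant at ``alpha`` and the median p.
    """
    rng = np.random.default_rng(rng)
    hit = set(overlap_table["transcript_id"].unique())
    pool = [t for t in expression.transcript_ids if t not in hit]
    if not pool:
        raise ValueError("no CNV-free transcripts available for the control")
    tpm = expression.tpm
    n_samples = tpm.shape[1]
    half = n_samples // 2
    values = tpm.loc[pool].to_numpy()
    p_values = np.empty(n_reps)
    for rep in range(n_reps):
        take = min(n_transcripts_per_rep, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        sub = values[idx]
        perm = rng.permutation(n_samples)
        g1 = sub[:, perm[:half]].mean(axis=1)
        g2 = sub[:, perm[half : 2 * half]].mean(axis=1)
        p_values[rep] = wilcoxon_test(g1, g2).p_value
    return {
        "n_reps": int(n_reps),
        "n_transcripts_per_rep": int(min(n_transcripts_per_rep, len(pool))),
        "pool_size": len(pool),
        "fraction_significant": float(np.mean(p_values < alpha)),
        "median_p": float(np.median(p_values)),
        "p_values": p_values,
    }


def coverage_expression_correlation(
    expression: ExpressionMatrix,
    overlap_table: pd.DataFrame,
    region_classes: Sequence[str] = ("intronic", "coding"),
    cnv_types: Sequence[str] = ("deletion", "duplication"),
    min_carriers: int = 1,
    max_carriers: int = 5,
    alternative: str = "two_sided",
) -> pd.DataFrame:
    """Per-animal Spearman correlation between percent-of-transcript covered
    and the carrier/non-carrier expression difference.

    For each (animal, CNV type, region class) cell: transcripts where the
    focal animal is a carrier (and the total carrier count is within the
    1-5 window); x = percent of the transcript body covered by the focal
    animal's calls, y = mean TPM of carriers minus mean TPM of
    non-carriers.  Cells with n < 3 or constant ranks are not computable.
    """
    samples = list(expression.sample_ids)
    tpm = expression.tpm
    rows = []
    for cnv_type in cnv_types:
        for region_class in region_classes:
            carr = carriers_by_transcript(overlap_table, region_class, cnv_type)
            mask = (overlap_table["cnv_type"] == cnv_type) & _stat_class_mask(
                region_class, overlap_table["region_class"]
            )
            sub = overlap_table.loc[mask]
            for animal in samples:
                own = sub[sub["animal_id"] == animal]
                pct = dict(zip(own["transcript_id"], own["percent_covered"]))
                xs, ys = [], []
                for tid, p in sorted(pct.items()):
                    if tid not in tpm.index:
                        continue
                    carriers = sorted(carr[tid])
                    k = len(carriers)
                    if not (min_carriers <= k <= min(max_carriers, len(samples) - 1)):
                        continue
                    noncarriers = [s for s in samples if s not in carr[tid]]
                    row = tpm.loc[tid]
                    xs.append(p)
                    ys.append(float(row[carriers].mean() - row[noncarriers].mean()))
                entry = {
                    "animal_id": animal,
                    "cnv_type": cnv_type,
                    "region_class": region_class,
                    "n": len(xs),
                }
                try:
                    res = spearman_test(xs, ys, alternative)
                    entry.update(r_s=res.statistic, p_value=res.p_value)
                except ValueError:
                    entry.update(r_s=np.nan, p_value=np.nan)
                rows.append(entry)
    return pd.DataFrame(rows)


def length_expression_correlation(
    transcripts: TranscriptSet, expression: ExpressionMatrix, alternative: str = "two_sided"
) -> TestResult:
    """Spearman correlation between transcript body length and mean TPM."""
    mean_tpm = expression.mean_per_transcript()
    lengths = transcripts.body_lengths()
    common = [t for t in lengths.index if t in mean_tpm.index]
    if len(common) < 3:
        raise ValueError("need at least 3 transcripts with expression values")
    return spearman_test(
        lengths.loc[common].to_numpy(), mean_tpm.loc[common].to_numpy(), alternative
    )
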