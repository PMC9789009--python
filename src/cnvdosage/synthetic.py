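"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a six-animal cohort: a small multi-chromosome
genome with assembly gaps, a transcriptome of strand-aware multi-exon
transcripts, planted polymorphic deletions and duplications with truncated
log-normal lengths, two imperfect caller views of the truth (read-depth
calls rounded to a 100-bp breakpoint grid; split-read calls with base-pair
jitter; independent false-positive/false-negative rates), and a TPM
expression matrix in which pre-normalization abundance decays
exponentially with transcript length and carriers of a planted CNV see a
multiplicative dosage effect.

Ground truth is retained for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from . import io_formats
from .annotation import MULTI_REGION, classify
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
    "SimulationConfig",
    "TruthRecord",
    "SyntheticDataset",
    "generate_genome",
    "generate_transcriptome",
    "plant_cnvs",
    "emulate_callers",
    "generate_expression",
    "generate_cohort_expression",
    "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the six-boar design: per-animal deletion counts of
    order 551-730 and duplication counts of order 619-693, deletion
    lengths 300-530,600 bp (log-normal body around a ~1.5 kb median),
    duplication lengths 900-346,200 bp, read-depth breakpoints on a 100-bp
    grid, and a length-expression decay calibrated so a large cohort shows
    a Spearman correlation near -0.27 between transcript length and mean
    TPM.
    """

    n_animals: int = 6
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"1": 50_000_000, "2": 45_000_000, "3": 35_000_000}
    )
    gap_fraction: float = 0.01
    gap_mean_length: int = 20_000

    n_transcripts: int = 2500
    exon_count_mean: float = 6.0  # geometric, >= 1
    exon_length_log_mean: float = math.log(300.0)
    exon_length_log_sd: float = 1.0
    intron_length_log_mean: float = math.log(1400.0)
    intron_length_log_sd: float = 0.9

    deletion_length_range: tuple[int, int] = (300, 530_600)
    deletion_length_log_mean: float = math.log(1500.0)
    deletion_length_log_sd: float = 1.4
    duplication_length_range: tuple[int, int] = (900, 346_200)
    duplication_length_log_mean: float = math.log(5000.0)
    duplication_length_log_sd: float = 1.35
    expected_deletions_per_animal: int = 640
    expected_duplications_per_animal: int = 655
    carrier_frequency: float = 0.5
    targeted_fraction: float = 0.7  # fraction of loci placed inside one region class

    deletion_multiplier: float = 0.5  # delta in [0, 1]; 0 = complete loss
    duplication_multiplier: float = 1.0  # gamma > 0; < 1 emulates dosage rebalancing
    proportional_dosage: bool = False

    length_decay_rate: float = 3.9e-5  # lambda, per bp of transcript body
    base_log_sd: float = 1.5
    noise_log_sd: float = 0.5  # sigma
    animal_effect_log_sd: float = 0.05

    breakpoint_grid: int = 100
    split_read_jitter_sd: float = 3.0
    rd_fp_rate: float = 0.05
    rd_fn_rate: float = 0.05
    sr_fp_rate: float = 0.05
    sr_fn_rate: float = 0.05

    n_cohort_samples: int = 143
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.deletion_multiplier <= 1):
            raise ValueError("deletion_multiplier must be in [0, 1]")
        if self.duplication_multiplier <= 0:
            raise ValueError("duplication_multiplier must be > 0")
        if self.noise_log_sd < 0:
            raise ValueError("noise_log_sd must be >= 0")
        if not (0 <= self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in [0, 1)")
        if not (0 < self.carrier_frequency <= 1):
            raise ValueError("carrier_frequency must be in (0, 1]")
        for lo, hi in (self.deletion_length_range, self.duplication_length_range):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must be positive and ordered")

    @property
    def animal_ids(self) -> list[str]:
        return [f"animal{i + 1}" for i in range(self.n_animals)]


@dataclass(frozen=True)
class TruthRecord:
    """One planted CNV locus with its carriers and expression consequences."""

    interval: GenomicInterval
    cnv_type: CnvType
    carrier_animals: tuple[str, ...]
    affected: tuple[tuple[str, str], ...]  # (transcript_id, region class or multi_region)
    multipliers: tuple[tuple[str, float], ...]  # (transcript_id, applied multiplier)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["genome", "transcriptome", "cnvs", "callers", "expression", "cohort"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, GapTrack]:
    """Chromosome table plus disjoint assembly gaps at ``gap_fraction``."""
    chrom_table = pd.DataFrame(
        {"chrom": list(config.chrom_lengths), "length": list(config.chrom_lengths.values())}
    )
    gaps: list[GenomicInterval] = []
    for chrom, length in config.chrom_lengths.items():
        target = config.gap_fraction * length
        placed: list[tuple[int, int]] = []
        total = 0
        attempts = 0
        while total < target and attempts < 10_000:
            attempts += 1
            glen = int(rng.exponential(config.gap_mean_length)) + 1000
            glen = min(glen, length // 10)
            start = int(rng.integers(0, max(1, length - glen)))
            if any(start < e and s < start + glen for s, e in placed):
                continue
            placed.append((start, start + glen))
            total += glen
        gaps.extend(GenomicInterval(chrom, s, e) for s, e in sorted(placed))
    return chrom_table, GapTrack(gaps)


def _sample_trunc_lognormal(
    rng: np.random.Generator, log_mean: float, log_sd: float, lo: float, hi: float
) -> int:
    for _ in range(200):
        x = rng.lognormal(log_mean, log_sd)
        if lo <= x <= hi:
            return int(round(x))
    return int(round(min(max(rng.lognormal(log_mean, log_sd), lo), hi)))


def generate_transcriptome(
    genome: tuple[pd.DataFrame, GapTrack],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TranscriptSet:
    """Place non-overlapping multi-exon transcripts outside assembly gaps."""
    chrom_table, gaps = genome
    chroms = list(chrom_table["chrom"])
    lengths = np.asarray(chrom_table["length"], dtype=float)
    weights = lengths / lengths.sum()
    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    transcripts = []
    n_digits = max(5, len(str(config.n_transcripts)))
    for i in range(config.n_transcripts):
        tid = f"T{i + 1:0{n_digits}d}"
        placed = None
        for _ in range(500):
            chrom = str(rng.choice(chroms, p=weights))
            chrom_len = int(config.chrom_lengths[chrom])
            k = 1 + int(rng.geometric(1.0 / config.exon_count_mean)) - 1
            k = max(1, min(k, 40))
            exon_lens = [
                _sample_trunc_lognormal(
                    rng, config.exon_length_log_mean, config.exon_length_log_sd, 30, 20_000
                )
                for _ in range(k)
            ]
            intron_lens = [
                _sample_trunc_lognormal(
                    rng,
                    config.intron_length_log_mean,
                    config.intron_length_log_sd,
                    60,
                    200_000,
                )
                for _ in range(k - 1)
            ]
            span = sum(exon_lens) + sum(intron_lens)
            if span >= chrom_len:
                continue
            start = int(rng.integers(0, chrom_len - span))
            iv = GenomicInterval(chrom, start, start + span)
            if gaps.overlaps(iv) or occupied[chrom].overlaps(start, start + span):
                continue
            exons = []
            pos = start
            for j in range(k):
                exons.append(GenomicInterval(chrom, pos, pos + exon_lens[j]))
                pos += exon_lens[j]
                if j < k - 1:
                    pos += intron_lens[j]
            strand = "+" if rng.random() < 0.5 else "-"
            placed = TranscriptModel(tid, chrom, strand, tuple(exons))
            occupied[chrom].addi(start, start + span)
            break
        if placed is None:
            raise RuntimeError(
                f"could not place transcript {tid}; genome too small or too gappy"
            )
        transcripts.append(placed)
    return TranscriptSet(transcripts)


def _length_params(config: SimulationConfig, cnv_type: CnvType):
    if cnv_type == CnvType.DELETION:
        return (
            config.deletion_length_log_mean,
            config.deletion_length_log_sd,
            config.deletion_length_range,
        )
    return (
        config.duplication_length_log_mean,
        config.duplication_length_log_sd,
        config.duplication_length_range,
    )


def plant_cnvs(
    genome: tuple[pd.DataFrame, GapTrack],
    transcripts: TranscriptSet,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[CnvCall]], list[TruthRecord]]:
    """Plant polymorphic CNV loci and assign carriers per animal.

    A fraction ``targeted_fraction`` of loci is placed entirely inside one
    region class (an exon, an intron, or a flank) of a random transcript so
    that single-class annotations dominate; the rest land uniformly.  Each
    animal carries a locus independently with ``carrier_frequency``.
    """
    chrom_table, gaps = genome
    chroms = list(chrom_table["chrom"])
    lengths = np.asarray(chrom_table["length"], dtype=float)
    weights = lengths / lengths.sum()
    tx_list = list(transcripts)
    chrom_len = dict(config.chrom_lengths)

    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    for t in tx_list:
        trees[t.chrom].addi(max(0, t.start - 5000), t.end + 5000, t.transcript_id)
    placed_by_type: dict[CnvType, dict[str, IntervalTree]] = {
        CnvType.DELETION: {c: IntervalTree() for c in chroms},
        CnvType.DUPLICATION: {c: IntervalTree() for c in chroms},
    }

    def targeted_interval(cnv_type: CnvType) -> Optional[GenomicInterval]:
        t = tx_list[int(rng.integers(len(tx_list)))]
        regions: list[GenomicInterval] = []
        regions.extend(t.exons)
        regions.extend(t.introns)
        flank = 5000
        lo = max(0, t.start - flank)
        if lo < t.start:
            regions.append(GenomicInterval(t.chrom, lo, t.start))
        hi = min(chrom_len[t.chrom], t.end + flank)
        if hi > t.end:
            regions.append(GenomicInterval(t.chrom, t.end, hi))
        region = regions[int(rng.integers(len(regions)))]
        log_mean, log_sd, (range_lo, range_hi) = _length_params(config, cnv_type)
        hi_eff = min(range_hi, region.length)
        if hi_eff < range_lo:
            return None
        length = _sample_trunc_lognormal(rng, log_mean, log_sd, range_lo, hi_eff)
        length = min(length, region.length)
        start = region.start + int(rng.integers(0, region.length - length + 1))
        return GenomicInterval(region.chrom, start, start + length)

    def uniform_interval(cnv_type: CnvType) -> GenomicInterval:
        log_mean, log_sd, (range_lo, range_hi) = _length_params(config, cnv_type)
        length = _sample_trunc_lognormal(rng, log_mean, log_sd, range_lo, range_hi)
        chrom = str(rng.choice(chroms, p=weights))
        length = min(length, chrom_len[chrom] - 1)
        start = int(rng.integers(0, chrom_len[chrom] - length))
        return GenomicInterval(chrom, start, start + length)

    animals = config.animal_ids
    truth_records: list[TruthRecord] = []
    truth_by_animal: dict[str, list[CnvCall]] = {a: [] for a in animals}

    for cnv_type, expected in (
        (CnvType.DELETION, config.expected_deletions_per_animal),
        (CnvType.DUPLICATION, config.expected_duplications_per_animal),
    ):
        n_loci = int(round(expected / config.carrier_frequency))
        for _ in range(n_loci):
            iv = None
            for attempt in range(300):
                cand = (
                    targeted_interval(cnv_type)
                    if rng.random() < config.targeted_fraction
                    else uniform_interval(cnv_type)
                )
                if cand is None:
                    continue
                if gaps.overlaps(cand):
                    continue
                if attempt < 200 and placed_by_type[cnv_type][cand.chrom].overlaps(
                    cand.start, cand.end
                ):
                    continue
                iv = cand
                break
            if iv is None:
                continue
            placed_by_type[cnv_type][iv.chrom].addi(iv.start, iv.end)
            carriers = tuple(a for a in animals if rng.random() < config.carrier_frequency)

            affected = []
            multipliers = []
            for hit in sorted(trees[iv.chrom][iv.start : iv.end], key=lambda h: h.data):
                t = transcripts[hit.data]
                cls = classify(iv, t, 5000, chrom_len.get(t.chrom))
                if cls is None:
                    continue
                affected.append((t.transcript_id, cls))
                body_bp = iv.overlap_bp(t.span)
                if body_bp > 0:
                    base_mult = (
                        config.deletion_multiplier
                        if cnv_type == CnvType.DELETION
                        else config.duplication_multiplier
                    )
                    if config.proportional_dosage:
                        frac = body_bp / t.body_length
                        mult = 1.0 + (base_mult - 1.0) * frac
                    else:
                        mult = base_mult
                    multipliers.append((t.transcript_id, mult))
            truth_records.append(
                TruthRecord(iv, cnv_type, carriers, tuple(affected), tuple(multipliers))
            )
            for a in carriers:
                truth_by_animal[a].append(
                    CnvCall(iv, cnv_type, a, Caller.READ_DEPTH)
                )
    return truth_by_animal, truth_records


def _round_to_grid(iv: GenomicInterval, grid: int, chrom_len: int) -> GenomicInterval:
    if grid <= 1:
        return iv
    start = int(round(iv.start / grid)) * grid
    end = int(round(iv.end / grid)) * grid
    if end <= start:
        end = start + grid
    start = max(0, min(start, chrom_len - grid))
    end = min(max(end, start + grid), chrom_len)
    return GenomicInterval(iv.chrom, start, end)


def _jitter(iv: GenomicInterval, sd: float, rng, chrom_len: int) -> GenomicInterval:
    if sd <= 0:
        return iv
    start = iv.start + int(round(rng.normal(0, sd)))
    end = iv.end + int(round(rng.normal(0, sd)))
    start = max(0, start)
    end = min(chrom_len, max(end, start + 1))
    return GenomicInterval(iv.chrom, start, end)


def emulate_callers(
    truth_by_animal: Mapping[str, Sequence[CnvCall]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[CnvCall]], dict[str, list[CnvCall]]]:
    """Produce the read-depth and split-read views of the truth.

    Read-depth breakpoints are rounded to ``breakpoint_grid``; split-read
    breakpoints get Gaussian jitter.  False negatives drop true calls and
    false positives inject random calls, independently per caller.
    """
    chrom_len = dict(config.chrom_lengths)
    chroms = list(chrom_len)
    lengths = np.asarray([chrom_len[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    def fp_call(animal: str, caller: Caller, cnv_type: CnvType) -> CnvCall:
        log_mean, log_sd, (lo, hi) = _length_params(config, cnv_type)
        length = _sample_trunc_lognormal(rng, log_mean, log_sd, lo, hi)
        chrom = str(rng.choice(chroms, p=weights))
        length = min(length, chrom_len[chrom] - 1)
        start = int(rng.integers(0, chrom_len[chrom] - length))
        iv = GenomicInterval(chrom, start, start + length)
        if caller is Caller.READ_DEPTH:
            iv = _round_to_grid(iv, config.breakpoint_grid, chrom_len[chrom])
        return CnvCall(iv, cnv_type, animal, caller)

    rd: dict[str, list[CnvCall]] = {}
    sr: dict[str, list[CnvCall]] = {}
    for animal in sorted(truth_by_animal):
        calls = list(truth_by_animal[animal])
        rd_calls, sr_calls = [], []
        for c in calls:
            clen = chrom_len[c.interval.chrom]
            if rng.random() >= config.rd_fn_rate:
                rd_calls.append(
                    CnvCall(
                        _round_to_grid(c.interval, config.breakpoint_grid, clen),
                        c.cnv_type,
                        animal,
                        Caller.READ_DEPTH,
                    )
                )
            if rng.random() >= config.sr_fn_rate:
                sr_calls.append(
                    CnvCall(
                        _jitter(c.interval, config.split_read_jitter_sd, rng, clen),
                        c.cnv_type,
                        animal,
                        Caller.SPLIT_READ,
                    )
                )
        for cnv_type in (CnvType.DELETION, CnvType.DUPLICATION):
            n_type = sum(1 for c in calls if c.cnv_type == cnv_type)
            for _ in range(rng.binomial(n_type, config.rd_fp_rate) if n_type else 0):
                rd_calls.append(fp_call(animal, Caller.READ_DEPTH, cnv_type))
            for _ in range(rng.binomial(n_type, config.sr_fp_rate) if n_type else 0):
                sr_calls.append(fp_call(animal, Caller.SPLIT_READ, cnv_type))
        key = lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type.value)
        rd[animal] = sorted(rd_calls, key=key)
        sr[animal] = sorted(sr_calls, key=key)
    return rd, sr


def _abundance(
    transcripts: TranscriptSet,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_samples: int,
    multiplier: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    tids = transcripts.ids
    lengths = transcripts.body_lengths().loc[tids].to_numpy(dtype=float)
    base = rng.lognormal(0.0, config.base_log_sd, size=len(tids))
    animal_factor = np.exp(rng.normal(0.0, config.animal_effect_log_sd, size=n_samples))
    noise = rng.lognormal(0.0, config.noise_log_sd, size=(len(tids), n_samples))
    ab = (
        base[:, None]
        * np.exp(-config.length_decay_rate * lengths)[:, None]
        * animal_factor[None, :]
        * noise
    )
    if multiplier is not None:
        ab = ab * multiplier
    return pd.DataFrame(ab, index=tids)


def generate_expression(
    transcripts: TranscriptSet,
    truth_records: Sequence[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """TPM matrix for the six animals with planted dosage effects.

    Pre-normalization abundance for transcript i in animal a is
    ``base_i * exp(-lambda * length_i) * animal_a * eps`` with log-normal
    eps; carriers of a planted CNV overlapping the transcript body are
    multiplied by the deletion/duplication multiplier; columns are then
    scaled to sum to one million.
    """
    animals = config.animal_ids
    tid_index = {t: i for i, t in enumerate(transcripts.ids)}
    mult = np.ones((len(tid_index), len(animals)))
    a_index = {a: j for j, a in enumerate(animals)}
    for rec in truth_records:
        for tid, m in rec.multipliers:
            i = tid_index[tid]
            for a in rec.carrier_animals:
                mult[i, a_index[a]] *= m
    ab = _abundance(transcripts, config, rng, len(animals), mult)
    ab.columns = animals
    return ExpressionMatrix.from_abundance(ab)


def generate_cohort_expression(
    transcripts: TranscriptSet,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_samples: Optional[int] = None,
) -> ExpressionMatrix:
    """CNV-free TPM matrix for a larger cohort (length-expression analysis)."""
    n = n_samples if n_samples is not None else config.n_cohort_samples
    ab = _abundance(transcripts, config, rng, n)
    ab.columns = [f"sow{j + 1}" for j in range(n)]
    return ExpressionMatrix.from_abundance(ab)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    chrom_table: pd.DataFrame
    gaps: GapTrack
    transcripts: TranscriptSet
    truth_by_animal: dict[str, list[CnvCall]]
    truth_records: list[TruthRecord]
    rd_calls: dict[str, list[CnvCall]]
    sr_calls: dict[str, list[CnvCall]]
    expression: ExpressionMatrix


def simulate_dataset(config: SimulationConfig, seed: Optional[int] = None) -> SyntheticDataset:
    """Run every generator stage with isolated RNG streams.

    Each stage draws from its own stream spawned from the master seed, so
    e.g. changing false-positive rates does not shift transcript placement.
    """
    seed = config.seed if seed is None else seed
    streams = _streams(seed)
    genome = generate_genome(config, streams["genome"])
    transcripts = generate_transcriptome(genome, config, streams["transcriptome"])
    truth_by_animal, truth_records = plant_cnvs(
        genome, transcripts, config, streams["cnvs"]
    )
    rd, sr = emulate_callers(truth_by_animal, config, streams["callers"])
    expression = generate_expression(
        transcripts, truth_records, config, streams["expression"]
    )
    return SyntheticDataset(
        config=config,
        chrom_table=genome[0],
        gaps=genome[1],
        transcripts=transcripts,
        truth_by_animal=truth_by_animal,
        truth_records=truth_records,
        rd_calls=rd,
        sr_calls=sr,
        expression=expression,
    )


def write_dataset(dataset: SyntheticDataset, outdir, seed: Optional[int] = None) -> None:
    """Write the dataset through io_formats plus truth TSV and metadata YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.chrom_table.to_csv(out / "genome.tsv", sep="\t", index=False)
    io_formats.write_bed_gaps(dataset.gaps, out / "gaps.bed")
    io_formats.write_gff3_transcripts(dataset.transcripts, out / "transcripts.gff3")
    for animal in sorted(dataset.rd_calls):
        io_formats.write_cnv_calls(
            dataset.rd_calls[animal], out / f"calls_rd_{animal}.txt", "read_depth_table"
        )
        io_formats.write_cnv_calls(
            dataset.sr_calls[animal], out / f"calls_sr_{animal}.txt", "split_read_table"
        )
    io_formats.write_tpm_table(dataset.expression, out / "expression.tsv")
    rows = []
    for rec in dataset.truth_records:
        rows.append(
            {
                "chrom": rec.interval.chrom,
                "start": rec.interval.start,
                "end": rec.interval.end,
                "cnv_type": rec.cnv_type.value,
                "carriers": ",".join(rec.carrier_animals),
                "affected": ";".join(f"{t}:{c}" for t, c in rec.affected),
                "multipliers": ";".join(f"{t}:{m:g}" for t, m in rec.multipliers),
            }
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "cnv_type", "carriers", "affected", "multipliers"],
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    meta = {
        "seed": dataset.config.seed if seed is None else seed,
        "config": _config_to_dict(dataset.config),
    }
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["chrom_lengths"] = dict(config.chrom_lengths)
    d["deletion_length_range"] = list(config.deletion_length_range)
    d["duplication_length_range"] = list(config.duplication_length_range)
    return d
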