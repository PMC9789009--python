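"""End-to-end orchestration: inputs -> consensus -> annotation -> statistics.

A run produces a reproducible report bundle: validated CNV BED, filter
audit TSV, overlap TSV, region-tally TSV, the six paired signed-rank tests
({deletion, duplication} x {coding, intronic, updown}) as JSON, the
random-split animal-effect control, the per-animal coverage-expression
correlation table, and the length-expression correlation.  With a fixed
seed the whole bundle is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io_formats
from .annotation import annotate, tally_regions
from .consensus import ValidationConfig, run_consensus
from .core import ExpressionMatrix, GapTrack, TranscriptSet
from .stats import (
    STAT_REGION_CLASSES,
    animal_effect_control,
    build_contrast,
    coverage_expression_correlation,
    length_expression_correlation,
    lilliefors_test,
    test_contrast,
)
from .synthetic import (
    SimulationConfig,
    SyntheticDataset,
    generate_cohort_expression,
    simulate_dataset,
    write_dataset,
    _config_to_dict,
    _streams,
)

__all__ = ["RunConfig", "run", "analyze", "AnalysisResult"]


@dataclass
class RunConfig:
    """Everything one run needs; echoed verbatim into the output bundle.

    Either ``simulation`` is set (synthetic mode) or ``paths`` maps the
    documented input files: ``rd_calls``/``sr_calls`` (animal -> file),
    ``gaps`` (BED), ``gff3``, ``tpm`` (TSV).
    """

    simulation: Optional[SimulationConfig] = None
    paths: Optional[dict] = None
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    flank_bp: int = 5000
    min_carriers: int = 1
    max_carriers: int = 5
    alternative: str = "two_sided"
    n_reps: int = 500
    n_transcripts_per_rep: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.paths is None):
            raise ValueError("exactly one of simulation/paths must be set")
        if self.flank_bp < 0 or self.n_reps < 1:
            raise ValueError("flank_bp must be >= 0 and n_reps >= 1")
        if not (1 <= self.min_carriers <= self.max_carriers):
            raise ValueError("carrier window must satisfy 1 <= min <= max")

    def to_dict(self) -> dict:
        d = {
            "validation": asdict(self.validation),
            "flank_bp": self.flank_bp,
            "min_carriers": self.min_carriers,
            "max_carriers": self.max_carriers,
            "alternative": self.alternative,
            "n_reps": self.n_reps,
            "n_transcripts_per_rep": self.n_transcripts_per_rep,
            "seed": self.seed,
        }
        if self.simulation is not None:
            d["simulation"] = _config_to_dict(self.simulation)
        if self.paths is not None:
            d["paths"] = {
                k: (dict(v) if isinstance(v, Mapping) else str(v))
                for k, v in self.paths.items()
            }
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        sim = d.get("simulation")
        if sim is not None:
            sim = dict(sim)
            if "chrom_lengths" in sim:
                sim["chrom_lengths"] = {str(k): int(v) for k, v in sim["chrom_lengths"].items()}
            for key in ("deletion_length_range", "duplication_length_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        val = ValidationConfig(**d.get("validation", {}))
        return RunConfig(
            simulation=sim,
            paths=d.get("paths"),
            validation=val,
            flank_bp=d.get("flank_bp", 5000),
            min_carriers=d.get("min_carriers", 1),
            max_carriers=d.get("max_carriers", 5),
            alternative=d.get("alternative", "two_sided"),
            n_reps=d.get("n_reps", 500),
            n_transcripts_per_rep=d.get("n_transcripts_per_rep", 100),
            seed=d.get("seed", 0),
        )

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh))


@dataclass
class AnalysisResult:
    """In-memory results of one full analysis."""

    audit: pd.DataFrame
    tally: pd.DataFrame
    overlaps: pd.DataFrame
    paired_tests: list[dict]
    animal_effect: dict
    coverage_correlation: pd.DataFrame
    length_correlation: dict
    n_discarded: int


def _load_inputs(config: RunConfig):
    p = config.paths
    rd = {a: io_formats.read_cnv_calls(f, "read_depth_table", a) for a, f in sorted(p["rd_calls"].items())}
    sr = {a: io_formats.read_cnv_calls(f, "split_read_table", a) for a, f in sorted(p["sr_calls"].items())}
    gaps = io_formats.read_bed_gaps(p["gaps"]) if p.get("gaps") else GapTrack()
    transcripts = io_formats.read_gff3_transcripts(p["gff3"])
    expression = io_formats.read_tpm_table(p["tpm"])
    return rd, sr, gaps, transcripts, expression, None, None


def analyze(config: RunConfig) -> AnalysisResult:
    """Run consensus, annotation and all statistics in memory."""
    if config.simulation is not None:
        ds = simulate_dataset(config.simulation, seed=config.seed)
        rd, sr, gaps, transcripts, expression = (
            ds.rd_calls,
            ds.sr_calls,
            ds.gaps,
            ds.transcripts,
            ds.expression,
        )
        chrom_lengths = dict(config.simulation.chrom_lengths)
        cohort = generate_cohort_expression(
            transcripts, config.simulation, _streams(config.seed)["cohort"]
        )
    else:
        rd, sr, gaps, transcripts, expression, chrom_lengths, cohort = _load_inputs(config)

    validated, audit = run_consensus(rd, sr, gaps, config.validation)
    ann = annotate(validated, transcripts, config.flank_bp, chrom_lengths)
    tally = tally_regions(ann)

    paired = []
    cell_idx = 0
    for cnv_type in ("deletion", "duplication"):
        for region_class in STAT_REGION_CLASSES:
            contrast = build_contrast(
                expression,
                ann.overlaps,
                region_class,
                cnv_type,
                config.min_carriers,
                config.max_carriers,
            )
            entry = test_contrast(contrast, config.alternative)
            # normality of the paired differences motivates the rank test
            entry["normality_p"] = None
            if contrast.n >= 4:
                d = contrast.y_noncarrier - contrast.x_carrier
                try:
                    entry["normality_p"] = lilliefors_test(
                        d,
                        n_sims=2000,
                        rng=np.random.default_rng(
                            np.random.SeedSequence([config.seed, 11, cell_idx])
                        ),
                    ).p_value
                except ValueError:
                    pass
            paired.append(entry)
            cell_idx += 1

    control_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    control = animal_effect_control(
        expression,
        ann.overlaps,
        n_reps=config.n_reps,
        n_transcripts_per_rep=config.n_transcripts_per_rep,
        rng=control_rng,
    )

    cov_corr = coverage_expression_correlation(
        expression,
        ann.overlaps,
        min_carriers=config.min_carriers,
        max_carriers=config.max_carriers,
        alternative=config.alternative,
    )

    length_expr = cohort if cohort is not None else expression
    lec = length_expression_correlation(transcripts, length_expr, config.alternative)
    length_corr = {
        "r_s": lec.statistic,
        "p_value": lec.p_value,
        "n": lec.n,
        "n_samples": len(length_expr.sample_ids),
    }
    return AnalysisResult(
        audit=audit,
        tally=tally,
        overlaps=ann.overlaps,
        paired_tests=paired,
        animal_effect=control,
        coverage_correlation=cov_corr,
        length_correlation=length_corr,
        n_discarded=ann.n_discarded,
    )


def run(config: RunConfig, outdir) -> AnalysisResult:
    """Full run with the report bundle written to ``outdir``.

    Any stage failure leaves a ``FAILED`` marker naming the stage and
    re-raises.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        stage = "inputs"
        if config.simulation is not None:
            ds = simulate_dataset(config.simulation, seed=config.seed)
            write_dataset(ds, out / "inputs", seed=config.seed)

        stage = "analysis"
        result = analyze(config)

        stage = "report"
        if config.simulation is not None:
            validated, _ = run_consensus(
                ds.rd_calls, ds.sr_calls, ds.gaps, config.validation
            )
            all_validated = [c for calls in validated.values() for c in calls]
            io_formats.write_validated_cnvs(all_validated, out / "validated_cnvs.bed")
        result.audit.to_csv(out / "audit.tsv", sep="\t", index=False)
        result.tally.to_csv(out / "region_tally.tsv", sep="\t")
        result.overlaps.to_csv(
            out / "overlaps.tsv", sep="\t", index=False, float_format="%.10g"
        )
        with open(out / "paired_tests.json", "w") as fh:
            json.dump(result.paired_tests, fh, indent=2, sort_keys=True)
        control = {
            k: v for k, v in result.animal_effect.items() if k != "p_values"
        }
        with open(out / "animal_effect.json", "w") as fh:
            json.dump(control, fh, indent=2, sort_keys=True)
        result.coverage_correlation.to_csv(
            out / "coverage_correlation.tsv", sep="\t", index=False, float_format="%.10g"
        )
        with open(out / "length_correlation.json", "w") as fh:
            json.dump(result.length_correlation, fh, indent=2, sort_keys=True)
        _write_log(out / "log.txt", config)
        return result
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_log(path, config: RunConfig) -> None:
    import scipy

    lines = [
        f"cnvdosage {__version__}",
        f"numpy {np.__version__}",
        f"scipy {scipy.__version__}",
        f"pandas {pd.__version__}",
        f"seed {config.seed}",
        f"mode {'synthetic' if config.simulation is not None else 'files'}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
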