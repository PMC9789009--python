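import numpy as np
import pytest

from cnvdosage.core import CnvType
from cnvdosage.stats import build_contrast, length_expression_correlation
from cnvdosage.synthetic import (
    SimulationConfig,
    generate_cohort_expression,
    generate_genome,
    generate_transcriptome,
    simulate_dataset,
    write_dataset,
    _streams,
)
from conftest import small_sim_config


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(deletion_multiplier=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(noise_log_sd=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(gap_fraction=1.0)

    def test_default_emulates_six_animal_cohort(self):
        cfg = SimulationConfig()
        assert cfg.n_animals == 6
        assert cfg.deletion_length_range == (300, 530_600)
        assert cfg.duplication_length_range == (900, 346_200)


class TestGenome:
    def test_zero_gap_fraction_gives_empty_track(self):
        cfg = small_sim_config(gap_fraction=0.0)
        table, gaps = generate_genome(cfg, np.random.default_rng(0))
        assert len(gaps) == 0
        assert list(table["chrom"]) == list(cfg.chrom_lengths)
        assert list(table["length"]) == list(cfg.chrom_lengths.values())

    def test_gap_budget_respected(self):
        cfg = small_sim_config(gap_fraction=0.02)
        _, gaps = generate_genome(cfg, np.random.default_rng(0))
        by_chrom = {}
        for iv in gaps:
            by_chrom[iv.chrom] = by_chrom.get(iv.chrom, 0) + iv.length
        for chrom, total in by_chrom.items():
            assert total < 0.05 * cfg.chrom_lengths[chrom]


class TestTranscriptome:
    def test_requested_count_and_gap_avoidance(self):
        cfg = small_sim_config(n_transcripts=120)
        rngs = _streams(0)
        genome = generate_genome(cfg, rngs["genome"])
        ts = generate_transcriptome(genome, cfg, rngs["transcriptome"])
        assert len(ts) == 120
        _, gaps = genome
        for t in ts:
            assert not gaps.overlaps(t.span)

    def test_round_trip_through_gff3(self, tmp_path, small_dataset):
        from cnvdosage import io_formats

        p = tmp_path / "t.gff3"
        io_formats.write_gff3_transcripts(small_dataset.transcripts, p)
        back = io_formats.read_gff3_transcripts(p)
        assert sorted(back.ids) == sorted(small_dataset.transcripts.ids)


class TestPlanting:
    def test_collapsed_length_range(self):
        cfg = small_sim_config(
            deletion_length_range=(1000, 1000),
            expected_deletions_per_animal=40,
            expected_duplications_per_animal=0,
        )
        ds = simulate_dataset(cfg, seed=3)
        lengths = {
            rec.interval.length
            for rec in ds.truth_records
            if rec.cnv_type == CnvType.DELETION
        }
        assert lengths == {1000}

    def test_planted_lengths_within_configured_ranges(self, small_dataset):
        for rec in small_dataset.truth_records:
            lo, hi = (
                small_dataset.config.deletion_length_range
                if rec.cnv_type == CnvType.DELETION
                else small_dataset.config.duplication_length_range
            )
            assert lo <= rec.interval.length <= hi

    def test_universal_carriers_leave_no_eligible_transcripts(self):
        from cnvdosage.annotation import annotate
        from cnvdosage.consensus import run_consensus

        cfg = small_sim_config(
            carrier_frequency=1.0,
            expected_deletions_per_animal=60,
            expected_duplications_per_animal=0,
            rd_fn_rate=0.0, sr_fn_rate=0.0, rd_fp_rate=0.0, sr_fp_rate=0.0,
        )
        ds = simulate_dataset(cfg, seed=2)
        validated, _ = run_consensus(ds.rd_calls, ds.sr_calls, ds.gaps)
        ann = annotate(validated, ds.transcripts, 5000, dict(cfg.chrom_lengths))
        for rc in ("coding", "intronic", "updown"):
            assert build_contrast(ds.expression, ann.overlaps, rc, "deletion").n == 0


class TestCallerEmulation:
    def test_identity_limit(self):
        cfg = small_sim_config(
            breakpoint_grid=1, split_read_jitter_sd=0.0,
            rd_fp_rate=0.0, rd_fn_rate=0.0, sr_fp_rate=0.0, sr_fn_rate=0.0,
        )
        ds = simulate_dataset(cfg, seed=1)
        key = lambda c: (c.interval, c.cnv_type.value)
        for animal in ds.truth_by_animal:
            truth = sorted(key(c) for c in ds.truth_by_animal[animal])
            assert sorted(key(c) for c in ds.rd_calls[animal]) == truth
            assert sorted(key(c) for c in ds.sr_calls[animal]) == truth

    def test_read_depth_breakpoints_on_grid(self, small_dataset):
        for calls in small_dataset.rd_calls.values():
            for c in calls:
                assert c.interval.start % 100 == 0
                assert c.interval.end % 100 == 0


class TestExpression:
    def test_columns_sum_to_one_million(self, small_dataset):
        sums = small_dataset.expression.tpm.sum(axis=0).to_numpy()
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_noise_free_expression_decreasing_in_length(self):
        cfg = small_sim_config(
            n_transcripts=150, base_log_sd=0.0, noise_log_sd=0.0,
            animal_effect_log_sd=0.0,
            deletion_multiplier=1.0, duplication_multiplier=1.0,
            expected_deletions_per_animal=0, expected_duplications_per_animal=0,
        )
        ds = simulate_dataset(cfg, seed=4)
        lengths = ds.transcripts.body_lengths()
        mean_tpm = ds.expression.mean_per_transcript().loc[lengths.index]
        order = np.argsort(lengths.to_numpy())
        assert np.all(np.diff(mean_tpm.to_numpy()[order]) <= 0)

    def test_full_deletion_zeroes_carrier_expression(self):
        cfg = small_sim_config(deletion_multiplier=0.0)
        ds = simulate_dataset(cfg, seed=6)
        tpm = ds.expression.tpm
        checked = 0
        for rec in ds.truth_records:
            for tid, mult in rec.multipliers:
                if rec.cnv_type != CnvType.DELETION or not rec.carrier_animals:
                    continue
                for animal in rec.carrier_animals:
                    assert tpm.loc[tid, animal] == 0.0
                    checked += 1
            if checked > 20:
                break
        assert checked > 0

    def test_length_correlation_negative_and_sharpens_with_less_noise(self):
        rs = {}
        for sigma in (1.2, 0.1):
            vals = []
            for seed in (1, 2, 3):
                cfg = small_sim_config(noise_log_sd=sigma, n_transcripts=250)
                s = _streams(seed)
                genome = generate_genome(cfg, s["genome"])
                ts = generate_transcriptome(genome, cfg, s["transcriptome"])
                cohort = generate_cohort_expression(ts, cfg, s["cohort"], n_samples=6)
                vals.append(length_expression_correlation(ts, cohort).statistic)
            rs[sigma] = np.mean(vals)
        assert rs[1.2] < 0 and rs[0.1] < 0
        assert abs(rs[0.1]) > abs(rs[1.2])


class TestDeterminism:
    def test_fixed_seed_reproduces_files_byte_identically(self, tmp_path):
        cfg = small_sim_config(n_transcripts=60,
                               expected_deletions_per_animal=25,
                               expected_duplications_per_animal=25)
        for d in ("a", "b"):
            write_dataset(simulate_dataset(cfg, seed=9), tmp_path / d, seed=9)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_rng_stream_isolation(self):
        # changing caller error rates must not move transcript placement
        a = simulate_dataset(small_sim_config(rd_fp_rate=0.0), seed=12)
        b = simulate_dataset(small_sim_config(rd_fp_rate=0.3), seed=12)
        assert a.transcripts.ids == b.transcripts.ids
        assert [t.exons for t in a.transcripts] == [t.exons for t in b.transcripts]
        assert a.truth_records == b.truth_records
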