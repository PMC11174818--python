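"""Model front ends, end-to-end pipeline, and the CLI stages."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from eegstates.cli import main as cli_main
from eegstates.data import CompletenessError, StudyDataset
from eegstates.models import CorrelationDiscrimination, SpectralRangeClassification
from eegstates.pipeline import RunConfig, run_pipeline
from eegstates.simulate import default_two_state_spec, generate_cohort
from eegstates.spectral import collect_peaks


class TestSpectralRangeClassification:
    def test_designated_channels_get_perfect_metrics(self, small_cohort,
                                                     small_peaks):
        _, dataset, truth = small_cohort
        res = SpectralRangeClassification(dataset, groups=("G", "G*")) \
            .fit(peaks=small_peaks)
        for channel, band in truth.designated_channels:
            for group in ("G", "G*"):
                row = res.metrics_for(channel, band, group)
                assert row.accuracy_pct == 100.0
                assert row.mcc == 1.0
                assert (row.fp, row.fn) == (0, 0)

    def test_metrics_table_shape(self, small_cohort, small_peaks):
        _, dataset, _ = small_cohort
        res = SpectralRangeClassification(dataset, groups=("G",)) \
            .fit(peaks=small_peaks)
        assert len(res.metrics) == 19 * 3
        assert set(res.metrics["group"]) == {"G"}

    def test_summary_mentions_discriminators(self, small_cohort, small_peaks):
        _, dataset, _ = small_cohort
        res = SpectralRangeClassification(dataset, groups=("G",)) \
            .fit(peaks=small_peaks)
        text = res.summary()
        assert "F7 (theta)" in text and "Fz (theta)" in text

    def test_empty_group_rejected(self, small_cohort, small_peaks):
        _, dataset, _ = small_cohort
        with pytest.raises(ValueError):
            SpectralRangeClassification(dataset, groups=("Q",)) \
                .fit(peaks=small_peaks)

    def test_incomplete_dataset_rejected_at_construction(self, small_cohort):
        _, dataset, _ = small_cohort
        broken = StudyDataset(recordings=dict(dataset.recordings),
                              manifest=dataset.manifest)
        sid = dataset.subjects()[0]
        del broken.recordings[(sid, "T")]
        with pytest.raises(CompletenessError, match=sid):
            SpectralRangeClassification(broken)


class TestCorrelationDiscrimination:
    def test_threshold_validation(self, small_cohort):
        _, dataset, _ = small_cohort
        with pytest.raises(ValueError):
            CorrelationDiscrimination(dataset, threshold=1.5)

    def test_summary_reports_top_pairs(self, small_cohort):
        _, dataset, _ = small_cohort
        res = CorrelationDiscrimination(dataset, group="G").fit()
        text = res.summary(k=2)
        assert "F4-F7" in text and "F3-F8" in text

    def test_count_matrices_cover_raw_and_bands(self, small_cohort):
        _, dataset, _ = small_cohort
        res = CorrelationDiscrimination(dataset, group="G").fit()
        keys = {band for band, _ in res.count_matrices}
        assert keys == {"raw", "theta", "alpha", "beta"}


class TestNullCohort:
    def test_zero_effect_yields_no_disjoint_ranges(self):
        """With identical generative parameters in both states, no
        (channel, band) range is disjoint for n >= 10 subjects, across
        20 independent seeds."""
        found = []
        for seed in range(20):
            # identical amplitude law in both states; sinusoid-dominated
            # peaks so the (length-dependent) noise floor stays negligible
            spec = default_two_state_spec(
                n_subjects=14, seed=seed, rate=125.0,
                duration_R=6.0, duration_T=4.0,
                band_peak_amplitude={},   # no state-dependent amplitudes
                pair_correlation={},      # no state-dependent correlation
                default_amplitude=(1.0, 5.0),
                band_noise_sd=1.0, noise_sd=0.5)
            dataset, _ = generate_cohort(spec)
            peaks = collect_peaks(dataset)
            res = SpectralRangeClassification(dataset, groups=("G",)) \
                .fit(peaks=peaks)
            found.extend(res.discriminators["G"])
        assert found == []


class TestPipeline:
    CONFIG = dict(mode="synthetic", n_subjects=6, seed=13, rate=250.0,
                  duration_R=12.0, duration_T=6.0)

    def test_artifacts_written_and_deterministic(self, tmp_path):
        out1 = run_pipeline(RunConfig(out_dir=str(tmp_path / "a"),
                                      **self.CONFIG))
        expected = {"spectral_peaks.csv", "range_summaries.csv", "metrics.csv",
                    "threshold_sweep.csv", "pair_rankings.csv",
                    "flagged_subjects.json", "discriminators.json",
                    "provenance.json"}
        assert expected <= set(out1["paths"])
        out2 = run_pipeline(RunConfig(out_dir=str(tmp_path / "b"),
                                      **self.CONFIG))
        # provenance embeds the output directory; every analysis artifact
        # must be byte-identical across reruns with the same seed
        for name in expected - {"provenance.json"}:
            b1 = Path(out1["paths"][name]).read_bytes()
            b2 = Path(out2["paths"][name]).read_bytes()
            assert b1 == b2, f"{name} not byte-identical across reruns"

    def test_designated_channels_perfect_in_metrics_csv(self, tmp_path):
        out = run_pipeline(RunConfig(out_dir=str(tmp_path / "m"),
                                     **self.CONFIG))
        metrics = pd.read_csv(out["paths"]["metrics.csv"])
        gstar = metrics[metrics.group == "G*"]
        for channel, band in (("F7", "theta"), ("Fz", "theta"), ("F7", "beta")):
            row = gstar[(gstar.channel == channel) & (gstar.band == band)]
            assert float(row.accuracy_pct.iloc[0]) == 100.0

    def test_provenance_records_decisions_and_seed(self, tmp_path):
        out = run_pipeline(RunConfig(out_dir=str(tmp_path / "p"),
                                     **self.CONFIG))
        prov = json.loads(Path(out["paths"]["provenance.json"]).read_text())
        assert prov["seed"] == 13
        assert prov["decisions"]["filter_family"] == "butterworth"
        assert prov["decisions"]["specificity_mode"] == "table_consistent"
        assert "config_hash" in prov

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(threshold=0.0)
        with pytest.raises(ValueError):
            RunConfig(mode="edf_dir")

    def test_config_round_trip_from_yaml(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("mode: synthetic\nn_subjects: 4\nseed: 2\n"
                     "threshold: 0.6\nsweep_thresholds: [0.5, 0.6]\n")
        cfg = RunConfig.from_file(p)
        assert cfg.n_subjects == 4 and cfg.threshold == 0.6
        assert cfg.sweep_thresholds == (0.5, 0.6)


class TestCli:
    def test_staged_workflow(self, tmp_path):
        runner = CliRunner()
        cohort_dir = str(tmp_path / "cohort")
        r = runner.invoke(cli_main, [
            "simulate", "--n-subjects", "4", "--seed", "3", "--rate", "250",
            "--duration-r", "8", "--duration-t", "6", "--out", cohort_dir])
        assert r.exit_code == 0, r.output
        peaks_csv = str(tmp_path / "peaks.csv")
        r = runner.invoke(cli_main, ["spectral", "--input", cohort_dir,
                                     "--out", peaks_csv])
        assert r.exit_code == 0, r.output
        assert len(pd.read_csv(peaks_csv)) == 4 * 19 * 3 * 2
        r = runner.invoke(cli_main, [
            "classify", "--input", cohort_dir, "--group", "G",
            "--peaks", peaks_csv, "--out", str(tmp_path / "cls")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "cls" / "metrics.csv").exists()
        r = runner.invoke(cli_main, [
            "report", "--metrics", str(tmp_path / "cls" / "metrics.csv")])
        assert r.exit_code == 0, r.output

    def test_filter_and_correlate_stages(self, tmp_path):
        runner = CliRunner()
        cohort_dir = str(tmp_path / "cohort")
        runner.invoke(cli_main, [
            "simulate", "--n-subjects", "3", "--seed", "5", "--rate", "250",
            "--duration-r", "8", "--duration-t", "6", "--out", cohort_dir])
        r = runner.invoke(cli_main, [
            "filter", "--input", cohort_dir, "--band", "beta",
            "--out", str(tmp_path / "beta")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "beta" / "filter_spec.json").exists()
        r = runner.invoke(cli_main, [
            "correlate", "--input", cohort_dir, "--group", "G",
            "--out", str(tmp_path / "corr")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "corr" / "pair_rankings.csv").exists()

    def test_run_all_with_config_file(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("mode: synthetic\nn_subjects: 3\nseed: 4\n"
                       "rate: 250.0\nduration_R: 8.0\nduration_T: 6.0\n")
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "run-all", "--config", str(cfg), "--out", str(tmp_path / "run")],
            catch_exceptions=False)
        assert r.exit_code == 0
        assert (tmp_path / "run" / "metrics.csv").exists()
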