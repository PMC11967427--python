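"""Records, summaries, crops/CSV bijection, and the evaluation metrics."""

from pathlib import Path

import numpy as np
import pytest

from sampdetect import report
from sampdetect.classify import Prediction
from sampdetect.evaluate import (confusion_summary, detection_efficiency,
                                 fov_coverage, size_histogram)


class TestEmitRecords:
    def test_empty_run_writes_header_only(self, tmp_path):
        records, summary = report.emit_records([], [], 18.0, tmp_path,
                                               run_id="empty")
        assert records == []
        assert summary.total_count == 0
        lines = (tmp_path / "empty_particles.csv").read_text().splitlines()
        assert lines == [",".join(report.CSV_HEADER)]

    def test_class_and_category_totals(self, clean_scene_result):
        s = clean_scene_result.summary
        assert s.total_count == sum(s.count_by_class.values())
        assert s.total_count == sum(n for per in s.count_by_category.values()
                                    for n in per.values())

    def test_csv_crop_bijection(self, clean_scene_result):
        res = clean_scene_result
        outdir = res.csv_path.parent
        csv_names = {r.crop_file for r in res.records}
        disk_jpg = {p.name for p in (outdir / "crops").glob("*.jpg")}
        assert csv_names == disk_jpg
        for name in csv_names:   # lossless mirror exists
            assert (outdir / "crops" / (name[:-4] + ".png")).exists()

    def test_rerun_reproduces_csv_and_png(self, clean_scene, tmp_path):
        from sampdetect.pipeline import RunConfig, run_pipeline
        _, frames, log = clean_scene
        win = log.window
        texts, pngs = [], []
        for sub in ("a", "b"):
            rc = RunConfig(output_dir=str(tmp_path / sub),
                           window=(win.x0, win.y0, win.width, win.height),
                           classifier="rough", run_id="rep")
            res = run_pipeline(rc, frames)
            texts.append(res.csv_path.read_text())
            pngs.append(sorted((Path(tmp_path / sub) / "crops").glob("*.png")))
        assert texts[0] == texts[1]
        for p1, p2 in zip(*pngs):
            assert p1.read_bytes() == p2.read_bytes()

    def test_unwritable_outdir_fails_early(self, tmp_path):
        target = tmp_path / "file"
        target.write_text("x")
        with pytest.raises(OSError):
            report.emit_records([], [], 18.0, target / "sub")


class TestOverlay:
    def test_empty_run_only_window_rectangle(self):
        frames = np.zeros((2, 60, 80), dtype=np.uint8)
        from sampdetect.detect import DetectionWindow
        win = DetectionWindow(10, 10, 40, 30)
        out = report.overlay_video(frames, [], [], win)
        assert out.shape == (2, 60, 80, 3)
        red = (out[0, :, :, 0] > 200) & (out[0, :, :, 1] < 50)
        assert red.any()

    def test_final_total_matches_record_count(self, clean_scene,
                                              clean_scene_result):
        _, frames, _ = clean_scene
        res = clean_scene_result
        out = report.overlay_video(frames, res.counted_tracks,
                                   res.predictions, res.window)
        assert out.shape[:3] == frames.shape
        # counters are rendered; the bookkeeping they show is the record list
        assert len(res.records) == res.summary.total_count


class TestConfusionSummary:
    def test_printed_counts_arithmetic(self):
        """24/25 grains and 25/25 fibers correct gives 96.0 / 100.0 / 98.0."""
        preds = ([Prediction("grain", 99.0)] * 24 + [Prediction("fiber", 99.0)]
                 + [Prediction("fiber", 99.0)] * 25)
        truths = ["grain"] * 25 + ["fiber"] * 25
        cs = confusion_summary(preds, truths)
        assert cs.correct_rate_pct["grain"] == pytest.approx(96.0)
        assert cs.correct_rate_pct["fiber"] == pytest.approx(100.0)
        assert cs.average_pct == pytest.approx(98.0)
        assert cs.counts.sum() == 50

    def test_all_correct_full_confidence(self):
        preds = [Prediction("grain", 100.0)] * 3 + [Prediction("fiber", 100.0)] * 3
        cs = confusion_summary(preds, ["grain"] * 3 + ["fiber"] * 3)
        assert cs.correct_rate_pct == {"grain": 100.0, "fiber": 100.0}

    def test_low_confidence_counts_as_incorrect(self):
        preds = [Prediction("grain", 80.0)] * 2 + [Prediction("fiber", 80.0)] * 2
        cs = confusion_summary(preds, ["grain", "grain", "fiber", "fiber"])
        assert cs.correct_rate_pct == {"grain": 0.0, "fiber": 0.0}
        assert cs.label_only_rate_pct == {"grain": 100.0, "fiber": 100.0}

    def test_order_invariance(self, rng):
        preds = [Prediction("grain", 95.0), Prediction("fiber", 85.0),
                 Prediction("fiber", 99.0), Prediction("grain", 91.0)]
        truths = ["grain", "grain", "fiber", "fiber"]
        base = confusion_summary(preds, truths)
        order = rng.permutation(4)
        shuf = confusion_summary([preds[i] for i in order],
                                 [truths[i] for i in order])
        assert shuf.correct_rate_pct == base.correct_rate_pct
        assert shuf.average_pct == base.average_pct

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_summary([], [])


class TestDetectionEfficiency:
    def test_clean_scene_full_recovery(self, clean_scene, clean_scene_result):
        _, _, log = clean_scene
        eff = detection_efficiency(clean_scene_result.records, log)
        assert eff.efficiency_pct == 100.0
        assert eff.false_positives == 0
        assert eff.n_matched == eff.n_truth

    def test_partial_recovery_arithmetic(self, clean_scene,
                                         clean_scene_result):
        _, _, log = clean_scene
        records = clean_scene_result.records
        # drop records: efficiency is the matched fraction of truth
        k = len(records) - 2
        eff = detection_efficiency(records[:k], log)
        assert eff.efficiency_pct == pytest.approx(100.0 * k / eff.n_truth)


class TestSizeHistogram:
    def test_partition_and_empty(self):
        counts, edges = size_histogram([25, 75, 432, 880])
        assert counts.sum() == 4
        assert counts[0] == 1 and counts[1] == 1
        assert counts[8] == 1         # 432 um in [400, 450)
        assert counts[-1] == 1        # 880 um overflows into the last bin
        zero, _ = size_histogram([])
        assert zero.sum() == 0

    def test_generated_sizes_follow_configured_lognormal(self):
        """Truth sizes from the simulator follow the truncated lognormal the
        population is configured with (KS test at n=500)."""
        from scipy import stats as sps
        from sampdetect.simulate import SceneConfig
        cfg = SceneConfig()
        cv2 = (cfg.grain_size_sd_um / cfg.grain_size_mean_um) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(cfg.grain_size_mean_um) - 0.5 * sigma ** 2
        rng = np.random.default_rng(0)
        draws = []
        while len(draws) < 500:
            s = rng.lognormal(mu, sigma)
            if 2 * cfg.pixel_scale_um <= s <= cfg.grain_size_max_um:
                draws.append(s)
        lo = sps.lognorm.cdf(2 * cfg.pixel_scale_um, sigma, scale=np.exp(mu))
        hi = sps.lognorm.cdf(cfg.grain_size_max_um, sigma, scale=np.exp(mu))

        def trunc_cdf(x):
            c = sps.lognorm.cdf(x, sigma, scale=np.exp(mu))
            return (c - lo) / (hi - lo)

        stat = sps.kstest(draws, trunc_cdf).pvalue
        assert stat > 0.01


class TestFovCoverage:
    @pytest.mark.parametrize("view,channel,expected", [
        (11.2, 12.0, 93.3),
        (12.0, 12.0, 100.0),
        (6.0, 12.0, 50.0),
    ])
    def test_coverage_percentages(self, view, channel, expected):
        assert fov_coverage(view, channel) == expected

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            fov_coverage(10, 0)
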