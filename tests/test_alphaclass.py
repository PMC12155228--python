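"""Heatmap targets, NMS, detector training, and trial quantification."""

import numpy as np
import pandas as pd
import pytest

from ethophys import alphaclass
from ethophys.benchmarks import brute_force_peaks
from ethophys.core import TrialTable


class TestHeatmapTargets:
    def test_single_label_peak_value_one(self):
        t = alphaclass.make_heatmap_targets(
            [(0, "a", 32.0, 16.0)], (64, 64), ["a"], sigma=1.5, stride=4
        )
        assert t.shape == (1, 1, 16, 16)
        assert t[0, 0, 4, 8] == pytest.approx(1.0)

    def test_no_labels_all_zero(self):
        t = alphaclass.make_heatmap_targets(
            [(1, "a", 10.0, 10.0)], (64, 64), ["a", "b"], stride=4
        )
        assert t[:, 1].sum() == 0.0
        assert t[0].sum() == 0.0  # frame 0 has no labels

    def test_two_labels_max_rule_midpoint(self):
        """Labels 2σ apart: midpoint value is exp(−0.5) of either Gaussian."""
        sigma = 2.0
        t = alphaclass.make_heatmap_targets(
            [(0, "a", 16.0, 32.0), (0, "a", 48.0, 32.0)], (64, 64), ["a"],
            sigma=sigma, stride=4,
        )
        # output coords: centers at (8, 4) and (8, 12); midpoint (8, 8)
        mid = t[0, 0, 8, 8]
        assert mid == pytest.approx(np.exp(-(4.0**2) / (2 * sigma**2)))
        assert t[0, 0].max() == pytest.approx(1.0)

    def test_out_of_image_label_rejected(self):
        with pytest.warns(UserWarning, match="rejected"):
            t = alphaclass.make_heatmap_targets(
                [(0, "a", 200.0, 10.0)], (64, 64), ["a"]
            )
        assert t.sum() == 0.0


class TestNMS:
    def test_single_maximum(self):
        hm = np.zeros((5, 5))
        hm[2, 2] = 0.9
        assert alphaclass.nms_peaks(hm, 5, 0.5) == [(2, 2, 0.9)]

    def test_uniform_plateau_keeps_origin(self):
        hm = np.full((5, 5), 0.8)
        assert alphaclass.nms_peaks(hm, 3, 0.5) == [(0, 0, 0.8)]

    def test_threshold_excludes_subthreshold_peaks(self):
        hm = np.zeros((7, 7))
        hm[1, 1], hm[5, 5] = 0.4, 0.6
        assert alphaclass.nms_peaks(hm, 3, 0.5) == [(5, 5, 0.6)]

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(17)
        for i in range(30):
            hm = rng.random((32, 32))
            if i % 3 == 0:
                hm = np.round(hm, 1)
            assert alphaclass.nms_peaks(hm, 5, 0.5) == brute_force_peaks(
                hm, 5, 0.5
            )

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            alphaclass.nms_peaks(np.zeros((5, 5)), 4, 0.5)


@pytest.fixture(scope="module")
def tiny_detector():
    """A very small trained detector on blob frames (fast, shared)."""
    rng = np.random.default_rng(5)
    n = 60
    pos = rng.random(n) < 0.5
    frames = 0.05 * rng.random((n, 32, 32)).astype(np.float32)
    labels = []
    yy, xx = np.mgrid[0:32, 0:32]
    for i in np.flatnonzero(pos):
        cx, cy = rng.integers(6, 26, 2)
        frames[i] += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 2.5**2))
        labels.append((int(i), "blob", float(cx), float(cy)))
    targets = alphaclass.make_heatmap_targets(labels, (32, 32), ["blob"],
                                              stride=4)
    full = np.zeros((n, 1, 8, 8), np.float32)
    full[: targets.shape[0]] = targets
    model = alphaclass.train_detector(frames, full, classes=("blob",),
                                      epochs=25, seed=0)
    return frames, pos, labels, model


class TestDetector:
    def test_training_reduces_loss(self, tiny_detector):
        _, _, _, model = tiny_detector
        assert model.loss_curve[-1] < model.loss_curve[0]

    def test_detects_blobs_and_ignores_background(self, tiny_detector):
        frames, pos, labels, model = tiny_detector
        _, etho = alphaclass.detect(frames, model, threshold=0.5)
        ev = alphaclass.evaluate_detector(etho[:, 0], pos)
        assert ev["f1"] >= 0.9

    def test_peak_near_planted_location(self, tiny_detector):
        frames, pos, labels, model = tiny_detector
        calls, _ = alphaclass.detect(frames, model, threshold=0.5)
        by_frame = {}
        for c in calls:
            by_frame.setdefault(c.frame, c)  # highest-confidence first
        hits = 0
        for i, cls, x, y in labels:
            c = by_frame.get(i)
            if c is not None and np.hypot(c.x - x, c.y - y) <= 6:
                hits += 1
        assert hits / len(labels) >= 0.9

    def test_all_zero_frame_no_calls(self, tiny_detector):
        _, _, _, model = tiny_detector
        calls, etho = alphaclass.detect(np.zeros((1, 32, 32)), model,
                                        threshold=0.5)
        assert calls == [] and not etho.any()

    def test_threshold_one_suppresses_everything(self, tiny_detector):
        frames, _, _, model = tiny_detector
        calls, etho = alphaclass.detect(frames[:5], model, threshold=1.0)
        assert calls == []

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        frames = rng.random((8, 32, 32)).astype(np.float32)
        targets = np.zeros((8, 1, 8, 8), np.float32)
        m1 = alphaclass.train_detector(frames, targets, epochs=2, seed=3)
        m2 = alphaclass.train_detector(frames, targets, epochs=2, seed=3)
        assert abs(m1.loss_curve[-1] - m2.loss_curve[-1]) < 1e-12

    def test_frame_size_mismatch_rejected(self, tiny_detector):
        _, _, _, model = tiny_detector
        with pytest.raises(ValueError, match="geometry"):
            alphaclass.detect(np.zeros((1, 30, 30)), model)

    def test_checkpoint_round_trip(self, tiny_detector, tmp_path):
        frames, _, _, model = tiny_detector
        p = tmp_path / "model.pkl"
        model.save(p)
        back = alphaclass.DetectorModel.load(p)
        np.testing.assert_array_equal(back.predict(frames[:2]),
                                      model.predict(frames[:2]))


class TestAttendingTimecourse:
    def _etho(self, n):
        return np.zeros(n, bool)

    def test_never_attending_all_zero(self):
        fps = 10.0
        etho = self._etho(1000)
        trials = TrialTable(onsets=[20.0, 60.0])
        df, kept = alphaclass.attending_timecourse(etho, trials, fps)
        assert (df[["dA_1", "dA_2", "dA_3", "total"]].to_numpy() == 0).all()

    def test_bin_arithmetic(self):
        fps = 1.0  # 1 frame per second for hand arithmetic
        etho = np.zeros(200, bool)
        onset = 50
        etho[onset - 5:onset] = np.r_[[True] * 2, [False] * 3]  # B = 2
        etho[onset:onset + 5] = True                            # 5
        etho[onset + 5:onset + 10] = np.r_[[True] * 3, [False] * 2]  # 3
        trials = TrialTable(onsets=[float(onset)])
        df, _ = alphaclass.attending_timecourse(etho, trials, fps)
        assert df.loc[0, "baseline"] == 2
        assert df.loc[0, ["dA_1", "dA_2", "dA_3"]].tolist() == [3, 1, -2]
        assert df.loc[0, "total"] == 2

    def test_constant_attending_total_zero(self):
        fps = 5.0
        etho = np.ones(2000, bool)
        trials = TrialTable(onsets=[100.0, 200.0])
        df, _ = alphaclass.attending_timecourse(etho, trials, fps)
        np.testing.assert_allclose(df["total"], 0.0)

    def test_truncated_trial_dropped(self):
        etho = np.zeros(100, bool)  # 20 s at 5 fps
        trials = TrialTable(onsets=[1.0, 5.0])  # first lacks a 5 s baseline
        with pytest.warns(UserWarning):
            df, kept = alphaclass.attending_timecourse(etho, trials, 5.0)
        assert kept.tolist() == [False, True]
        assert len(df) == 1


class TestClassifyTrials:
    def test_local_median_strict(self):
        out = alphaclass.classify_trials([0, 1, 2, 3, 4, 5], mode="local")
        assert out["threshold"] == 2.5
        assert (out["labels"] == "Attending").sum() == 3

    def test_all_equal_counts_none_attending(self):
        out = alphaclass.classify_trials([4, 4, 4, 4], mode="local")
        assert (out["labels"] == "NotAttending").all()

    def test_global_pool_overrides_local(self):
        out = alphaclass.classify_trials([1, 2], mode="global",
                                         pool=[0, 0, 0, 10])
        assert (out["labels"] == "Attending").all()

    def test_top_bottom_selection_disjoint(self, rng):
        counts = rng.integers(0, 100, 60)
        out = alphaclass.classify_trials(counts, select_n=15)
        top, bottom = set(out["top_idx"]), set(out["bottom_idx"])
        assert len(top) == len(bottom) == 15
        assert not top & bottom

    def test_too_few_trials_for_selection(self):
        with pytest.raises(ValueError, match="select_n"):
            alphaclass.classify_trials([1, 2, 3], select_n=2)
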