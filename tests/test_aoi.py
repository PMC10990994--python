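"""AOI segmentation, sample assignment and dwell detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazekit import (
    AOIHistogram,
    ConfigError,
    DataError,
    Dwell,
    InfantSimConfig,
    ManualDwellFile,
    assign_samples,
    build_histogram,
    detect_dwells_estimated,
    dwells_from_manual,
    segment_aois,
    simulate_infant_session,
)

from conftest import make_recording


def mixture(rng, means, sds, weights, n):
    comp = rng.choice(len(means), size=n, p=np.asarray(weights) / np.sum(weights))
    return rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])


class TestBuildHistogram:
    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10, 500)
        for bw in (0.5, 1.0, 3.0):
            edges, counts = build_histogram(x, bw)
            assert counts.sum() == 500
            assert edges[0] <= x.min() and edges[-1] >= x.max()

    def test_identical_values_single_bin(self):
        edges, counts = build_histogram(np.full(40, 3.25), 1.0)
        assert (counts > 0).sum() == 1

    def test_three_modes_visible(self):
        rng = np.random.default_rng(1)
        x = mixture(rng, [-20, 0, 20], [2, 2, 2], [1, 1, 1], 3000)
        edges, counts = build_histogram(x, 1.0)
        centers = (edges[:-1] + edges[1:]) / 2
        for mu, valley_at in ((-20, -10), (0, -10), (0, 10), (20, 10)):
            near = counts[np.abs(centers - mu) < 2].max()
            valley = counts[np.abs(centers - valley_at) < 2].max()
            assert near > 3 * valley

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ConfigError):
            build_histogram([1.0, 2.0], 0.0)


class TestSegmentation:
    def test_trimodal_sections_near_analytic_valleys(self):
        # overlapping components (sd 5, separation 20) keep the valley
        # density above the trim floor, so section boundaries converge to
        # the analytic valleys of the equal mixture: the midpoints +-10
        rng = np.random.default_rng(2)
        x = mixture(rng, [-20, 0, 20], [5, 5, 5], [1, 1, 1], 20000)
        seg = segment_aois(x)
        assert not seg.excluded and seg.n_peaks == 3
        assert seg.sections["left_lamp"][1] == pytest.approx(-10, abs=2)
        assert seg.sections["parent"][0] == pytest.approx(-10, abs=2)
        assert seg.sections["parent"][1] == pytest.approx(10, abs=2)
        assert seg.sections["right_lamp"][0] == pytest.approx(10, abs=2)

    def test_tight_clusters_leave_none_gaps_between_sections(self):
        # well-separated tight clusters: the density floor trims sections
        # before the empty valleys, so sections do not tile the axis
        rng = np.random.default_rng(2)
        x = mixture(rng, [-20, 0, 20], [2, 2, 2], [1, 1, 1], 6000)
        seg = segment_aois(x)
        assert not seg.excluded
        assert seg.sections["left_lamp"][1] < seg.sections["parent"][0]
        assert seg.sections["parent"][1] < seg.sections["right_lamp"][0]

    def test_sections_ordered_and_disjoint(self):
        rng = np.random.default_rng(3)
        x = mixture(rng, [-20, 0, 20], [2, 2, 2], [3, 2, 3], 4000)
        seg = segment_aois(x)
        lo_l, hi_l = seg.sections["left_lamp"]
        lo_p, hi_p = seg.sections["parent"]
        lo_r, hi_r = seg.sections["right_lamp"]
        assert hi_l <= lo_p and hi_p <= lo_r

    def test_unimodal_data_excluded(self):
        rng = np.random.default_rng(4)
        seg = segment_aois(rng.normal(0, 3, 2000))
        assert seg.excluded and seg.n_peaks < 2
        assert all(s is None for s in seg.sections.values())

    def test_bimodal_space_between_is_parent(self):
        rng = np.random.default_rng(5)
        x = mixture(rng, [-20, 20], [2, 2], [1, 1], 4000)
        seg = segment_aois(x)
        assert not seg.excluded
        assert seg.sections["parent"] is not None
        lo, hi = seg.sections["parent"]
        assert seg.sections["left_lamp"][1] == pytest.approx(lo)
        assert seg.sections["right_lamp"][0] == pytest.approx(hi)
        assert lo < 0 < hi

    def test_distractor_peaks_do_not_become_aois(self):
        # two small far-out lumps must not displace the true AOI triple
        rng = np.random.default_rng(6)
        x = np.concatenate(
            [
                mixture(rng, [-20, 0, 20], [2, 2, 2], [3, 2, 3], 4000),
                rng.normal(-50, 3, 300),
                rng.normal(50, 3, 300),
            ]
        )
        seg = segment_aois(x)
        for aoi, mu in zip(("left_lamp", "parent", "right_lamp"), (-20, 0, 20)):
            lo, hi = seg.sections[aoi]
            assert lo < mu < hi

    def test_model_class_accepts_recording(self, noise_free_infant_cfg):
        rec, _ = simulate_infant_session(noise_free_infant_cfg)
        seg = AOIHistogram(rec).fit()
        assert not seg.excluded


class TestAssignSamples:
    def _simple_seg(self):
        rng = np.random.default_rng(7)
        x = mixture(rng, [-20, 0, 20], [2, 2, 2], [1, 1, 1], 5000)
        return segment_aois(x)

    def test_labels_follow_sections(self):
        seg = self._simple_seg()
        rec = make_recording([-20.0, 0.0, 20.0, 60.0])
        labels = assign_samples(rec, seg)
        assert list(labels) == ["left_lamp", "parent", "right_lamp", "none"]

    def test_invalid_samples_labelled_none(self):
        seg = self._simple_seg()
        rec = make_recording([-20.0, -20.0], valid=[True, False])
        assert list(assign_samples(rec, seg)) == ["left_lamp", "none"]

    def test_excluded_segmentation_is_usage_error(self):
        rng = np.random.default_rng(8)
        seg = segment_aois(rng.normal(0, 3, 1000))
        with pytest.raises(DataError):
            assign_samples(make_recording([0.0]), seg)

    def test_noise_free_pipeline_labels_equal_truth(self, noise_free_infant_cfg):
        rec, truth = simulate_infant_session(noise_free_infant_cfg)
        seg = AOIHistogram(rec).fit()
        labels = assign_samples(rec, seg)
        idx = 0
        for label, s, e in truth.entries:
            while idx < len(rec) and rec.t[idx] < e - 1e-9:
                assert labels[idx] == label
                idx += 1
        assert idx == len(rec)


def rle(labels):
    runs, start = [], 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return runs


def hysteresis_oracle(labels, switch_frames):
    """Independent re-statement of the dwell rule: per-frame dwell labels."""
    out = [labels[0]]
    current = labels[0]
    for i in range(1, len(labels)):
        if labels[i] != current:
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            if j - i >= switch_frames:
                current = labels[i]
        out.append(current)
    return out


class TestDwellDetection:
    def test_single_label_single_dwell(self):
        t = np.arange(10) / 30.0
        dwells = detect_dwells_estimated(["left_lamp"] * 10, t)
        assert len(dwells) == 1
        assert dwells[0].n_frames == 10
        assert dwells[0].start == 0.0

    def test_two_frame_excursion_absorbed(self):
        labels = ["left_lamp"] * 5 + ["parent"] * 2 + ["left_lamp"] * 5
        t = np.arange(12) / 30.0
        dwells = detect_dwells_estimated(labels, t, switch_frames=3)
        assert len(dwells) == 1
        assert dwells[0].aoi == "left_lamp" and dwells[0].n_frames == 12

    def test_three_frame_run_breaks_dwell(self):
        labels = ["left_lamp"] * 5 + ["parent"] * 3 + ["left_lamp"] * 5
        t = np.arange(13) / 30.0
        dwells = detect_dwells_estimated(labels, t, switch_frames=3)
        assert [d.aoi for d in dwells] == ["left_lamp", "parent", "left_lamp"]
        assert dwells[1].start == pytest.approx(t[5])

    def test_dwells_partition_frames(self):
        rng = np.random.default_rng(9)
        labels = list(rng.choice(["left_lamp", "parent", "none"], 300))
        t = np.arange(300) / 30.0
        dwells = detect_dwells_estimated(labels, t, switch_frames=3)
        assert sum(d.n_frames for d in dwells) == 300
        for a, b in zip(dwells, dwells[1:]):
            assert a.end == b.start

    @given(
        seq=st.lists(st.sampled_from(["left_lamp", "parent", "none"]),
                     min_size=1, max_size=200),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_switch_frames_one_equals_rle(self, seq):
        t = np.arange(len(seq)) / 30.0
        dwells = detect_dwells_estimated(seq, t, switch_frames=1)
        assert [(d.aoi, d.n_frames) for d in dwells] == [
            (lab, ln) for lab, _, ln in rle(seq)
        ]

    @given(
        seq=st.lists(st.sampled_from(["left_lamp", "parent", "none"]),
                     min_size=1, max_size=200),
        k=st.integers(1, 4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_independent_hysteresis_oracle(self, seq, k):
        t = np.arange(len(seq)) / 30.0
        dwells = detect_dwells_estimated(seq, t, switch_frames=k)
        frame_labels = []
        for d in dwells:
            frame_labels.extend([d.aoi] * d.n_frames)
        assert frame_labels == hysteresis_oracle(seq, k)

    def test_invalid_switch_frames(self):
        with pytest.raises(ConfigError):
            detect_dwells_estimated(["none"], [0.0], switch_frames=0)


class TestManualDwells:
    def test_verbatim_conversion(self):
        f = ManualDwellFile(
            [("left_lamp", 0.0, 5.0), ("parent", 5.0, 7.0), ("none", 7.0, 9.0)]
        )
        dwells = dwells_from_manual(f, rate=30.0)
        assert [(d.aoi, d.start, d.end) for d in dwells] == f.entries
        assert sum(d.duration for d in dwells) == pytest.approx(9.0)

    def test_simulator_truth_roundtrip(self):
        _, truth = simulate_infant_session(InfantSimConfig(seed=6))
        dwells = dwells_from_manual(truth)
        assert [(d.aoi, d.start, d.end) for d in dwells] == truth.entries
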