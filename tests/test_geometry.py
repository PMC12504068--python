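"""Geometric measurement oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ctikin as ck
from ctikin.errors import DegenerateInputError
from ctikin.synth import SyntheticConfig, generate_cine, neutral_truth
from conftest import make_cine


def brute_curvilinear(pts):
    return sum(
        float(np.hypot(*(np.subtract(b, a)))) for a, b in zip(pts[:-1], pts[1:])
    )


def brute_pouch(pts):
    a, b = np.asarray(pts[0]), np.asarray(pts[-1])
    d = b - a
    best = 0.0
    for p in pts[1:-1]:
        r = np.asarray(p) - a
        best = max(best, abs(r[0] * d[1] - r[1] * d[0]) / np.hypot(*d))
    return best


class TestLengths:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0), (3, 4)], 5.0),
            ([(0, 0)], 0.0),
            ([(0, 0), (1, 0), (1, 1), (2, 1)], 3.0),
        ],
    )
    def test_curvilinear_examples(self, pts, expected):
        assert ck.curvilinear_length(np.array(pts, float)) == pytest.approx(expected)

    def test_curvilinear_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            ck.curvilinear_length(np.empty((0, 2)))

    def test_linear_examples(self):
        assert ck.linear_length(np.array([(0, 0), (5, 0)], float)) == 5.0
        loop = np.array([(0, 0), (2, 3), (0, 0)], float)
        assert ck.linear_length(loop) == 0.0
        with pytest.raises(DegenerateInputError):
            ck.linear_length(np.array([(1, 1)], float))

    def test_collinear_contour_linear_equals_curvilinear(self, rng):
        direction = rng.normal(size=2)
        ts = np.sort(rng.uniform(0, 10, size=12))
        pts = np.outer(ts, direction) + rng.normal(size=2)
        assert ck.linear_length(pts) == pytest.approx(ck.curvilinear_length(pts))

    def test_curvilinear_dominates_linear(self, rng):
        for _ in range(50):
            pts = rng.normal(scale=10, size=(rng.integers(2, 15), 2))
            assert ck.curvilinear_length(pts) >= ck.linear_length(pts) - 1e-12


class TestPouchDepth:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0), (1, 0), (2, 0)], 0.0),
            ([(0, 0), (1, 1), (2, 0)], 1.0),
            ([(0, 0), (1, -1), (1, 2), (2, 0)], 2.0),
        ],
    )
    def test_examples(self, pts, expected):
        assert ck.pouch_depth(np.array(pts, float)) == pytest.approx(expected)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            pts = rng.normal(scale=8, size=(10, 2))
            assert ck.pouch_depth(pts) == pytest.approx(brute_pouch(pts))

    def test_coincident_endpoints_rejected(self):
        pts = np.array([(1, 1), (5, 3), (1, 1)], float)
        with pytest.raises(DegenerateInputError, match="coincident"):
            ck.pouch_depth(pts)


class TestPhaseFrames:
    def test_argmin_argmax_of_cti_length(self):
        # CTI lengths over 3 frames: 10, 8, 12
        frames = [
            [(0, 0), (5, 0), (10, 0)],
            [(0, 0), (4, 0), (8, 0)],
            [(0, 0), (6, 0), (12, 0)],
        ]
        cine = make_cine(frames, cti_index_range=(0, 3))
        assert ck.select_phase_frames(cine) == (1, 2)

    def test_ties_break_to_earliest_frame(self):
        frames = np.tile(np.array([[(0, 0), (1, 0), (2, 0)]], float), (4, 1, 1))
        cine = make_cine(frames, cti_index_range=(0, 3))
        assert ck.select_phase_frames(cine) == (0, 0)

    def test_matches_generator_ground_truth(self):
        cfg = SyntheticConfig(seed=5, noise_sd_mm=0.0)
        truth = neutral_truth(cfg)
        cine = generate_cine(cfg, truth)
        assert ck.select_phase_frames(cine) == (
            truth.systole_frame,
            truth.diastole_frame,
        )


class TestComputeGeometry:
    def test_doubled_contour_gives_ne_one(self):
        base = np.array([(0, 0), (1, 0.5), (2, 0), (3, -0.5), (4, 0), (5, 0), (6, 1)], float)
        cine = make_cine([base, 2.0 * base], cti_index_range=(0, 7))
        geo = ck.compute_geometry(cine)
        assert geo.ne == pytest.approx(1.0)
        assert geo.elongation_mm == pytest.approx(geo.curvilinear_systolic_mm)

    def test_static_cine_has_zero_elongation(self):
        base = np.array([(0, 0), (1, 1), (2, 0), (3, 1), (4, 0), (5, 1), (6, 0)], float)
        cine = make_cine([base, base], cti_index_range=(0, 7))
        geo = ck.compute_geometry(cine)
        assert geo.elongation_mm == 0.0 and geo.ne == 0.0

    def test_zero_systolic_length_flagged(self):
        collapsed = np.zeros((7, 2))
        spread = np.column_stack([np.arange(7.0), np.zeros(7)])
        cine = make_cine([spread, collapsed], cti_index_range=(0, 7))
        with pytest.raises(DegenerateInputError, match="NE undefined"):
            ck.compute_geometry(cine)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 9999),
        scale=st.floats(0.1, 20.0),
        angle=st.floats(-np.pi, np.pi),
    )
    def test_scale_equivariance_and_rigid_invariance(self, seed, scale, angle):
        cfg = SyntheticConfig(seed=seed % 100, noise_sd_mm=0.0)
        cine = generate_cine(cfg, neutral_truth(cfg))
        geo = ck.compute_geometry(cine)

        scaled = make_cine(cine.frames * scale, cti_index_range=cine.cti_index_range)
        gs = ck.compute_geometry(scaled)
        assert gs.ne == pytest.approx(geo.ne, rel=1e-9)
        for f in ("curvilinear_systolic_mm", "curvilinear_diastolic_mm",
                  "linear_diastolic_mm", "pouch_depth_mm", "elongation_mm"):
            assert getattr(gs, f) == pytest.approx(scale * getattr(geo, f), rel=1e-9)

        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = make_cine(
            cine.frames @ rot.T + np.array([13.0, -7.0]),
            cti_index_range=cine.cti_index_range,
        )
        gr = ck.compute_geometry(moved)
        for f in ("curvilinear_systolic_mm", "curvilinear_diastolic_mm",
                  "linear_diastolic_mm", "pouch_depth_mm", "elongation_mm", "ne"):
            assert getattr(gr, f) == pytest.approx(getattr(geo, f), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("ratio", [0.2, 0.5, 0.8, 1.0])
    def test_ne_recovers_uniform_contraction_exactly(self, ratio):
        cfg = SyntheticConfig(
            seed=2, noise_sd_mm=0.0, contraction_ratio=ratio,
            segment_ap_amplitude_mm=None, segment_cc_amplitude_mm=None,
        )
        cine = generate_cine(cfg, neutral_truth(cfg, contraction_ratio=ratio))
        geo = ck.compute_geometry(cine)
        assert geo.ne == pytest.approx(1.0 / ratio - 1.0, abs=1e-9)


class TestMedianSplit:
    @staticmethod
    def _cohort(values, ne=None):
        df = pd.DataFrame(
            {
                "curvilinear_systolic_mm": values,
                "ne": ne if ne is not None else np.linspace(1, 0.2, len(values)),
            },
            index=[f"P{i}" for i in range(len(values))],
        )
        df.index.name = "patient_id"
        return df

    def test_even_cohort_splits_at_midpoint_median(self):
        res = ck.median_split(self._cohort([1, 2, 3, 4]), "curvilinear_systolic_mm")
        assert res.threshold == pytest.approx(2.5)
        assert sorted(res.low["curvilinear_systolic_mm"]) == [1, 2]
        assert sorted(res.high["curvilinear_systolic_mm"]) == [3, 4]

    def test_all_equal_values_leave_low_group_empty(self):
        res = ck.median_split(self._cohort([5, 5, 5, 5]), "curvilinear_systolic_mm")
        assert len(res.low) == 0 and len(res.high) == 4

    def test_excluded_outlier_absent_from_both_groups(self):
        df = self._cohort([10, 20, 30, 40], ne=[0.4, 0.6, 0.8, 3.38])
        res = ck.median_split(df, "curvilinear_systolic_mm", exclude=("P3",))
        assert "P3" not in res.low.index and "P3" not in res.high.index
        assert res.threshold == pytest.approx(20.0)  # median of remaining three
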