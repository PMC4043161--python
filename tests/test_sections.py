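"""Poincare crossings, histograms, colour coding and phasegram assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phasegram as ph
from phasegram.sections import (
    DegenerateAttractorError,
    histogram_edges,
    histogram_entropy,
    revolution_crossings,
)
from phasegram.types import (
    CrossingSet,
    InvalidParameterError,
    PhasePortrait,
    SignalTooShortError,
    TrajectoryHistogram,
)


def circle_portrait(n=1000, radius=1.0, center=(0.0, 0.0), turns=1.0):
    t = np.linspace(0.0, 2 * np.pi * turns, int(n * turns), endpoint=False)
    return PhasePortrait(
        np.column_stack([center[0] + radius * np.cos(t),
                         center[1] + radius * np.sin(t)]), 0.0, (0, 1))


def oracle_crossings(points: np.ndarray, angle: float):
    """Independent half-plane scan: signed area test per segment."""
    d = np.array([math.cos(angle), math.sin(angle)])
    positions = []
    for p0, p1 in zip(points[:-1], points[1:]):
        c0 = d[0] * p0[1] - d[1] * p0[0]
        c1 = d[0] * p1[1] - d[1] * p1[0]
        if (c0 < 0 <= c1) or (c1 < 0 <= c0):
            if c0 == c1:
                continue
            t = c0 / (c0 - c1)
            pt = p0 + t * (p1 - p0)
            positions.append(float(pt @ d))
    return np.asarray(positions)


class TestPoincareCrossings:
    def test_unit_circle_two_positions(self):
        cs = ph.poincare_crossings(circle_portrait(), 0.0)
        assert len(cs) == 2
        assert np.allclose(np.sort(cs.positions), [-1.0, 1.0], atol=1e-4)
        assert sorted(cs.directions.tolist()) == [-1, 1]

    def test_twelve_revolutions_give_24_crossings(self):
        cs = ph.poincare_crossings(circle_portrait(turns=12), 0.0)
        assert len(cs) == 24
        assert (cs.directions > 0).sum() == 12
        assert (cs.directions < 0).sum() == 12

    def test_segment_interpolation(self):
        portrait = PhasePortrait([[1.0, -0.2], [1.0, 0.2]], 0.0, (0, 1))
        cs = ph.poincare_crossings(portrait, 0.0)
        assert len(cs) == 1
        assert cs.positions[0] == pytest.approx(1.0)
        assert cs.directions[0] == 1

    def test_point_on_line_counts_once(self):
        # tangent-style touch: a vertex exactly on the line is attributed
        # to the following segment only
        portrait = PhasePortrait([[1.0, -0.3], [1.0, 0.0], [1.0, 0.3]],
                                 0.0, (0, 1))
        cs = ph.poincare_crossings(portrait, 0.0)
        assert len(cs) == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           angle=st.floats(0.0, math.pi - 1e-6))
    def test_matches_half_plane_oracle(self, seed, angle):
        gen = np.random.default_rng(seed)
        pts = gen.uniform(-1, 1, size=(gen.integers(2, 200), 2))
        portrait = PhasePortrait(pts, 0.0, (0, 1))
        cs = ph.poincare_crossings(portrait, angle)
        ref = oracle_crossings(pts, angle)
        assert len(cs) == ref.size
        assert np.allclose(np.sort(cs.positions), np.sort(ref), atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), phi=st.floats(0.05, 1.0))
    def test_rotation_covariance(self, seed, phi):
        # rotating portrait and section together leaves positions unchanged
        gen = np.random.default_rng(seed)
        pts = gen.uniform(-1, 1, size=(100, 2))
        theta = 0.3
        rot = np.array([[math.cos(phi), -math.sin(phi)],
                        [math.sin(phi), math.cos(phi)]])
        a = ph.poincare_crossings(PhasePortrait(pts, 0.0, (0, 1)), theta)
        b = ph.poincare_crossings(
            PhasePortrait(pts @ rot.T, 0.0, (0, 1)), theta + phi)
        assert np.allclose(np.sort(a.positions), np.sort(b.positions),
                           atol=1e-9)


class TestHistogram:
    def test_bins_cover_and_center_zero(self):
        edges = histogram_edges(0.025, 1.0)
        assert np.any(np.isclose(edges, -0.0125))
        assert np.any(np.isclose(edges, 0.0125))
        assert edges[0] <= -1.0 and edges[-1] >= 1.0

    def test_24_crossings_at_plus_minus_one(self):
        cs = CrossingSet(np.tile([1.0, -1.0], 12),
                         np.tile([1, -1], 12), 0.0)
        hist = ph.crossings_histogram(cs, 0.025)
        assert (hist.counts > 0).sum() == 2
        assert sorted(hist.counts[hist.counts > 0].tolist()) == [12, 12]

    def test_empty_crossings_all_zero(self):
        cs = CrossingSet(np.array([]), np.array([]), 0.0)
        hist = ph.crossings_histogram(cs, 0.01)
        assert hist.total == 0

    def test_out_of_range_extends_rather_than_drops(self):
        cs = CrossingSet(np.array([3.7, -0.2]), np.array([1, -1]), 0.0)
        hist = ph.crossings_histogram(cs, 0.1, range_limit=1.0)
        assert hist.total == 2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation(self, seed):
        gen = np.random.default_rng(seed)
        pts = gen.uniform(-1, 1, size=(150, 2))
        cs = ph.poincare_crossings(PhasePortrait(pts, 0.0, (0, 1)), 0.7)
        hist = ph.crossings_histogram(cs, 0.01)
        assert hist.total == len(cs)


class TestSelectAngle:
    def test_tie_breaks_to_smallest(self):
        # a circle looks identical under every section angle
        angle = ph.select_angle([circle_portrait()],
                                [0.3, 0.1, 0.9], bin_width=0.05)
        assert angle == pytest.approx(0.1)

    def test_prefers_angle_revealing_structure(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        c_a = np.column_stack([0.5 + 0.2 * np.cos(th),
                               0.5 + 0.2 * np.sin(th)])
        c_b = np.column_stack([-0.5 + 0.2 * np.cos(th),
                               -0.5 + 0.2 * np.sin(th)])
        tline = np.linspace(0.35, -0.35, 50)
        off = 0.06 / np.sqrt(2)
        b1 = np.column_stack([tline - off, tline + off])
        b2 = np.column_stack([-tline + off, -tline - off])
        portrait = PhasePortrait(np.vstack([c_a, b1, c_b, b2, c_a[:1]]),
                                 0.0, (0, 1))
        candidates = [0.0, np.pi / 4]
        assert ph.select_angle([portrait], candidates, 0.05) == \
            pytest.approx(np.pi / 4)
        # exhaustive oracle: the diagonal section occupies more bins
        occ = {}
        for angle in candidates:
            cs = ph.poincare_crossings(portrait, angle)
            occ[angle] = (ph.crossings_histogram(cs, 0.05).counts > 0).sum()
        assert occ[0.0] == 2 and occ[np.pi / 4] > occ[0.0]

    def test_degenerate_attractor_raises(self):
        # a tiny cluster far from the origin intersects no section line
        pts = np.column_stack([2.0 + 0.01 * np.cos(np.linspace(0, 6, 50)),
                               2.0 + 0.01 * np.sin(np.linspace(0, 6, 50))])
        with pytest.raises(DegenerateAttractorError):
            ph.select_angle([PhasePortrait(pts, 0.0, (0, 1))],
                            [0.0, 1.0], 0.01)


class TestColourCode:
    def test_global_normalization(self):
        edges = histogram_edges(0.5, 1.0)
        h1 = TrajectoryHistogram(edges, [0, 6, 0, 0, 0])
        h2 = TrajectoryHistogram(edges, [0, 0, 12, 0, 0])
        matrix = ph.colour_code([h1, h2])
        assert matrix.max() == 1.0
        assert matrix[0].max() == pytest.approx(0.5)

    def test_extremes(self):
        edges = histogram_edges(0.5, 1.0)
        h = TrajectoryHistogram(edges, [0, 3, 0, 0, 0])
        matrix = ph.colour_code([h])
        assert matrix[0, 1] == 1.0 and matrix[0, 0] == 0.0

    def test_all_zero_histograms(self):
        edges = histogram_edges(0.5, 1.0)
        h = TrajectoryHistogram(edges, np.zeros(5, dtype=int))
        assert np.all(ph.colour_code([h, h]) == 0.0)


class TestBuildPhasegram:
    def test_sine_two_constant_occupied_bins(self):
        ts = ph.gen_sine(100.0, 1.0, 3.0, 8000.0)
        pg = ph.build_phasegram(ts)
        occupied = (pg.matrix > 0).sum(axis=1)
        assert np.all(occupied == 2)
        cols = [np.flatnonzero(row > 0) for row in pg.matrix]
        assert all(np.array_equal(c, cols[0]) for c in cols)

    def test_too_short_signal(self):
        ts = ph.gen_sine(100.0, 1.0, 0.05, 8000.0)
        with pytest.raises(SignalTooShortError):
            ph.build_phasegram(ts, ph.EmbeddingConfig(window_s=1.0))

    def test_matrix_and_axes_consistent(self):
        ts = ph.gen_sine(100.0, 1.0, 1.0, 8000.0)
        pg = ph.build_phasegram(ts)
        assert pg.matrix.shape == (pg.n_windows, pg.n_bins)
        assert pg.matrix.max() == 1.0
        assert np.all(np.diff(pg.times_s) > 0)
        assert pg.meta["hist_max"] >= 1

    def test_amplitude_scale_equivariance(self):
        ts = ph.gen_sine(100.0, 1.0, 1.0, 8000.0)
        scaled = ts.replace(samples=2.5 * ts.samples)
        pg1 = ph.build_phasegram(ts, bin_width=0.005)
        pg2 = ph.build_phasegram(scaled, bin_width=2.5 * 0.005)
        occ1 = (pg1.matrix > 0).sum(axis=1)
        occ2 = (pg2.matrix > 0).sum(axis=1)
        assert np.array_equal(occ1, occ2)

    def test_histogram_entropy_values(self):
        assert histogram_entropy(np.array([0, 0])) == 0.0
        assert histogram_entropy(np.array([5, 5])) == pytest.approx(np.log(2))


class TestRevolutionCrossings:
    def test_sine_revolution_window(self):
        ts = ph.remove_dc(ph.gen_sine(100.0, 1.0, 2.0, 8000.0))
        cs = revolution_crossings(ts, 8000, delay_n=20, angle=0.0,
                                  n_revolutions=12, period_samples=80.0)
        assert len(cs) == 24

    def test_rejects_bad_parameters(self):
        ts = ph.gen_sine(100.0, 1.0, 1.0, 8000.0)
        with pytest.raises(InvalidParameterError):
            revolution_crossings(ts, 4000, 20, 0.0, 0, 80.0)
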