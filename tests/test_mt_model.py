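"""Single-microtubule rules: growth noise, cue, encounters, anchoring, ends."""

import math

import numpy as np
import pytest

from cmtsim.geometry import CellSurface, ShapeSpec, build_shape
from cmtsim.mt_model import (CueField, GrowthParams, Microtubule, ModelError,
                             apply_strong_anchoring, apply_weak_anchoring,
                             circumferential_cue, classify_encounter,
                             expected_nucleations_per_step,
                             expected_step_correlation, fit_decay_rate,
                             free_growth_correlation, minus_end_update,
                             nucleate, plus_end_update,
                             propose_growth_direction)


class TestGrowthDirection:
    def test_noise_free_identity(self, rng):
        params = GrowthParams(r_d=0.0)
        out = propose_growth_direction([0, 0, 1], rng, params)
        assert np.allclose(out, [0, 0, 1])

    def test_full_cue_weight(self, rng):
        params = GrowthParams(r_d=0.0, b_d=1.0)
        out = propose_growth_direction([0, 1, 0], rng, params, b=[1, 0, 0])
        assert np.allclose(out, [1, 0, 0])

    def test_unit_norm_preserved(self, rng):
        params = GrowthParams(r_d=0.3, b_d=0.2)
        d = np.array([0.0, 0.0, 1.0])
        for _ in range(200):
            d = propose_growth_direction(d, rng, params, b=[1, 0, 0])
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)

    def test_step_correlation_matches_quadrature_oracle(self, rng):
        # E[r_{n+1}.r_n] from adaptive quadrature over c = u.r ~ U[-1,1];
        # for r_d = 0.025 this is 0.99978085 (~ 1 - r_d^2/3, not the
        # commonly quoted 1 - r_d^2/4)
        r_d = 0.025
        oracle = expected_step_correlation(r_d)
        assert oracle == pytest.approx(0.9997808459, abs=1e-9)
        params = GrowthParams(r_d=r_d)
        prev = np.array([0.0, 0.0, 1.0])
        n = 100_000
        acc = np.empty(n)
        for i in range(n):
            acc[i] = propose_growth_direction(prev, rng, params) @ prev
        sem = acc.std(ddof=1) / math.sqrt(n)
        assert abs(acc.mean() - oracle) < 4 * sem

    def test_free_decay_rate_matches_oracle(self):
        # tangent correlation decays as q^s with q the one-step expectation
        r_d = 0.025
        s, corr = free_growth_correlation(r_d, n_steps=4000, n_traj=3000,
                                          seed=99, record_every=100)
        rate = fit_decay_rate(s, corr)
        oracle_rate = -math.log(expected_step_correlation(r_d))
        assert rate == pytest.approx(oracle_rate, rel=0.05)

    def test_nominal_persistence_length(self):
        params = GrowthParams()
        assert params.persistence_length == pytest.approx(25.6)
        assert round(params.persistence_length) == 26


class TestCircumferentialCue:
    def test_basic_direction(self):
        b = circumferential_cue([1, 0, 5], [0, 0, 1])
        assert np.allclose(b, [0, 1, 0])

    def test_orthogonality_everywhere(self, rng):
        axis = np.array([0.0, 0.0, 1.0])
        for _ in range(300):
            p = rng.uniform(-5, 5, size=3)
            if np.linalg.norm(p[:2]) < 1e-6:
                continue
            b = circumferential_cue(p, axis)
            rad = np.array([p[0], p[1], 0.0])
            assert abs(b @ axis) < 1e-12
            assert abs(b @ rad) < 1e-9
            assert np.linalg.norm(b) == pytest.approx(1.0, abs=1e-12)

    def test_on_axis_error(self):
        with pytest.raises(ModelError):
            circumferential_cue([0, 0, 3], [0, 0, 1])


class TestClassifyEncounter:
    def test_shallow_angle_zippers(self):
        d = np.array([0.0, math.sin(math.radians(30)),
                      math.cos(math.radians(30))])
        outcome, aligned = classify_encounter([0, 0, 1], d, 40.0)
        assert outcome == "zipper"
        assert np.allclose(aligned, d)

    def test_perpendicular_catastrophe(self):
        outcome, aligned = classify_encounter([0, 0, 1], [1, 0, 0], 40.0)
        assert outcome == "catastrophe"
        assert aligned is None

    def test_sign_adjustment_for_antiparallel(self):
        # target at 170 deg: the line angle is 10 deg -> zipper along -target
        t = np.array([0.0, math.sin(math.radians(170)),
                      math.cos(math.radians(170))])
        outcome, aligned = classify_encounter([0, 0, 1], t, 40.0)
        assert outcome == "zipper"
        assert np.allclose(aligned, -t)
        # brute-force both signs: aligned must give the smaller angle
        assert aligned @ np.array([0, 0, 1.0]) > abs(t @ np.array([0, 0, 1.0])) - 1e-12

    def test_symmetric_under_target_flip(self, rng):
        for _ in range(200):
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            b = rng.normal(size=3)
            b /= np.linalg.norm(b)
            o1, _ = classify_encounter(a, b, 40.0)
            o2, _ = classify_encounter(a, -b, 40.0)
            assert o1 == o2
            angle = math.degrees(math.acos(min(1.0, abs(a @ b))))
            assert (o1 == "catastrophe") == (angle >= 40.0)


class TestStrongAnchoring:
    def test_projection(self):
        out = apply_strong_anchoring(np.array([1, 0, 1]) / math.sqrt(2),
                                     [0, 0, 1])
        assert np.allclose(out, [1, 0, 0])

    def test_tangential_unchanged(self):
        out = apply_strong_anchoring([0, 1, 0], [0, 0, 1])
        assert np.allclose(out, [0, 1, 0])

    def test_result_orthogonal_to_normal(self, rng):
        for _ in range(300):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            if abs(d @ n) > 0.999:
                continue
            out = apply_strong_anchoring(d, n)
            assert abs(out @ n) < 1e-9
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_parallel_to_normal_raises(self):
        with pytest.raises(ModelError):
            apply_strong_anchoring([0, 0, 1], [0, 0, 1])


class TestWeakAnchoring:
    def test_steep_angle_catastrophe(self, cube_surface, rng):
        params = GrowthParams()
        tip = np.array([0.0, 0.0, 4.4 - 0.005])
        probe = cube_surface.probe(tip)
        steep = np.array([0.0, math.cos(math.radians(60)),
                          math.sin(math.radians(60))])  # 60 deg to plane
        outcome, d = apply_weak_anchoring(tip, steep, probe, params, rng,
                                          cube_surface)
        assert outcome == "catastrophe"

    def test_tangential_accepted_unchanged(self, cube_surface, rng):
        params = GrowthParams(r_d=0.0)
        tip = np.array([0.0, 0.0, 4.4 - 0.005])
        probe = cube_surface.probe(tip)
        outcome, d = apply_weak_anchoring(tip, np.array([1.0, 0, 0]), probe,
                                          params, rng, cube_surface)
        assert outcome == "grow"
        assert np.allclose(d, [1, 0, 0])

    def test_endpoints_stay_inside(self, cube_surface, rng):
        # repeated shallow growth right at a flat face never exits the cell
        params = GrowthParams()
        mt = Microtubule(origin=np.array([0.0, 0.0, 4.4 - 0.004]),
                         directions=[np.array([1.0, 0.0, 0.0])])
        for _ in range(2000):
            plus_end_update(mt, None, cube_surface, params, rng)
        ends = mt.endpoints()
        if len(ends):
            _, _, _, sign = cube_surface.probe_points(ends)
            # inside up to a sub-nanometre surface-snapping margin
            assert sign.max() <= 1e-3


class TestNucleation:
    def test_zero_rate(self, cube_surface):
        params = GrowthParams(n_p=0.0)
        assert expected_nucleations_per_step(params, cube_surface.area) == 0.0

    def test_expected_rate_per_unit_surface(self):
        # n_p per ell^2 on the sharp-cube area gives ~3 events/step
        params = GrowthParams()
        area = 6 * 8.8 ** 2  # unsmoothed upper bound
        rate = expected_nucleations_per_step(params, area)
        assert rate == pytest.approx(4.7e-7 * area / 6.4e-5, rel=1e-12)
        assert 1.0 < rate < 4.0

    def test_initial_direction_modes(self, cube_surface, rng):
        weak = GrowthParams(nucleation_direction="isotropic")
        strong = GrowthParams(anchoring="strong")
        for _ in range(50):
            mt = nucleate(cube_surface, weak, rng)
            probe = cube_surface.probe(mt.origin)
            assert mt.directions[0] @ probe.normal <= 1e-9
            mt = nucleate(cube_surface, strong, rng)
            probe = cube_surface.probe(mt.origin)
            assert abs(mt.directions[0] @ probe.normal) < 1e-6


class TestMinusEnd:
    def test_always_starts_shrinking(self, rng):
        mt = Microtubule(origin=np.zeros(3),
                         directions=[np.array([0, 0, 1.0])] * 3)
        minus_end_update(mt, 1.0, rng)
        assert mt.minus_shrinking
        assert mt.n_segments == 3  # flip and removal are separate steps

    def test_never_shrinks_at_zero(self, rng):
        mt = Microtubule(origin=np.zeros(3),
                         directions=[np.array([0, 0, 1.0])] * 3)
        for _ in range(100):
            minus_end_update(mt, 0.0, rng)
        assert mt.n_segments == 3

    def test_disappears_after_length_steps(self, rng):
        mt = Microtubule(origin=np.zeros(3),
                         directions=[np.array([0, 0, 1.0])] * 5,
                         minus_shrinking=True)
        for k in range(5):
            assert mt.alive
            minus_end_update(mt, 1.0, rng)
        assert not mt.alive

    def test_origin_advances_with_treadmilling(self, rng):
        mt = Microtubule(origin=np.zeros(3),
                         directions=[np.array([0, 0, 1.0])] * 4,
                         minus_shrinking=True)
        tip_before = mt.tip.copy()
        minus_end_update(mt, 1.0, rng)
        assert np.allclose(mt.tip, tip_before)
        assert mt.origin[2] == pytest.approx(0.008)


class TestPlusEnd:
    def test_straight_growth_without_interactions(self, rng):
        params = GrowthParams(r_d=0.0)
        mt = Microtubule(origin=np.zeros(3),
                         directions=[np.array([1.0, 0, 0])])
        for _ in range(10):
            assert plus_end_update(mt, None, None, params, rng) == "grow"
        assert mt.n_segments == 11
        assert np.allclose(mt.tip, [11 * 0.008, 0, 0])

    def test_perpendicular_neighbor_triggers_catastrophe(self, rng):
        params = GrowthParams(r_d=0.0)
        mt = Microtubule(origin=np.zeros(3),
                         directions=[np.array([1.0, 0, 0])])
        hit = (mt.tip + [0.02, 0, 0], np.array([0, 1.0, 0]), 0.020)
        event = plus_end_update(mt, lambda tip: hit, None, params, rng)
        assert event == "catastrophe_start"
        assert mt.plus_catastrophe
        # next step shrinks by one segment
        assert plus_end_update(mt, None, None, params, rng) == "shrink"
        assert mt.n_segments == 0

    def test_shallow_neighbor_zippers_onto_host(self, rng):
        params = GrowthParams(r_d=0.0)
        host_dir = np.array([math.cos(math.radians(20)),
                             math.sin(math.radians(20)), 0.0])
        mt = Microtubule(origin=np.zeros(3),
                         directions=[np.array([1.0, 0, 0])])
        hit = (mt.tip + [0.02, 0, 0], host_dir, 0.020)
        event = plus_end_update(mt, lambda tip: hit, None, params, rng)
        assert event == "zipper"
        assert np.allclose(mt.directions[-1], host_dir)
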