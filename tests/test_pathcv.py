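"""Frame metric, reference-path construction, and path-CV evaluation."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pathmetad import (
    ParameterError,
    ReferencePath,
    build_reference_path,
    choose_lambda,
    frame_distance,
    pcv_evaluate,
    rmsd_matrix,
)
from pathmetad.pathcv import AlignmentError, IdentityCVMapping, PathCVMapping

from conftest import straight_line_frames


def brute_force_msd(config, ref, align_sel, dist_sel, n_restarts=24, seed=0):
    """Independent superposition oracle: direct minimisation over rotation
    vectors of the alignment error, then the mean-square deviation over the
    distance selection."""
    config = np.asarray(config, float)
    ref = np.asarray(ref, float)
    p, q = config[align_sel], ref[align_sel]
    pc, qc = p.mean(axis=0), q.mean(axis=0)

    def align_err(rv):
        rm = Rotation.from_rotvec(rv).as_matrix()
        fitted = (ref - qc) @ rm.T + pc
        return float(np.sum((fitted[align_sel] - config[align_sel]) ** 2))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        res = minimize(align_err, rng.normal(size=3) * 2.0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    rm = Rotation.from_rotvec(best.x).as_matrix()
    fitted = (ref - qc) @ rm.T + pc
    diff = config[dist_sel] - fitted[dist_sel]
    return float(np.mean(np.sum(diff * diff, axis=1)))


class TestFrameDistance:
    def test_identical_frames_zero(self):
        f = np.random.default_rng(0).normal(size=(6, 3))
        assert frame_distance(f, f, [0, 1, 2, 3], [4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        b = a @ rot.T + np.array([1.0, -2.0, 3.0])
        assert frame_distance(b, a, [0, 1, 2, 3], [4, 5]) < 1e-10

    def test_matches_brute_force_superposition_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            cfg = rng.normal(size=(4, 3))
            ref = rng.normal(size=(4, 3))
            mine = frame_distance(cfg, ref, [0, 1, 2], [3])
            oracle = brute_force_msd(cfg, ref, [0, 1, 2], [3], seed=trial)
            assert mine == pytest.approx(oracle, abs=1e-6)

    def test_degenerate_alignment_rejected(self):
        collinear = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 1]])
        with pytest.raises(AlignmentError):
            frame_distance(collinear, collinear, [0, 1, 2], [3])

    def test_empty_selection_rejected(self):
        f = np.zeros((4, 3))
        with pytest.raises(ParameterError):
            frame_distance(f, f, [], [3])


ALIGN = np.arange(4)
DIST = np.array([4])


class TestBuildReferencePath:
    def test_frame_count_configurations(self):
        # inner + interpolated counts as used for the two studied ligands
        frames = straight_line_frames(n_frames=60, step=0.5)
        end = frames[0].copy()
        end[4] = [40.0, 0.0, 0.0]
        for n_smd, n_interp, total in [(7, 5, 12), (6, 5, 11)]:
            path = build_reference_path(frames, 2.0, n_smd, end, n_interp,
                                        ALIGN, DIST)
            assert path.n_frames == total

    def test_straight_line_frames_exactly_spaced(self):
        frames = straight_line_frames(n_frames=40, step=0.5)
        end = frames[0].copy()
        end[4] = [30.0, 0.0, 0.0]
        path = build_reference_path(frames, 2.0, 7, end, 3, ALIGN, DIST)
        inner = path.adjacent_distances()[:6]
        assert np.allclose(inner, 2.0, atol=1e-6)

    def test_interpolated_segment_equidistant(self):
        frames = straight_line_frames(n_frames=40, step=0.5)
        end = frames[0].copy()
        end[4] = [14.0, 3.0, 0.0]
        path = build_reference_path(frames, 2.0, 5, end, 5, ALIGN, DIST)
        outer = path.adjacent_distances()[5:]
        assert np.ptp(outer) < 1e-9

    def test_too_short_trajectory_reports_achievable_count(self):
        frames = straight_line_frames(n_frames=6, step=0.5)
        end = frames[-1]
        with pytest.raises(ParameterError, match="achievable"):
            build_reference_path(frames, 2.0, 7, end, 3, ALIGN, DIST)


class TestRmsdMatrix:
    def test_collinear_path_proportional_to_index_separation(self, line_path):
        m, ok = rmsd_matrix(line_path)
        assert ok
        assert np.allclose(m, np.abs(np.subtract.outer(range(12), range(12))),
                           atol=1e-9)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_shuffled_frames_fail_gull_wing_diagnostic(self, line_path):
        rng = np.random.default_rng(4)
        frames = list(line_path.frames)
        rng.shuffle(frames)
        shuffled = ReferencePath(frames, line_path.align_selection,
                                 line_path.distance_selection,
                                 line_path.lambda_, line_path.spacing_target)
        _, ok = rmsd_matrix(shuffled)
        assert not ok


class TestPCVEvaluate:
    def test_on_frame_nearest_limit(self, line_path):
        # large lambda: s collapses to the frame index, z to zero
        line_path.lambda_ = 40.0
        for k in (1, 5, 12):
            val = pcv_evaluate(line_path.frames[k - 1], line_path)
            assert val.s == pytest.approx(k, abs=1e-6)
            assert val.z == pytest.approx(0.0, abs=1e-6)
        line_path.lambda_ = math.log(2.0)

    def test_equidistant_between_two_frames_gives_midpoint(self, line_path):
        cfg = line_path.frames[1].copy()
        cfg[4, 0] += 0.5          # halfway between frames 2 and 3
        line_path.lambda_ = 8.0   # all other frames negligible
        val = pcv_evaluate(cfg, line_path)
        assert val.s == pytest.approx(2.5, abs=1e-6)
        line_path.lambda_ = math.log(2.0)

    def test_three_frame_formula_oracle(self):
        # direct, safeguard-free evaluation of the softmax formulas for
        # d = (0.01, 0.04, 0.09) A^2 and lambda = 33 A^-2
        from pathmetad.pathcv import _pcv_from_distances

        lam = 33.0
        d = np.array([0.01, 0.04, 0.09])
        w = np.exp(-lam * d)
        s_expect = float(np.arange(1, 4) @ w / w.sum())
        z_expect = float(-math.log(w.sum()) / lam)
        s, z, _ = _pcv_from_distances(d, lam)
        assert s == pytest.approx(s_expect, abs=1e-12)
        assert z == pytest.approx(z_expect, abs=1e-12)

    def test_matches_plain_brute_force_on_random_configs(self, line_path):
        rng = np.random.default_rng(5)
        lam = line_path.lambda_
        for _ in range(100):
            cfg = line_path.frames[rng.integers(0, 12)].copy()
            cfg[4] += rng.normal(scale=1.5, size=3)
            val = pcv_evaluate(cfg, line_path)
            # naive re-implementation without log-sum-exp safeguards
            d = np.array([
                frame_distance(cfg, f, ALIGN, DIST) for f in line_path.frames
            ])
            w = np.exp(-lam * d)
            s_naive = float(np.arange(1, 13) @ w / w.sum())
            z_naive = float(-math.log(w.sum()) / lam)
            assert val.s == pytest.approx(s_naive, abs=1e-8)
            assert val.z == pytest.approx(z_naive, abs=1e-8)

    def test_bounds_invariant(self, line_path):
        rng = np.random.default_rng(6)
        n = line_path.n_frames
        for _ in range(50):
            cfg = line_path.frames[0].copy()
            cfg[4] = rng.normal(scale=6.0, size=3)
            val = pcv_evaluate(cfg, line_path)
            assert 1.0 - 1e-9 <= val.s <= n + 1e-9
            assert val.z >= -math.log(n) / line_path.lambda_ - 1e-9

    def test_gradient_matches_central_differences(self, line_path):
        rng = np.random.default_rng(7)
        h = 1e-6
        for _ in range(5):
            cfg = line_path.frames[3].copy()
            cfg[4] += rng.normal(scale=0.8, size=3)
            val = pcv_evaluate(cfg, line_path, gradient_indices=[4])
            for k in range(3):
                e = np.zeros((5, 3))
                e[4, k] = h
                sp = pcv_evaluate(cfg + e, line_path)
                sm = pcv_evaluate(cfg - e, line_path)
                num_s = (sp.s - sm.s) / (2 * h)
                num_z = (sp.z - sm.z) / (2 * h)
                assert val.grad_s[0, k] == pytest.approx(
                    num_s, rel=1e-5, abs=1e-7)
                assert val.grad_z[0, k] == pytest.approx(
                    num_z, rel=1e-5, abs=1e-7)

    def test_gradient_atoms_must_not_align(self, line_path):
        with pytest.raises(ParameterError):
            pcv_evaluate(line_path.frames[0], line_path, gradient_indices=[0])

    def test_progress_monotone_along_seed_track(self, line_path):
        # s evaluated along the ordered generating track never decreases
        # by more than the tolerance
        svals = []
        for x in np.linspace(0.0, 11.0, 45):
            cfg = line_path.frames[0].copy()
            cfg[4] = [x, 0.0, 0.0]
            svals.append(pcv_evaluate(cfg, line_path).s)
        assert np.all(np.diff(svals) > -0.2)

    def test_mapping_fast_route_matches_generic(self, host_guest):
        n_host = len(host_guest.host_coords)
        base = host_guest.frame_coords(host_guest.default_start())
        frames = []
        for x in np.linspace(0.0, 10.0, 12):
            f = base.copy()
            f[n_host] = [x, 0.0, 0.0]
            frames.append(f)
        path = ReferencePath(frames, np.arange(n_host), [n_host], 0.3, 1.0)
        mapping = PathCVMapping(path, host_guest)
        assert mapping._fast
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.uniform(-3, 11, 2)
            s, z, ds, dz = mapping.evaluate(x)
            val = pcv_evaluate(host_guest.frame_coords(x), path,
                               gradient_indices=[n_host])
            assert s == pytest.approx(val.s, abs=1e-10)
            assert z == pytest.approx(val.z, abs=1e-10)
            assert np.allclose(ds[:2], val.grad_s[0, :2], atol=1e-10)
            assert np.allclose(dz[:2], val.grad_z[0, :2], atol=1e-10)


class TestChooseLambda:
    def test_uniform_spacing_value(self):
        # adjacent squared distance uniformly 0.021 A^2 -> lambda = ln2/0.021
        step = math.sqrt(0.021)
        frames = straight_line_frames(n_frames=3, step=step)
        path = ReferencePath(frames, ALIGN, DIST, 1.0, step)
        assert choose_lambda(path) == pytest.approx(33.007, abs=0.01)

    def test_coordinate_scaling(self, line_path):
        lam = choose_lambda(line_path)
        doubled = ReferencePath([2.0 * f for f in line_path.frames],
                                line_path.align_selection,
                                line_path.distance_selection, 1.0, 2.0)
        assert choose_lambda(doubled) == pytest.approx(lam / 4.0, rel=1e-9)

    def test_coincident_frames_rejected(self, line_path):
        frames = [line_path.frames[0]] * 3
        path = ReferencePath(frames, ALIGN, DIST, 1.0, 1.0)
        with pytest.raises(ParameterError):
            choose_lambda(path)


def test_identity_mapping_is_trivial():
    m = IdentityCVMapping()
    s, z, ds, dz = m.evaluate(np.array([1.7]))
    assert (s, z) == (1.7, 0.0)
    assert ds[0] == 1.0 and dz[0] == 0.0


def test_progress_invariant_under_rigid_motion_of_query(line_path):
    # with the host spanned by the alignment selection, superposition
    # removes any rigid motion applied to the query configuration
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(9)
    for _ in range(5):
        cfg = line_path.frames[4].copy()
        cfg[4] += rng.normal(scale=1.0, size=3)
        base = pcv_evaluate(cfg, line_path)
        rot = Rotation.random(random_state=rng.integers(1 << 30)).as_matrix()
        moved = cfg @ rot.T + rng.normal(scale=5.0, size=3)
        val = pcv_evaluate(moved, line_path)
        assert val.s == pytest.approx(base.s, abs=1e-8)
        assert val.z == pytest.approx(base.z, abs=1e-8)
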