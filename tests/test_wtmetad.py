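"""Well-tempered bias machinery, biased runs, FES reconstruction and the
binding-free-energy analysis."""

import math

import numpy as np
import pytest

from pathmetad import (
    FreeEnergySurface,
    HillRecord,
    IdentityCVMapping,
    LangevinParams,
    ParameterError,
    Profile1D,
    UnconvergedError,
    WallSpec,
    WTParams,
    bias_potential,
    binding_free_energy,
    convergence_series,
    hill_height,
    make_double_well,
    project_fes_1d,
    reconstruct_fes,
    run_langevin,
    run_wt_metad,
    sigma_from_unbiased,
)
from pathmetad.units import KB, KJ_TO_KCAL
from pathmetad.wtmetad import GridBias

W0_DEFAULT = 1.0 * KJ_TO_KCAL


class TestHillHeight:
    def test_zero_bias_gives_initial_height(self):
        p = WTParams()
        assert hill_height(0.0, p) == pytest.approx(W0_DEFAULT, abs=1e-12)

    def test_bias_equal_kb_delta_t_gives_w0_over_e(self):
        p = WTParams(bias_factor=10.0, temperature=300.0)
        v = KB * p.delta_t
        assert hill_height(v, p) == pytest.approx(W0_DEFAULT / math.e, rel=1e-12)

    def test_formula_evaluation(self):
        # gamma = 10, T = 300 -> DeltaT = 2700 K; V = 1 kcal/mol
        p = WTParams(bias_factor=10.0, temperature=300.0)
        assert p.delta_t == pytest.approx(2700.0)
        assert hill_height(1.0, p) == pytest.approx(
            W0_DEFAULT * 0.8299601263577688, rel=1e-12)

    def test_bias_factor_must_exceed_one(self):
        with pytest.raises(ParameterError):
            WTParams(bias_factor=1.0)


class TestBiasPotential:
    HILL = HillRecord(time=1.0, center=(3.0, 0.5), widths=(0.1, 0.05), height=0.3)

    def test_no_hills_zero(self):
        assert bias_potential((2.0, 0.1), []) == 0.0

    def test_at_center_equals_height(self):
        assert bias_potential((3.0, 0.5), [self.HILL]) == pytest.approx(0.3)

    def test_one_sigma_offset(self):
        v = bias_potential((3.1, 0.5), [self.HILL])
        assert v == pytest.approx(0.3 * math.exp(-0.5), rel=1e-12)

    def test_gradient_matches_central_difference(self):
        hills = [self.HILL,
                 HillRecord(time=2.0, center=(2.8, 0.4), widths=(0.2, 0.1),
                            height=0.2)]
        pt = (2.93, 0.47)
        v, dvs, dvz = bias_potential(pt, hills, gradient=True)
        h = 1e-7
        num_s = (bias_potential((pt[0] + h, pt[1]), hills)
                 - bias_potential((pt[0] - h, pt[1]), hills)) / (2 * h)
        num_z = (bias_potential((pt[0], pt[1] + h), hills)
                 - bias_potential((pt[0], pt[1] - h), hills)) / (2 * h)
        assert dvs == pytest.approx(num_s, rel=1e-6)
        assert dvz == pytest.approx(num_z, rel=1e-6)


def test_grid_bias_interpolation_error_below_contract():
    rng = np.random.default_rng(0)
    grid = GridBias(np.linspace(0.0, 10.0, 200), np.linspace(0.0, 2.0, 200))
    hills = []
    for _ in range(50):
        h = HillRecord(time=1.0,
                       center=(rng.uniform(1, 9), rng.uniform(0.2, 1.8)),
                       widths=(0.3, 0.12), height=rng.uniform(0.05, 0.3))
        hills.append(h)
        grid.add_hill(h)
    for _ in range(200):
        s, z = rng.uniform(0.5, 9.5), rng.uniform(0.1, 1.9)
        exact = bias_potential((s, z), hills)
        approx, _, _ = grid.value_and_grad(s, z)
        assert abs(approx - exact) < 1e-3


@pytest.fixture(scope="module")
def asym_metad_run():
    """Well-tempered run on the asymmetric double well, shared by the FES
    and convergence tests."""
    surf = make_double_well(5.0, 4.0, 2.0)
    lo, hi = surf.domain_bounds[0]
    grid = (np.linspace(lo, hi, 400), np.array([0.0]))
    params = WTParams(sigma_s=0.2, sigma_z=0.7)
    run = run_wt_metad(surf, IdentityCVMapping(), params, None,
                       LangevinParams(seed=21), 300_000, grid=grid)
    return surf, grid, run


class TestRunWTMetad:
    def test_zero_height_reduces_to_unbiased_bit_exactly(self):
        surf = make_double_well(5.0, 4.0, 0.0)
        lp = LangevinParams(seed=13)
        grid = (np.linspace(*surf.domain_bounds[0], 100), np.array([0.0]))
        run = run_wt_metad(surf, IdentityCVMapping(),
                           WTParams(w0=0.0, sigma_s=0.2), None, lp, 20_000,
                           grid=grid, colvar_stride=10)
        ref = run_langevin(surf, lp, 20_000, sample_stride=10)
        assert run.hills == []
        assert np.array_equal(run.positions[:, 0], ref.positions[:, 0])

    def test_hill_heights_non_increasing_at_revisited_points(self, asym_metad_run):
        _, _, run = asym_metad_run
        # bin hill centres at ~0.1 sigma_s; within a bin the bias only
        # grows, so deposited heights must not increase (1% slack for the
        # residual spatial spread inside a bin)
        bins = {}
        for h in run.hills:
            key = round(h.center[0] / 0.02)
            bins.setdefault(key, []).append(h.height)
        checked = 0
        for heights in bins.values():
            for a, b in zip(heights, heights[1:]):
                assert b <= a * 1.01
                checked += 1
        assert checked > 50

    def test_heights_bounded_by_w0_and_positive(self, asym_metad_run):
        _, _, run = asym_metad_run
        p = run.params
        assert all(0 < h.height <= p.w0 + 1e-12 for h in run.hills)

    def test_free_energy_recovery_within_half_kcal(self, asym_metad_run):
        from pathmetad import double_well_free_energy_difference

        surf, grid, run = asym_metad_run
        fes = reconstruct_fes(run.hills, grid)
        prof = project_fes_1d(fes)
        kT = KB * 300.0
        top = surf.metadata["barrier_top"]
        mask = prof.s < top
        za = np.trapezoid(np.exp(-prof.F[mask] / kT), prof.s[mask])
        zb = np.trapezoid(np.exp(-prof.F[~mask] / kT), prof.s[~mask])
        est = -kT * math.log(zb / za)
        oracle = double_well_free_energy_difference(surf, 300.0)
        assert est == pytest.approx(oracle, abs=0.5)


class TestReconstructFes:
    GRID = (np.linspace(0.0, 6.0, 121), np.linspace(0.0, 1.0, 41))

    def test_single_hill_scaled_inverted_gaussian(self):
        hill = HillRecord(time=1.0, center=(3.0, 0.5), widths=(0.3, 0.1),
                          height=0.25)
        fes = reconstruct_fes([hill], self.GRID, 300.0, 10.0)
        i = np.argmin(np.abs(self.GRID[0] - 3.0))
        j = np.argmin(np.abs(self.GRID[1] - 0.5))
        assert fes.F[i, j] == pytest.approx(0.0, abs=1e-9)
        # far from the hill, F plateaus at (T+DT)/DT * height = (10/9)*h
        assert fes.F[0, 0] == pytest.approx(10.0 / 9.0 * 0.25, abs=1e-4)

    def test_doubling_heights_preserves_argmin(self):
        rng = np.random.default_rng(1)
        hills = [HillRecord(time=i, center=(rng.uniform(1, 5), rng.uniform(0.1, 0.9)),
                            widths=(0.4, 0.15), height=rng.uniform(0.1, 0.3))
                 for i in range(20)]
        f1 = reconstruct_fes(hills, self.GRID)
        doubled = [HillRecord(h.time, h.center, h.widths, 2 * h.height)
                   for h in hills]
        f2 = reconstruct_fes(doubled, self.GRID)
        assert np.argmin(f1.F) == np.argmin(f2.F)

    def test_requires_hills_and_grid(self):
        with pytest.raises(ParameterError):
            reconstruct_fes([], self.GRID)


class TestProjection:
    def _fes(self, F):
        s = np.linspace(0.0, 5.0, 60)
        z = np.linspace(0.0, 2.0, 30)
        return FreeEnergySurface(s, z, F(s[:, None], z[None, :]), 300.0, 10.0)

    def test_z_independent_surface_projects_to_any_slice(self):
        fes = self._fes(lambda s, z: np.cos(s) + 0 * z)
        prof = project_fes_1d(fes)
        slice0 = fes.F[:, 0] - fes.F[:, 0].min()
        assert np.allclose(prof.F, slice0, atol=1e-9)

    def test_separable_surface_projects_to_s_part(self):
        fes = self._fes(lambda s, z: np.cos(s) + 0.5 * z**2)
        prof = project_fes_1d(fes)
        expect = np.cos(fes.s_grid)
        expect -= expect.min()
        assert np.allclose(prof.F, expect, atol=1e-9)


def _profile(F, s=None, visited=None):
    F = np.asarray(F, dtype=float)
    s = np.linspace(1.0, 12.0, len(F)) if s is None else s
    visited = np.ones(len(F), bool) if visited is None else visited
    return Profile1D(s=s, F=F, temperature=300.0, visited=visited)


class TestBindingFreeEnergy:
    def test_flat_profile_zero(self):
        bfe = binding_free_energy(_profile(np.zeros(100)))
        assert bfe.value == pytest.approx(0.0)
        assert bfe.plateau_sd == pytest.approx(0.0)

    def test_synthetic_deep_bound_minimum(self):
        s = np.linspace(1.0, 12.0, 221)
        F = np.zeros_like(s)
        F[(s >= 1) & (s <= 3)] = -11.8     # deepest bound minimum vs plateau 0
        bfe = binding_free_energy(_profile(F, s=s))
        assert bfe.value == pytest.approx(-11.8)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        F = rng.uniform(0, 5, 200)
        a = binding_free_energy(_profile(F)).value
        b = binding_free_energy(_profile(F + 3.7)).value
        assert a == pytest.approx(b, abs=1e-9)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ParameterError):
            binding_free_energy(_profile(np.zeros(50)), (1, 5), (4, 9))

    def test_unvisited_plateau_raises_unconverged(self):
        visited = np.ones(100, bool)
        visited[40:] = False
        with pytest.raises(UnconvergedError):
            binding_free_energy(_profile(np.zeros(100), visited=visited))


class TestConvergenceSeries:
    @staticmethod
    def _regions(surf):
        top = surf.metadata["barrier_top"]
        lo, hi = surf.domain_bounds[0]
        return (lo, top), (top, hi)

    def test_hill_heights_decay(self, asym_metad_run):
        surf, grid, run = asym_metad_run
        bound, unbound = self._regions(surf)
        _, _, _, heights = convergence_series(run.hills, 50, grid,
                                              bound_region=bound,
                                              unbound_region=unbound)
        n = len(heights) // 10
        assert heights[-n:].mean() < heights[:n].mean()

    def test_single_checkpoint(self, asym_metad_run):
        surf, grid, run = asym_metad_run
        bound, unbound = self._regions(surf)
        t, df, _, _ = convergence_series(run.hills, len(run.hills) + 10, grid,
                                         bound_region=bound,
                                         unbound_region=unbound)
        assert len(t) == len(df) == 1


class TestSigmaFromUnbiased:
    def test_third_of_sd_rule(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        x = x / x.std(ddof=1)
        series = np.column_stack([0.15 * x, 0.021 * x])
        sig_s, sig_z = sigma_from_unbiased(series)
        assert sig_s == pytest.approx(0.05, abs=1e-12)
        assert sig_z == pytest.approx(0.007, abs=1e-12)

    def test_gaussian_sampling_accuracy(self):
        rng = np.random.default_rng(4)
        series = rng.normal(0.0, 0.3, size=(100_000, 1))
        (sig,) = sigma_from_unbiased(series)
        assert sig == pytest.approx(0.1, rel=0.02)

    def test_constant_and_short_series_rejected(self):
        with pytest.raises(ParameterError):
            sigma_from_unbiased(np.ones((200, 1)))
        with pytest.raises(ParameterError):
            sigma_from_unbiased(np.random.default_rng(0).normal(size=(50, 2)))


def test_wall_energy_zero_inside_quadratic_outside():
    w = WallSpec(s_max=12.0, z_max=20.0, kappa_s=100.0, kappa_z=0.5)
    assert w.energy_grad(5.0, 10.0) == (0.0, 0.0, 0.0)
    v, gs, gz = w.energy_grad(12.5, 21.0)
    assert v == pytest.approx(100.0 * 0.25 + 0.5 * 1.0)
    assert gs == pytest.approx(2 * 100.0 * 0.5)
    assert gz == pytest.approx(2 * 0.5 * 1.0)


def test_wall_containment_on_biased_host_guest_run(host_guest):
    """Upper walls keep the sampled CVs essentially inside their limits:
    fewer than 0.1% of samples stray beyond limit + 3 sigma."""
    from pathmetad import PathCVMapping, ReferencePath, run_wt_metad
    from pathmetad.units import KJ_TO_KCAL

    n_host = len(host_guest.host_coords)
    base = host_guest.frame_coords(host_guest.default_start())
    frames = []
    for x in np.linspace(0.0, 10.0, 12):
        f = base.copy()
        f[n_host] = [x, 0.0, 0.0]
        frames.append(f)
    path = ReferencePath(frames, np.arange(n_host), [n_host], 0.8, 1.0)
    mapping = PathCVMapping(path, host_guest)
    params = WTParams(w0=4 * KJ_TO_KCAL, sigma_s=0.12, sigma_z=0.3)
    walls = WallSpec(s_max=12.0, z_max=10.0, kappa_z=0.5)
    run = run_wt_metad(host_guest, mapping, params, walls,
                       LangevinParams(seed=99), 200_000)
    s, z = run.colvar.s, run.colvar.z
    frac = np.mean((s > walls.s_max + 3 * params.sigma_s)
                   | (z > walls.z_max + 3 * params.sigma_z))
    assert frac < 1e-3
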