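import numpy as np
import pytest

from conftest import analytic_reference
from ureaconf import sim, wham
from ureaconf.geometry import wrap_angle
from ureaconf.sim import SimConfig, TrajectorySample, UmbrellaWindow


def _window(angles, center=0.0, k=0.0, temperature=300.0):
    return UmbrellaWindow(
        center=center, k=k,
        samples=TrajectorySample(
            angles=np.asarray(angles, float), dt=0.02,
            temperature=temperature, seed=0, stride=1,
        ),
    )


class TestBuildInput:
    def test_row_sums_conserve_snapshots(self):
        w1 = _window(np.linspace(-170, 170, 10))
        w2 = _window(np.linspace(-10, 10, 10), center=10.0, k=0.01)
        inp = wham.build_wham_input([w1, w2], bin_width=10.0)
        assert inp.counts.sum(axis=1).tolist() == [10.0, 10.0]

    def test_periodic_neighbors_near_the_seam(self):
        inp = wham.build_wham_input([_window([-180.0, 179.99])], bin_width=3.0)
        occupied = np.where(inp.counts[0] > 0)[0]
        # -180 and +179.99 are 0.01 deg apart on the circle: same or
        # adjacent periodic bin, never opposite ends of the grid
        assert len(occupied) == 2
        gap = (occupied[1] - occupied[0]) % inp.counts.shape[1]
        assert min(gap, inp.counts.shape[1] - gap) == 1

    def test_bias_at_opposite_point_reaches_200(self):
        w = UmbrellaWindow(center=-180.0, k=sim.bias_constant())
        # a full half-turn displacement costs exactly the 200 kcal/mol the
        # protocol prescribes over 180 deg
        assert w.bias(0.0) == pytest.approx(200.0)
        inp = wham.build_wham_input([_window([0.0], center=-180.0, k=w.k)], bin_width=3.0)
        d = wrap_angle(inp.bin_centers - (-180.0))
        v = inp.bias_matrix[0]
        assert v.max() == pytest.approx(200.0, rel=0.02)
        assert v[np.argmax(np.abs(d))] == pytest.approx(v.max())

    def test_empty_windows_excluded_with_warning(self):
        w1 = _window(np.linspace(-170, 170, 50))
        w2 = UmbrellaWindow(center=0.0, k=0.01, samples=None)
        with pytest.warns(UserWarning):
            inp = wham.build_wham_input([w1, w2], bin_width=10.0)
        assert inp.counts.shape[0] == 1


class TestWhamSolve:
    def test_degenerate_single_window_equals_boltzmann_inversion(self):
        """Zero-bias single-window WHAM is exactly direct inversion."""
        rng = np.random.default_rng(0)
        angles = wrap_angle(rng.uniform(-180, 180, 4000))
        inp = wham.build_wham_input([_window(angles)], bin_width=10.0)
        profile = wham.wham_solve(inp)
        direct = wham.boltzmann_invert(inp.counts[0], 300.0)
        assert np.array_equal(profile.free_energy, direct)

    def test_flat_potential_two_wide_windows(self):
        """Two opposing wide harmonic windows on a flat landscape, each
        sampled from its exact biased Boltzmann density, re-weight back to
        a flat profile."""
        rng = np.random.default_rng(3)
        kbt = sim.KB_KCAL * 300.0
        sigma = 60.0
        k = kbt / (2.0 * sigma**2)  # harmonic window with 60 deg spread
        windows = [
            _window(wrap_angle(rng.normal(c, sigma, 50000)), center=c, k=k)
            for c in (0.0, -180.0)
        ]
        profile = wham.wham_solve(wham.build_wham_input(windows, bin_width=10.0))
        assert profile.free_energy.max() < 0.15

    def test_uncovered_bins_are_an_error(self):
        with pytest.raises(ValueError, match="uncovered"):
            wham.wham_solve(
                wham.build_wham_input([_window(np.zeros(100))], bin_width=10.0)
            )

    def test_gauge_invariance_of_min_shifted_profile(self, vacuum_windows):
        inp = wham.build_wham_input(vacuum_windows, bin_width=3.0)
        p1 = wham.wham_solve(inp)
        p2 = wham.wham_solve(inp, f_init=p1.window_free_energies + 7.0)
        assert np.allclose(p1.free_energy, p2.free_energy, atol=1e-5)

    def test_rotation_equivariance(self):
        flat = sim.get_preset("flat")
        windows = sim.make_umbrella_protocol(n_windows=24, shift=15.0)
        cfg = SimConfig(n_snapshots=500, seed=9)
        sampled = sim.run_umbrella_protocol(flat, windows, cfg)
        p1 = wham.wham_solve(wham.build_wham_input(sampled, bin_width=15.0))
        rotated = [
            UmbrellaWindow(
                center=float(wrap_angle(w.center + 30.0)), k=w.k,
                samples=TrajectorySample(
                    angles=wrap_angle(w.samples.angles + 30.0),
                    dt=w.samples.dt, temperature=w.samples.temperature,
                    seed=w.samples.seed, stride=w.samples.stride,
                ),
            )
            for w in sampled
        ]
        p2 = wham.wham_solve(wham.build_wham_input(rotated, bin_width=15.0))
        assert np.allclose(np.roll(p1.free_energy, 2), p2.free_energy, atol=1e-9)

    def test_residual_trace_decreases_after_transient(self, vacuum_profile):
        """The self-consistency residual decays monotonically once the
        initial cold-start transient (first couple of iterations) passes,
        and ends below the convergence tolerance."""
        trace = vacuum_profile.residual_trace
        assert trace[-1] < 1e-7
        assert np.all(np.diff(trace[2:]) <= 0)

    def test_recovers_analytic_vacuum_profile(self, vacuum_windows, vacuum_potential, vacuum_profile):
        """Full 121-window protocol reconstructs the analytic potential to
        better than 0.3 kcal/mol everywhere."""
        ref = analytic_reference(vacuum_potential, vacuum_profile.angles)
        assert np.abs(vacuum_profile.free_energy - ref).max() < 0.3


class TestFeatures:
    def test_analytic_double_well_features(self):
        pot = sim.get_preset("paper_vacuum")
        phi = np.arange(-180.0, 180.0, 0.1)
        u = pot.energy(phi)
        f = wham.pmf_features(phi, u - u.min())
        assert f.trans_angle == pytest.approx(0.0, abs=0.1)
        assert abs(f.cis_angle) == pytest.approx(180.0, abs=0.2)
        assert f.delta_g == pytest.approx(4.1, abs=1e-3)
        assert f.barrier == pytest.approx(14.0, abs=1e-3)
        assert f.ts_angle == pytest.approx(94.96, abs=0.1)

    def test_solution_preset_features(self):
        """Densely sampled solution-phase profile returns the 5.7 kcal/mol
        cis offset and 14.8 kcal/mol barrier it encodes."""
        pot = sim.get_preset("paper_solution")
        phi = np.arange(-180.0, 180.0, 0.05)
        u = pot.energy(phi)
        f = wham.pmf_features(phi, u - u.min())
        assert f.delta_g == pytest.approx(5.7, abs=1e-3)
        assert f.barrier == pytest.approx(14.8, abs=1e-3)

    def test_flat_profile(self):
        phi = np.arange(-180.0, 180.0, 3.0)
        f = wham.pmf_features(phi, np.zeros_like(phi))
        assert f.delta_g == 0.0
        assert f.barrier == 0.0

    def test_missing_cis_minimum_flagged(self):
        # single well at 0, monotone rise to 180: no cis minimum exists
        phi = np.arange(-180.0, 180.0, 1.0)
        u = 3.0 * (1.0 - np.cos(np.radians(phi)))
        f = wham.pmf_features(phi, u - u.min())
        assert not f.cis_is_local_min
        assert abs(f.cis_angle) == pytest.approx(180.0, abs=1.0)
        assert f.delta_g == pytest.approx(6.0, abs=1e-3)


class TestBootstrap:
    def test_duplicate_data_gives_zero_errors(self):
        rng = np.random.default_rng(1)
        windows = [
            _window(rng.uniform(-180, 180, 3000)),
            _window(rng.uniform(-180, 180, 3000)),
        ]
        per_bin, feat_err, _ = wham.bootstrap_errors(
            windows, n_subsets=4, subset_fraction=1.0, replace=False,
            seed=2, bin_width=10.0,
        )
        assert per_bin.max() == pytest.approx(0.0, abs=1e-12)
        assert feat_err["delta_g"] == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_usable_subsets(self):
        rng = np.random.default_rng(4)
        w = _window(rng.uniform(-180, 180, 500))
        with pytest.raises(RuntimeError, match="subsets"):
            wham.bootstrap_errors([w], n_subsets=2, bin_width=30.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        windows = [
            _window(rng.uniform(-180, 180, 2000)),
            _window(rng.uniform(-180, 180, 2000)),
        ]
        a = wham.bootstrap_errors(windows, n_subsets=3, seed=5, bin_width=10.0)[0]
        b = wham.bootstrap_errors(windows, n_subsets=3, seed=5, bin_width=10.0)[0]
        assert np.array_equal(a, b)
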