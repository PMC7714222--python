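import numpy as np
import pytest

from dgfold.exceptions import (ChainTooShortError, ConfigError,
                               DivergenceError)
from dgfold.formats import Restraint, RestraintSet
from dgfold.geometry import (CaTrace, cartesian_to_internal,
                             pairwise_distances)
from dgfold.optimize import (CascadeSpec, GDConfig, SAConfig,
                             benchmark_cascade, case_study_cascade,
                             cascade_from_dict, extended_state,
                             gradient_descent, preset_cascade, run_cascade,
                             simulated_annealing)
from dgfold.perturb import near_native_restraints


def exact_bounds(trace):
    """Zero-width restraints pinning every pair at its true distance."""
    d = pairwise_distances(trace)
    L = len(trace)
    return RestraintSet(L, [
        Restraint(i + 1, j + 1, float(d[i, j]), float(d[i, j]))
        for i in range(L) for j in range(i + 1, L)
    ])


class TestExtendedState:
    def test_three_residue_law_of_cosines(self):
        t = extended_state(3)
        expected = 3.8 * np.sqrt(2.0 - 2.0 * np.cos(np.deg2rad(135.0)))
        assert np.linalg.norm(t.coords[2] - t.coords[0]) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(7.0224, abs=1e-3)

    def test_deterministic_bitwise(self):
        assert np.array_equal(extended_state(20).coords,
                              extended_state(20).coords)

    def test_end_to_end_increases_with_length(self):
        # oracle: direct computation on the zig-zag geometry
        prev = 0.0
        for L in range(3, 51):
            t = extended_state(L)
            e2e = float(np.linalg.norm(t.coords[-1] - t.coords[0]))
            assert e2e > prev
            prev = e2e

    def test_too_short(self):
        with pytest.raises(ChainTooShortError):
            extended_state(1)


class TestGradientDescent:
    def test_fixed_point_at_zero_energy(self):
        t = extended_state(5)
        rs = exact_bounds(t)
        traj = gradient_descent(t, rs, GDConfig(iterations=50))
        assert np.allclose(traj.final_trace.coords, t.coords, atol=1e-12)

    def test_two_point_monotone_to_flat_bottom(self):
        # 1-D oracle: x <- x - step*2(x-8)/L per iteration until x <= 8
        rs = RestraintSet(2, [Restraint(1, 2, 4.0, 8.0)])
        t = CaTrace([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        step = 0.01
        traj = gradient_descent(t, rs, GDConfig(step_size=step, iterations=40,
                                                report_every=1,
                                                centering=0.0))
        es = traj.energies
        assert np.all(np.diff(es) < 0)
        # closed-form iterate of the per-residue objective (L = 2):
        # E(d) = max(d-8, 0)^2/2 + 5 (d-3.8)^2, both endpoints step along
        # the axis so d shrinks by 2*step*dE/dd per iteration
        d = 10.0
        for k in range(5):
            e = max(d - 8.0, 0.0) ** 2 / 2.0 + 5.0 * (d - 3.8) ** 2
            assert es[k] == pytest.approx(e, rel=1e-9)
            d -= step * 2.0 * (max(d - 8.0, 0.0) + 10.0 * (d - 3.8))
        assert traj.final_energy < es[0]

    def test_helix_reconstruction_energy_drops(self, helix30):
        trace, _ = helix30
        rs = exact_bounds(trace)
        traj = run_cascade(rs, benchmark_cascade())
        assert traj.final_energy < 0.01 * traj.initial_energy

    def test_divergence_guard(self):
        rs = RestraintSet(2, [Restraint(1, 2, 4.0, 8.0)])
        t = CaTrace([[0.0, 0.0, 0.0], [1000.0, 0.0, 0.0]])
        with pytest.raises(DivergenceError, match="step_size"):
            gradient_descent(t, rs, GDConfig(step_size=50.0, iterations=500))

    def test_cancellation_returns_partial(self):
        t = extended_state(30)
        rs = near_native_restraints(t)
        calls = []

        def stop():
            calls.append(1)
            return len(calls) >= 2

        traj = gradient_descent(t, rs, GDConfig(iterations=5000,
                                                report_every=10), stop=stop)
        assert traj.stages[0].iterations[-1] < 5000


class TestSimulatedAnnealing:
    def test_seeded_bitwise_reproducibility(self, helix30):
        trace, _ = helix30
        rs = near_native_restraints(trace)
        start = extended_state(30)
        cfg = SAConfig(seed=0, iterations=2000)
        a = simulated_annealing(start, rs, cfg)
        b = simulated_annealing(start, rs, cfg)
        assert np.array_equal(a.final_trace.coords, b.final_trace.coords)
        assert np.array_equal(a.energies, b.energies)

    def test_different_seeds_differ(self, helix30):
        trace, _ = helix30
        rs = near_native_restraints(trace)
        start = extended_state(30)
        a = simulated_annealing(start, rs, SAConfig(seed=0, iterations=2000))
        b = simulated_annealing(start, rs, SAConfig(seed=1, iterations=2000))
        assert not np.array_equal(a.final_trace.coords, b.final_trace.coords)

    def test_greedy_limit_monotone(self, helix30):
        trace, _ = helix30
        rs = near_native_restraints(trace)
        cfg = SAConfig(seed=3, iterations=3000, t_initial=1e-12,
                       t_final=1e-12, report_every=1)
        traj = simulated_annealing(extended_state(30), rs, cfg)
        assert np.all(np.diff(traj.energies) <= 1e-12)

    def test_lowers_energy_from_extended(self, helix30):
        trace, _ = helix30
        rs = near_native_restraints(trace)
        traj = simulated_annealing(extended_state(30), rs,
                                   SAConfig(seed=0, iterations=5000))
        assert traj.final_energy < traj.initial_energy

    def test_bond_lengths_preserved(self, rng, helix30):
        trace, _ = helix30
        rs = near_native_restraints(trace)
        cfg = SAConfig(seed=1, iterations=1500, relax_every=0)
        traj = simulated_annealing(extended_state(30), rs, cfg)
        bonds = cartesian_to_internal(traj.final_trace).bond_lengths
        assert np.allclose(bonds, 3.8, atol=1e-9)


class TestCascade:
    def test_single_stage_equals_direct_call(self, helix30):
        trace, _ = helix30
        rs = near_native_restraints(trace)
        cfg = SAConfig(seed=5, iterations=1000)
        direct = simulated_annealing(extended_state(30), rs, cfg)
        spec = CascadeSpec((("sa", cfg),))
        via_cascade = run_cascade(rs, spec)
        assert np.array_equal(direct.final_trace.coords,
                              via_cascade.final_trace.coords)

    def test_benchmark_preset_stages(self):
        spec = benchmark_cascade()
        kinds = [k for k, _ in spec.stages]
        assert kinds == ["gd", "gd"]
        assert spec.stages[0][1].step_size == 0.005
        assert spec.stages[1][1].step_size == 0.0001
        assert all(c.iterations == 65000 for _, c in spec.stages)

    def test_case_study_preset_structure(self):
        spec = case_study_cascade(seed=0)
        kinds = [k for k, _ in spec.stages]
        assert kinds == ["sa", "gd", "gd", "gd"]
        assert spec.stages[0][1].seed == 0

    def test_cascade_not_worse_than_first_stage(self, helix30):
        trace, _ = helix30
        rs = exact_bounds(trace)
        spec = CascadeSpec((
            ("sa", SAConfig(seed=0, iterations=2000)),
            ("gd", GDConfig(iterations=5000)),
        ))
        first = run_cascade(rs, CascadeSpec(spec.stages[:1]))
        full = run_cascade(rs, spec)
        assert full.final_energy <= first.final_energy + 1e-12

    def test_empty_cascade_rejected(self):
        with pytest.raises(ConfigError):
            CascadeSpec(())

    def test_unknown_preset(self):
        with pytest.raises(ConfigError):
            preset_cascade("nope")

    def test_cascade_from_dict(self):
        spec = cascade_from_dict({"stages": [
            {"kind": "sa", "seed": 7, "iterations": 100},
            {"kind": "gd", "step_size": 0.01, "iterations": 10},
        ]})
        assert spec.stages[0][1].seed == 7
        assert spec.stages[1][1].step_size == 0.01

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            GDConfig(step_size=-1.0)
        with pytest.raises(ConfigError):
            SAConfig(t_initial=0.1, t_final=1.0)
        with pytest.raises(ConfigError):
            SAConfig(cooling="linear")
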