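"""Monte Carlo pose search: moves, annealing, ensembles."""

import numpy as np
import pytest
from scipy.stats import chisquare

import swdock.docking as docking
from swdock.docking import (
    ComplexEnsemble,
    DockedComplex,
    MCSchedule,
    RigidPose,
    ensemble_dock,
    initial_placement,
    mc_dock,
    propose_move,
)
from swdock.energy import interface_energy
from swdock.fixtures import FixtureSpec, make_toy_unit
from swdock.structure import prepare_unit

from conftest import build_unit

IDENTITY_Q = np.array([0.0, 0.0, 0.0, 1.0])


class TestRigidPose:
    def test_apply_invert_roundtrip(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=4)
        pose = RigidPose(q / np.linalg.norm(q), rng.normal(size=3))
        x = rng.normal(size=(40, 3))
        back = pose.inverse_apply(pose.apply(x))
        assert np.allclose(back, x, atol=1e-9)

    def test_unnormalized_quaternion_rejected(self):
        with pytest.raises(ValueError):
            RigidPose(np.array([1.0, 1.0, 0.0, 0.0]), np.zeros(3))

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            MCSchedule(t_start=-1.0)
        with pytest.raises(ValueError):
            MCSchedule(n_steps=0)


class TestInitialPlacement:
    def test_deterministic(self, params, donor_unit, acceptor_unit):
        p1 = initial_placement(donor_unit, acceptor_unit, rng_seed=42)
        p2 = initial_placement(donor_unit, acceptor_unit, rng_seed=42)
        assert np.array_equal(p1.rotation, p2.rotation)
        assert np.array_equal(p1.translation, p2.translation)

    def test_clash_free(self, params):
        ua = prepare_unit(make_toy_unit(FixtureSpec(n_residues=5, seed=1)), params=params)
        ub = prepare_unit(make_toy_unit(FixtureSpec(n_residues=5, seed=2)), params=params)
        ua_c = ua.with_coords(ua.coords() - ua.center())
        for seed in range(10):
            pose = initial_placement(ua_c, ub, rng_seed=seed)
            xb = pose.apply(ub.coords() - ub.center())
            _, _, _, nclash = interface_energy(ua_c, ub, params, coords_b=xb)
            assert nclash == 0

    def test_docking_axes_cover_all_octants(self, donor_unit, acceptor_unit):
        counts = {}
        for seed in range(1000):
            t = initial_placement(donor_unit, acceptor_unit, rng_seed=seed).translation
            key = (t[0] > 0, t[1] > 0, t[2] > 0)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 8
        stat, _ = chisquare(list(counts.values()))
        assert stat < 40  # uniform directions; far below any plausible rejection

    def test_degenerate_unit_rejected(self, params, donor_unit):
        bad = build_unit(
            [("CA", "C", "GLY", 1, (0, 0, 0)), ("CB", "C", "GLY", 1, (0, 0, 0))]
        )
        from swdock.structure import assign_radii

        assign_radii(bad)
        with pytest.raises(ValueError, match="degenerate"):
            initial_placement(donor_unit, bad, rng_seed=0)


class TestProposeMove:
    def test_rotation_only_keeps_center(self):
        rng = np.random.default_rng(1)
        pose = RigidPose(IDENTITY_Q.copy(), np.array([10.0, 0.0, 0.0]))
        for _ in range(200):
            pose = propose_move(pose, (15.0, 0.0), rng)
        assert np.allclose(pose.translation, [10.0, 0.0, 0.0], atol=1e-9)

    def test_translation_only_stays_on_axis(self):
        rng = np.random.default_rng(2)
        t0 = np.array([6.0, 3.0, -2.0])
        pose = RigidPose(IDENTITY_Q.copy(), t0.copy())
        axis = t0 / np.linalg.norm(t0)
        for _ in range(300):
            pose = propose_move(pose, (0.0, 1.5), rng)
            residual = np.linalg.norm(np.cross(pose.translation, axis))
            assert residual < 1e-6

    def test_quaternion_stays_normalized(self):
        rng = np.random.default_rng(3)
        pose = RigidPose(IDENTITY_Q.copy(), np.array([8.0, 0.0, 0.0]))
        for _ in range(10_000):
            pose = propose_move(pose, (25.0, 1.0), rng)
        assert abs(np.linalg.norm(pose.rotation) - 1.0) < 1e-9


class TestMcDock:
    def test_bit_identical_across_runs(self, params, donor_unit, acceptor_unit):
        sched = MCSchedule(n_steps=500)
        a = mc_dock(donor_unit, acceptor_unit, params, sched, rng_seed=9)
        b = mc_dock(donor_unit, acceptor_unit, params, sched, rng_seed=9)
        assert a.binding_energy == b.binding_energy
        assert np.array_equal(a.pose.rotation, b.pose.rotation)
        assert np.array_equal(a.pose.translation, b.pose.translation)

    def test_two_atom_analytic_optimum(self, params, donor_unit, acceptor_unit):
        """The deepest attainable well on the 2-atom system is one h-bond."""
        sched = MCSchedule(n_steps=30_000)
        result = mc_dock(donor_unit, acceptor_unit, params, sched, rng_seed=0)
        assert result.binding_energy == -1.0
        assert result.n_clashes == 0

    def test_no_qualifying_pairs(self, params):
        # bare backbone carbons: no donors, charges or hydropathy types
        fixed = build_unit(
            [("CA", "C", "GLY", 1, (0, 0, 0)), ("CA", "C", "GLY", 2, (3.8, 0, 0))], "f"
        )
        mobile = build_unit(
            [("CA", "C", "GLY", 1, (0, 0, 0)), ("CA", "C", "GLY", 2, (3.8, 0, 0))], "m"
        )
        for u in (fixed, mobile):
            prepare_unit(u, params=params)
        result = mc_dock(fixed, mobile, params, MCSchedule(n_steps=2000), rng_seed=4)
        assert result.binding_energy == 0.0
        assert result.n_clashes == 0

    def test_best_objective_trace_monotone(self, params, donor_unit, acceptor_unit):
        result = mc_dock(
            donor_unit, acceptor_unit, params, MCSchedule(n_steps=3000),
            rng_seed=5, keep_trace=True,
        )
        assert np.all(np.diff(result.objective_trace) <= 0)

    def test_energy_bookkeeping(self, params):
        """Stored U matches a fresh evaluation of the stored pose."""
        ua = prepare_unit(make_toy_unit(FixtureSpec(n_residues=6, seed=31)), params=params)
        ub = prepare_unit(make_toy_unit(FixtureSpec(n_residues=6, seed=32)), params=params)
        result = mc_dock(ua, ub, params, MCSchedule(n_steps=4000), rng_seed=8)
        xb = result.pose.apply(ub.coords() - ub.center())
        U, _, ncont, nclash = interface_energy(result.fixed_unit, ub, params, coords_b=xb)
        assert abs(U - result.binding_energy) < 1e-9
        assert (ncont, nclash) == (result.n_contacts, result.n_clashes)

    def test_acceptance_rate_strictly_between_zero_and_one(self, params, donor_unit, acceptor_unit):
        sched = MCSchedule(n_steps=5000, t_start=1.0, t_end=1.0)  # fixed temperature
        result = mc_dock(donor_unit, acceptor_unit, params, sched, rng_seed=6)
        assert 0.0 < result.acceptance_rate < 1.0


class TestPatchSystem:
    def test_encounter_ensemble_reaches_grid_optimum(self, params):
        """Two 5-atom units with complementary donor/acceptor patches on
        hydrophobic scaffolds: a single run explores one encounter ray, so
        the grid optimum is reached by the best of several encounters."""
        from swdock.fixtures import grid_search_dock

        neutral = {"NTER": 1.0, "CTER": 20.0}
        fixed = prepare_unit(build_unit(
            [
                ("CB", "C", "ALA", 1, (-2.0, 1.0, 0)),
                ("CB", "C", "ALA", 2, (-2.0, -1.0, 0)),
                ("CB", "C", "ALA", 3, (-2.0, 0, 1.5)),
                ("C", "C", "GLY", 4, (0, 0, 0)),
                ("O", "O", "GLY", 4, (0.7, 1.0, 0)),
            ],
            "pf",
        ), params=params, pka_table=neutral)
        mobile = prepare_unit(build_unit(
            [
                ("CB", "C", "ALA", 1, (2.0, 1.0, 0)),
                ("CB", "C", "ALA", 2, (2.0, -1.0, 0)),
                ("CB", "C", "ALA", 3, (2.0, 0, 1.5)),
                ("N", "N", "GLY", 4, (0, 0, 0)),
                ("H", "H", "GLY", 4, (-0.7, 0.7, 0)),
            ],
            "pm",
        ), params=params, pka_table=neutral)
        oracle = grid_search_dock(fixed, mobile, params, resolution=(1.0, 60.0))
        schedule = MCSchedule(n_steps=45_000, n_restarts=3)
        best = min(
            mc_dock(fixed, mobile, params, schedule, rng_seed=s).objective
            for s in range(12)
        )
        assert best <= oracle.objective + 0.05
        # every encounter at least finds the hydrophobic funnel
        assert oracle.n_clashes == 0


class TestEnsembleDock:
    def test_small_ensemble_with_full_trace(self, params):
        ua = prepare_unit(make_toy_unit(FixtureSpec(n_residues=3, seed=41)), params=params)
        ub = prepare_unit(make_toy_unit(FixtureSpec(n_residues=3, seed=42)), params=params)
        ens = ensemble_dock(
            [ua], [ub], params, MCSchedule(n_steps=100),
            target=(10, 20), tol=5.0, window=3, rng_seed=1,
        )
        assert len(ens.members) >= 10
        assert len(ens.convergence_trace) == len(ens.members)
        assert ens.target_range == (10, 20)

    def test_stub_energies_trigger_stopping_rule(self, params, monkeypatch):
        """Normal stub energies converge well before the member cap."""

        def stub_mc(fixed, mobile, p, schedule, rng):
            return DockedComplex(
                fixed_source="stub", mobile_source="stub",
                pose=RigidPose(IDENTITY_Q.copy(), np.array([30.0, 0.0, 0.0])),
                binding_energy=float(rng.normal(-18.0, 1.0)),
                n_contacts=0, n_clashes=0,
            )

        monkeypatch.setattr(docking, "mc_dock", stub_mc)
        ua = prepare_unit(make_toy_unit(FixtureSpec(n_residues=3, seed=1)), params=params)
        ens = ensemble_dock(
            [ua], [ua.copy()], params, MCSchedule(n_steps=1),
            target=(100, 1500), tol=0.02, window=50, rng_seed=3,
        )
        assert ens.converged
        assert 100 <= len(ens.members) < 1500

    def test_member_cap_honored(self, params, monkeypatch):
        def stub_mc(fixed, mobile, p, schedule, rng):
            # wandering energies that never converge
            return DockedComplex(
                fixed_source="s", mobile_source="s",
                pose=RigidPose(IDENTITY_Q.copy(), np.array([30.0, 0.0, 0.0])),
                binding_energy=float(rng.uniform(-100, 0)),
                n_contacts=0, n_clashes=0,
            )

        monkeypatch.setattr(docking, "mc_dock", stub_mc)
        ua = prepare_unit(make_toy_unit(FixtureSpec(n_residues=3, seed=1)), params=params)
        ens = ensemble_dock(
            [ua], [ua.copy()], params, MCSchedule(n_steps=1),
            target=(2, 40), tol=1e-9, window=10, rng_seed=5,
        )
        assert len(ens.members) == 40
        assert not ens.converged

    def test_reproducible_energies(self, params):
        ua = prepare_unit(make_toy_unit(FixtureSpec(n_residues=3, seed=51)), params=params)
        ub = prepare_unit(make_toy_unit(FixtureSpec(n_residues=3, seed=52)), params=params)
        kwargs = dict(
            params=params, schedule=MCSchedule(n_steps=150),
            target=(4, 6), tol=5.0, window=2, rng_seed=11,
        )
        e1 = ensemble_dock([ua], [ub], **kwargs).energies()
        e2 = ensemble_dock([ua], [ub], **kwargs).energies()
        assert np.array_equal(e1, e2)

    def test_argument_validation(self, params, donor_unit):
        with pytest.raises(ValueError):
            ensemble_dock([], [donor_unit], params)
        with pytest.raises(ValueError):
            ensemble_dock([donor_unit], [donor_unit.copy()], params, tol=0.0)
        with pytest.raises(ValueError):
            ensemble_dock([donor_unit], [donor_unit.copy()], params, target=(1, 5))
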