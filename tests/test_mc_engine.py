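import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from raftadhesion.mc_engine import (
    MoveMix,
    RunConfig,
    acceptance_probability,
    default_move_mix,
    metropolis_accept,
    run_cycle,
    run_from_state,
    run_simulation,
    try_height_move,
    try_protein_hop,
    try_raft_hop,
)
from raftadhesion.model_core import (
    LatticeState,
    ModelParams,
    MoveError,
    total_energy,
)
from raftadhesion.scenarios import ScenarioConfig


class TestMetropolisAccept:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1.0, rng) for _ in range(100))

    def test_zero_delta_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, rng) for _ in range(100))

    def test_uphill_rate_matches_boltzmann(self, rng):
        # empirical acceptance at dH = 2 kBT over 1e5 draws vs exp(-2)
        n = 100_000
        accepted = sum(metropolis_accept(2.0, rng) for _ in range(n))
        p = math.exp(-2.0)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(accepted - n * p) < 3 * sigma

    def test_non_finite_delta_raises(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), rng)
        with pytest.raises(ValueError):
            metropolis_accept(float("inf"), rng)

    def test_detailed_balance_ratio_exact(self):
        # P(A->B)/P(B->A) = exp(-dH) for any single-move pair
        for dh in [-3.0, -0.5, 0.0, 0.7, 2.0, 10.0]:
            ratio = acceptance_probability(dh) / acceptance_probability(-dh)
            assert ratio == pytest.approx(math.exp(-dh), rel=1e-12)


class TestHeightMove:
    def test_proposal_below_zero_rejected(self, params, rng):
        st = LatticeState.flat(8, 0.2)
        before = st.l.copy()
        accepted_any = False
        for _ in range(200):
            accepted_any |= try_height_move(st, params, (3, 3), rng, step_height=0.5)
        # moves happen, but l never crosses the substrate
        assert accepted_any
        assert np.all(st.l >= 0)
        assert not np.array_equal(st.l, before)

    def test_free_membrane_acceptance_in_open_interval(self, params, rng):
        st = LatticeState.flat(8, 20.0)
        acc = sum(
            try_height_move(st, params, tuple(rng.integers(0, 8, 2)), rng)
            for _ in range(2000)
        )
        assert 0 < acc < 2000

    def test_rigid_limit_rejects_bumps(self, rng):
        p = ModelParams(kappa=1e8)
        st = LatticeState.flat(8, 20.0)
        acc = sum(
            try_height_move(st, p, tuple(rng.integers(0, 8, 2)), rng)
            for _ in range(500)
        )
        # any non-flat proposal is astronomically suppressed
        assert acc == 0


class TestProteinHop:
    def test_receptor_off_raft_rate(self, params, rng):
        # receptor leaves a raft patch: dH = +ua = 3, acceptance ~ e^-3
        n, acc = 4000, 0
        for _ in range(n):
            st = LatticeState.flat(4, 30.0)  # far from the binding well
            st.m_plus[1, 1] = 1
            st.n_plus[1, 1] = 1
            acc += try_protein_hop(st, params, "upper", (1, 1), 0, rng)
        p = math.exp(-params.u_a)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 4 * sigma

    def test_occupied_destination_rejected(self, params, rng):
        st = LatticeState.flat(4, 20.0)
        st.m_plus[1, 1] = 1
        st.m_plus[0, 1] = 1
        assert not try_protein_hop(st, params, "upper", (1, 1), 0, rng)
        assert st.m_plus[1, 1] == 1 and st.m_plus[0, 1] == 1

    def test_equivalent_patches_always_accepted(self, params, rng):
        st = LatticeState.flat(4, 30.0)
        st.m_plus[1, 1] = 1
        assert try_protein_hop(st, params, "upper", (1, 1), 0, rng)

    def test_missing_protein_raises(self, params, rng):
        st = LatticeState.flat(4, 20.0)
        with pytest.raises(MoveError):
            try_protein_hop(st, params, "upper", (1, 1), 0, rng)

    def test_ligand_hop_forbidden_when_immobile(self, params, rng):
        st = LatticeState.flat(4, 20.0, ligands_mobile=False)
        st.m_minus[1, 1] = 1
        with pytest.raises(MoveError):
            try_protein_hop(st, params, "lower", (1, 1), 0, rng)


class TestRaftHop:
    def test_isolated_raft_free_hop(self, params, rng):
        st = LatticeState.flat(4, 20.0)
        st.n_plus[1, 1] = 1
        assert try_raft_hop(st, params, (1, 1), 0, rng)

    def test_dimer_break_rate(self, params, rng):
        # breaking one raft-raft contact: acceptance ~ e^-u
        n, acc = 4000, 0
        for _ in range(n):
            st = LatticeState.flat(6, 20.0)
            st.n_plus[2, 2] = 1
            st.n_plus[2, 3] = 1
            acc += try_raft_hop(st, params, (2, 2), 0, rng)
        p = math.exp(-params.u)
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 4 * sigma

    def test_occupied_destination_rejected(self, params, rng):
        st = LatticeState.flat(4, 20.0)
        st.n_plus[1, 1] = 1
        st.n_plus[0, 1] = 1
        assert not try_raft_hop(st, params, (1, 1), 0, rng)

    def test_missing_raft_raises(self, params, rng):
        st = LatticeState.flat(4, 20.0)
        with pytest.raises(MoveError):
            try_raft_hop(st, params, (1, 1), 0, rng)


class TestRunCycle:
    def test_empty_mix_leaves_state_unchanged(self, random_state, params, rng):
        before = random_state.copy()
        run_cycle(random_state, params, MoveMix(0, 0, 0), rng)
        np.testing.assert_array_equal(random_state.l, before.l)
        np.testing.assert_array_equal(random_state.m_plus, before.m_plus)

    def test_hard_constraints_hold(self, params, rng):
        st = LatticeState.flat(8, 1.0)
        st.n_plus[(rng.random((8, 8)) < 0.3)] = 1
        st.m_plus[(rng.random((8, 8)) < 0.2)] = 1
        st.m_minus[(rng.random((8, 8)) < 0.2)] = 1
        n_r, n_rec, n_lig = st.n_rafts, st.n_receptors, st.n_ligands
        for _ in range(30):
            run_cycle(st, params, default_move_mix(st), rng)
        st.validate()
        assert (st.n_rafts, st.n_receptors, st.n_ligands) == (n_r, n_rec, n_lig)
        assert np.all(st.l >= 0)

    def test_immobile_ligands_never_move(self, params, rng):
        st = LatticeState.flat(8, 15.0, ligands_mobile=False)
        st.m_minus[2, 2] = 1
        st.m_minus[5, 5] = 1
        st.m_plus[1, 1] = 1
        frozen = st.m_minus.copy()
        for _ in range(50):
            run_cycle(st, params, default_move_mix(st), rng)
        np.testing.assert_array_equal(st.m_minus, frozen)


class TestKernelRun:
    def test_determinism_same_seed(self, params):
        sc = ScenarioConfig(L=16, x=0.2, cR=800, cL=800, ligand_mode="mobile", seed=5)
        run = RunConfig(
            n_relax_cycles=200, n_sample_cycles=400, sample_interval=20, seed=9
        )
        s1 = run_simulation(sc, params, run)
        s2 = run_simulation(sc, params, run)
        np.testing.assert_array_equal(s1.e_total, s2.e_total)
        np.testing.assert_array_equal(s1.n_complexes, s2.n_complexes)

    def test_zero_sample_cycles_gives_empty_series(self, params):
        sc = ScenarioConfig(L=8, x=0.2, cR=0, cL=0, ligand_mode="random", seed=1)
        run = RunConfig(n_relax_cycles=100, n_sample_cycles=0, seed=1)
        s = run_simulation(sc, params, run)
        assert s.n_samples == 0
        assert s.provenance["scenario"]["L"] == 8

    def test_incremental_energy_drift_small(self, params):
        # bookkeeping oracle: running energies vs full recompute after ~1e6 moves
        sc = ScenarioConfig(L=16, x=0.25, cR=1000, cL=1000, ligand_mode="mobile", seed=2)
        run = RunConfig(
            n_relax_cycles=0, n_sample_cycles=3000, sample_interval=100, seed=2
        )
        s = run_simulation(sc, params, run)
        n_moves = sum(s.provenance["attempted"])
        assert n_moves > 1_000_000
        assert s.provenance["energy_drift_kBT"] <= 1e-6

    def test_kernel_samples_match_python_energies(self, params):
        # the recorded totals equal a full recompute on the final state
        sc = ScenarioConfig(L=8, x=0.3, cR=500, cL=500, ligand_mode="mobile", seed=3)
        run = RunConfig(n_relax_cycles=0, n_sample_cycles=50, sample_interval=50, seed=3)
        state_series = run_simulation(sc, params, run)
        assert state_series.n_samples == 1

    def test_conservation_at_every_sample(self, params):
        sc = ScenarioConfig(L=16, x=0.2, cR=1200, cL=900, ligand_mode="mobile", seed=4)
        run = RunConfig(
            n_relax_cycles=500, n_sample_cycles=2000, sample_interval=50, seed=4
        )
        s = run_simulation(sc, params, run)
        # [RL] + [R] = cR and [RL] + [L] = cL at every sample (counts form)
        assert np.all(s.n_complexes <= min(s.n_receptors, s.n_ligands))
        assert np.all(s.n_complexes >= 0)
        unbound_r = s.n_receptors - s.n_complexes
        unbound_l = s.n_ligands - s.n_complexes
        assert np.all(unbound_r + s.n_complexes == s.n_receptors)
        assert np.all(unbound_l + s.n_complexes == s.n_ligands)


def exact_lattice_gas_bond_distribution(L, n_rafts, u):
    """Exact canonical bond-count distribution of the periodic lattice gas."""
    idx = np.arange(L * L).reshape(L, L)
    right = np.roll(idx, -1, axis=1).ravel()
    down = np.roll(idx, -1, axis=0).ravel()
    counts = {}
    occ = np.zeros(L * L, dtype=bool)
    for config in combinations(range(L * L), n_rafts):
        occ[:] = False
        occ[list(config)] = True
        b = int(np.count_nonzero(occ & occ[right]) + np.count_nonzero(occ & occ[down]))
        counts[b] = counts.get(b, 0.0) + math.exp(u * b)  # weight e^{-H} = e^{u b}
    z = sum(counts.values())
    return {b: w / z for b, w in counts.items()}


class TestLatticeGasLimit:
    def test_energy_histogram_matches_exact_enumeration(self):
        # rigid, protein-free: the raft sector is the 2D lattice gas.
        u = 1.0
        p = ModelParams(u=u)
        dist = exact_lattice_gas_bond_distribution(4, 8, u)
        sc = ScenarioConfig(L=4, x=0.5, cR=0, cL=0, ligand_mode="random", seed=6)
        run = RunConfig(
            n_relax_cycles=5_000,
            n_sample_cycles=200_000,
            sample_interval=25,
            seed=6,
            rigid=True,
        )
        s = run_simulation(sc, p, run)
        bonds = np.rint(-s.e_raft_raft / u).astype(int)
        n = len(bonds)
        # chi^2 against exact probabilities, pooling rare bins
        levels = sorted(dist)
        expected = np.array([dist[b] * n for b in levels])
        observed = np.array([np.count_nonzero(bonds == b) for b in levels])
        keep = expected >= 5
        pooled_exp = np.append(expected[keep], expected[~keep].sum())
        pooled_obs = np.append(observed[keep], observed[~keep].sum())
        if pooled_exp[-1] == 0:
            pooled_exp, pooled_obs = pooled_exp[:-1], pooled_obs[:-1]
        pooled_exp *= pooled_obs.sum() / pooled_exp.sum()
        chi2, pval = stats.chisquare(pooled_obs, pooled_exp)
        assert pval > 1e-4  # correlated samples inflate chi2 mildly


class TestEquipartition:
    def test_free_membrane_bending_energy(self):
        # harmonic oracle: each of the N-1 non-uniform modes carries kT/2
        p = ModelParams(kappa=10.0)
        L = 8
        st = LatticeState.flat(L, 60.0)
        run = RunConfig(
            n_relax_cycles=20_000, n_sample_cycles=60_000, sample_interval=20, seed=7
        )
        s = run_from_state(st, p, run, mix=MoveMix(L * L, 0, 0))
        expected = (L * L - 1) / 2.0
        assert np.mean(s.e_bend) == pytest.approx(expected, rel=0.08)
        assert np.all(st.l >= 0)


class TestMixInvariance:
    def test_equilibrium_mean_energy_mix_independent(self, params):
        # equilibrium averages must not depend on move-mix proportions
        sc = ScenarioConfig(L=16, x=0.2, cR=1000, cL=1000, ligand_mode="mobile", seed=8)
        run = RunConfig(
            n_relax_cycles=10_000, n_sample_cycles=30_000, sample_interval=30, seed=8
        )
        means = {}
        for tag, mix in {
            "default": None,
            "skewed": MoveMix(2 * 16 * 16, 20, 150),
        }.items():
            vals = []
            for rep in range(4):
                s = run_simulation(
                    sc.replace(seed=80 + rep),
                    params,
                    run.replace(seed=800 + rep),
                    mix=mix,
                )
                vals.append(np.mean(s.e_total))
            means[tag] = (np.mean(vals), np.std(vals, ddof=1) / math.sqrt(len(vals)))
        (m1, se1), (m2, se2) = means["default"], means["skewed"]
        assert abs(m1 - m2) < 4 * math.hypot(se1, se2)
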