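"""Fast release-gate checks against independent oracles.

Each check recomputes a quantity with the package and compares it with
an analytic value or an exact small-lattice enumeration.  Kept cheap
enough (< ~1 min) to run on every checkout via ``raftadhesion validate``.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .mc_engine import RunConfig, acceptance_probability, run_simulation
from .model_core import ModelParams
from .observables import heat_capacity, raft_receptor_concentration
from .phase_analysis import U0_STAR_LATTICE_GAS
from .mean_field import MFConfig, transition_u
from .scenarios import ScenarioConfig


def exact_lattice_gas_cv(L: int, n_rafts: int, u: float) -> float:
    """CV per site of the L x L periodic lattice gas with ``n_rafts``
    particles at contact energy u, by exact canonical enumeration."""
    n_sites = L * L
    idx = np.arange(n_sites).reshape(L, L)
    right = np.roll(idx, -1, axis=1).ravel()
    down = np.roll(idx, -1, axis=0).ravel()
    energies = []
    occ = np.zeros(n_sites, dtype=bool)
    for config in combinations(range(n_sites), n_rafts):
        occ[:] = False
        occ[list(config)] = True
        bonds = int(np.count_nonzero(occ & occ[right]) + np.count_nonzero(occ & occ[down]))
        energies.append(-u * bonds)
    energies = np.array(energies)
    w = np.exp(-(energies - energies.min()))
    z = w.sum()
    e1 = (w * energies).sum() / z
    e2 = (w * energies**2).sum() / z
    return (e2 - e1 * e1) / n_sites


def run_validation(seed: int = 0, accept_fn=acceptance_probability) -> dict:
    checks = []

    def add(name, measured, expected, tol):
        checks.append(
            {
                "name": name,
                "measured": float(measured),
                "expected": float(expected),
                "tol": float(tol),
                "passed": bool(abs(measured - expected) <= tol),
            }
        )

    add(
        "lattice-gas critical coupling (analytic)",
        U0_STAR_LATTICE_GAS,
        2.0 * math.log(1.0 + math.sqrt(2.0)),
        1e-12,
    )
    add(
        "mean-field critical contact energy at x=1/2, cR=0",
        transition_u(MFConfig(x=0.5, cR=0.0)),
        1.0,
        1e-6,
    )
    add(
        "detailed-balance ratio at dH=2 kBT",
        accept_fn(2.0) / accept_fn(-2.0),
        math.exp(-2.0),
        1e-12,
    )

    # 4x4 half-filled lattice gas: MC vs exact canonical enumeration
    u = 1.0
    cv_exact = exact_lattice_gas_cv(4, 8, u)
    scenario = ScenarioConfig(L=4, x=0.5, cR=0.0, cL=0.0, ligand_mode="random", seed=seed)
    run = RunConfig(
        n_relax_cycles=20_000, n_sample_cycles=200_000, sample_interval=20,
        seed=seed, rigid=True,
    )
    series = run_simulation(scenario, ModelParams(u=u), run)
    add("4x4 lattice-gas CV vs exact enumeration", heat_capacity(series), cv_exact, 0.05)

    # dilute raft partitioning of receptors: concentration ratio e^{ua}
    p = ModelParams(u_a=3.0, u=0.0)
    scenario = ScenarioConfig(
        L=16, x=0.2, cR=80.0, cL=0.0, ligand_mode="random", seed=seed + 1
    )
    run = RunConfig(
        n_relax_cycles=20_000, n_sample_cycles=200_000, sample_interval=20,
        seed=seed + 1, rigid=True,
    )
    series = run_simulation(scenario, p, run)
    x_real = series.provenance["scenario"]["x"]
    c_in = raft_receptor_concentration(series, x_real)
    n_rafts = round(x_real * 16 * 16)
    x_eff = n_rafts / 256
    expected_in = (
        series.n_receptors
        / series.area_um2
        * math.exp(p.u_a)
        / (x_eff * math.exp(p.u_a) + 1 - x_eff)
    )
    add("dilute receptor raft enrichment", c_in, expected_in, 0.12 * expected_in)

    return {
        "seed": seed,
        "checks": checks,
        "all_passed": all(c["passed"] for c in checks),
    }
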