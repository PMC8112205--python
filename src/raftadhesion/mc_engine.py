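"""Metropolis Monte Carlo engine.

Three trial-move types: vertical membrane height shifts, lateral protein
hops (receptors; ligands only in the mobile-ligand scenario), and raft
patch hops that leave receptors behind.  A slow pure-Python path
(`try_*`, `run_cycle`) backs the unit tests and oracles; `run_simulation`
drives the compiled kernel for production runs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _kernels
from .model_core import (
    DIRS,
    HeightMove,
    LatticeState,
    ModelParams,
    MoveError,
    ProteinHop,
    RaftHop,
    apply_move,
    local_delta_energy,
    total_energy,
)
from .observables import SampleSeries
from .scenarios import ScenarioConfig, build_initial_state


@dataclass(frozen=True)
class MoveMix:
    """Attempted moves of each type per MC cycle."""

    n_height: int
    n_protein: int
    n_raft: int

    def __post_init__(self):
        if min(self.n_height, self.n_protein, self.n_raft) < 0:
            raise ValueError("move counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_height + self.n_protein + self.n_raft


@dataclass(frozen=True)
class RunConfig:
    """Cycle counts, sampling cadence and seeding of one MC run.

    ``rigid=True`` disables height moves (planar rigid membranes).
    The effective RNG seed is ``seed + replicate_id``.

    The ``*_move_boost`` factors scale the default number of attempts of
    each type per cycle.  Equilibrium averages are independent of
    the move mix (tested), so boosting the slow conserved raft sector
    shortens correlation times without biasing observables; only the
    cycle-to-time mapping loses meaning.
    """

    n_relax_cycles: int = 100_000
    n_sample_cycles: int = 100_000
    sample_interval: int = 1000
    step_height: float = 0.5
    seed: int = 0
    replicate_id: int = 0
    rigid: bool = False
    height_move_boost: float = 1.0
    protein_move_boost: float = 1.0
    raft_move_boost: float = 1.0

    def __post_init__(self):
        if self.n_relax_cycles < 0 or self.n_sample_cycles < 0:
            raise ValueError("cycle counts must be >= 0")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.step_height <= 0:
            raise ValueError("step_height must be > 0")

    @property
    def effective_seed(self) -> int:
        return (self.seed + self.replicate_id) % 2**32

    def replace(self, **kw) -> "RunConfig":
        d = asdict(self)
        d.update(kw)
        return RunConfig(**d)


def acceptance_probability(delta_h: float, kT: float = 1.0) -> float:
    """Metropolis acceptance probability ``min(1, exp(-dH/kT))``."""
    if not math.isfinite(delta_h):
        raise ValueError(f"non-finite energy change {delta_h}")
    if delta_h <= 0.0:
        return 1.0
    return math.exp(-delta_h / kT)


def metropolis_accept(delta_h: float, rng: np.random.Generator, kT: float = 1.0) -> bool:
    """Accept downhill moves always, uphill with ``exp(-dH/kT)``."""
    p = acceptance_probability(delta_h, kT)
    return p >= 1.0 or rng.random() < p


# ---------------------------------------------------------------------------
# pure-Python move attempts (reference path, used by tests and oracles)


def try_height_move(
    state: LatticeState,
    p: ModelParams,
    site: tuple,
    rng: np.random.Generator,
    step_height: float = 0.5,
) -> bool:
    dl = rng.uniform(-step_height, step_height)
    if state.l[site] + dl < 0.0:
        return False  # hard wall: membrane cannot cross the substrate
    move = HeightMove(site, dl)
    if metropolis_accept(local_delta_energy(state, p, move), rng, p.kT):
        apply_move(state, move)
        return True
    return False


def try_protein_hop(
    state: LatticeState,
    p: ModelParams,
    surface: str,
    site: tuple,
    direction: int,
    rng: np.random.Generator,
) -> bool:
    if surface == "lower" and not state.ligands_mobile:
        raise MoveError("ligand hops are disabled in immobile-ligand scenarios")
    occ = state.m_plus if surface == "upper" else state.m_minus
    if not occ[site]:
        raise MoveError(f"no protein at {surface} site {site}")
    di, dj = DIRS[direction]
    dest = ((site[0] + di) % state.L, (site[1] + dj) % state.L)
    if occ[dest]:
        return False  # single occupancy per surface
    move = ProteinHop(surface, site, direction)
    if metropolis_accept(local_delta_energy(state, p, move), rng, p.kT):
        apply_move(state, move)
        return True
    return False


def try_raft_hop(
    state: LatticeState,
    p: ModelParams,
    site: tuple,
    direction: int,
    rng: np.random.Generator,
) -> bool:
    if not state.n_plus[site]:
        raise MoveError(f"no raft at site {site}")
    di, dj = DIRS[direction]
    dest = ((site[0] + di) % state.L, (site[1] + dj) % state.L)
    if state.n_plus[dest]:
        return False  # raft number conserved
    move = RaftHop(site, direction)
    if metropolis_accept(local_delta_energy(state, p, move), rng, p.kT):
        apply_move(state, move)
        return True
    return False


def default_move_mix(state: LatticeState, rigid: bool = False) -> MoveMix:
    """One attempt per membrane patch, mobile protein and raft per cycle."""
    n_mobile = state.n_receptors + (state.n_ligands if state.ligands_mobile else 0)
    return MoveMix(
        n_height=0 if rigid else state.L**2,
        n_protein=n_mobile,
        n_raft=state.n_rafts,
    )


def run_cycle(
    state: LatticeState,
    p: ModelParams,
    mix: MoveMix,
    rng: np.random.Generator,
    step_height: float = 0.5,
) -> LatticeState:
    """One MC cycle on the Python path: ``mix`` attempts in randomized
    interleaving.  Slow; intended for small lattices and tests."""
    total = mix.total
    for _ in range(total):
        r = rng.random() * total
        if r < mix.n_height:
            site = tuple(rng.integers(0, state.L, size=2))
            try_height_move(state, p, site, rng, step_height)
        elif r < mix.n_height + mix.n_protein:
            rec = np.argwhere(state.m_plus)
            ligs = (
                np.argwhere(state.m_minus)
                if state.ligands_mobile
                else np.empty((0, 2), dtype=int)
            )
            n = len(rec) + len(ligs)
            if n == 0:
                continue
            k = int(rng.integers(n))
            if k < len(rec):
                try_protein_hop(state, p, "upper", tuple(rec[k]), int(rng.integers(4)), rng)
            else:
                try_protein_hop(
                    state, p, "lower", tuple(ligs[k - len(rec)]), int(rng.integers(4)), rng
                )
        else:
            rafts = np.argwhere(state.n_plus)
            if len(rafts) == 0:
                continue
            k = int(rng.integers(len(rafts)))
            try_raft_hop(state, p, tuple(rafts[k]), int(rng.integers(4)), rng)
    return state


# ---------------------------------------------------------------------------
# compiled production path


def run_from_state(
    state: LatticeState,
    p: ModelParams,
    run: RunConfig,
    mix: MoveMix | None = None,
    provenance: dict | None = None,
) -> SampleSeries:
    """Relax + sample the given state with the compiled kernel.

    Mutates ``state`` in place and returns the recorded series.  The
    running incremental energies are checked against a full recompute;
    the absolute drift is stored in the provenance.
    """
    if mix is None:
        base = default_move_mix(state, rigid=run.rigid)
        mix = MoveMix(
            n_height=int(round(base.n_height * run.height_move_boost)),
            n_protein=int(round(base.n_protein * run.protein_move_boost)),
            n_raft=int(round(base.n_raft * run.raft_move_boost)),
        )
    L = state.L
    nbr = _kernels.neighbor_table(L)
    l = state.l.ravel()
    mp = state.m_plus.ravel()
    mm = state.m_minus.ravel()
    npr = state.n_plus.ravel()

    def _lists(occ):
        sites = np.flatnonzero(occ).astype(np.int64)
        pos = np.full(L * L, -1, dtype=np.int64)
        pos[sites] = np.arange(len(sites))
        return sites, pos

    rec_list, rec_pos = _lists(mp)
    lig_list, lig_pos = _lists(mm if state.ligands_mobile else np.zeros_like(mm))
    raft_list, raft_pos = _lists(npr)

    n_samples = run.n_sample_cycles // run.sample_interval
    samples = np.zeros((n_samples, _kernels.N_SAMPLE_COLS))
    e_bend, e_bind, e_rp, e_rr, s_idx, acc, att = _kernels.run_mc(
        l, mp, mm, npr, nbr,
        rec_list, lig_list, raft_list, rec_pos, lig_pos, raft_pos,
        p.kappa, p.a, p.u_b, p.l_b, p.l_c, p.u_a, p.u,
        mix.n_height, mix.n_protein, mix.n_raft,
        run.step_height,
        run.n_relax_cycles, run.n_sample_cycles, run.sample_interval,
        run.effective_seed,
        samples,
    )
    state.l = l.reshape(L, L)
    state.m_plus = mp.reshape(L, L)
    state.m_minus = mm.reshape(L, L)
    state.n_plus = npr.reshape(L, L)

    ref = total_energy(state, p)
    drift = max(
        abs(e_bend - ref.e_bend),
        abs(e_bind - ref.e_bind),
        abs(e_rp - ref.e_raft_receptor),
        abs(e_rr - ref.e_raft_raft),
    )
    prov = dict(provenance or {})
    prov.update(
        {
            "run": asdict(run),
            "mix": asdict(mix),
            "params": asdict(p),
            "energy_drift_kBT": drift,
            "accepted": acc.tolist(),
            "attempted": att.tolist(),
        }
    )
    samples = samples[:s_idx]
    return SampleSeries(
        cycle=samples[:, 0].astype(np.int64),
        e_total=samples[:, 1],
        e_bend=samples[:, 2],
        e_bind=samples[:, 3],
        e_raft_receptor=samples[:, 4],
        e_raft_raft=samples[:, 5],
        n_complexes=samples[:, 6].astype(np.int64),
        n_receptors_on_raft=samples[:, 7].astype(np.int64),
        n_patches_in_well=samples[:, 8].astype(np.int64),
        n_receptors=int(mp.sum()),
        n_ligands=int(mm.sum()),
        N=L * L,
        area_um2=(L * p.a) ** 2 / 1e6,
        provenance=prov,
    )


def run_simulation(
    scenario: ScenarioConfig,
    p: ModelParams,
    run: RunConfig,
    mix: MoveMix | None = None,
) -> SampleSeries:
    """Build the scenario's initial state, relax, then sample."""
    state = build_initial_state(scenario, p)
    return run_from_state(
        state, p, run, mix=mix, provenance={"scenario": scenario.to_dict()}
    )
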