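"""Synthetic initial configurations for every studied adhesion system.

Generates lattice states for the scenarios: mobile ligands anchored to a
supported bilayer, and immobile ligands placed uniformly, randomly, or
as rasterized circular clusters on the substrate.  Area concentrations
(per µm^2) are converted to entity counts via the patch area ``a**2``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np

from .model_core import LatticeState, ModelParams

LIGAND_MODES = ("mobile", "uniform", "random", "clustered")


class ConfigurationError(ValueError):
    """Inconsistent or unsatisfiable scenario configuration."""


class PlacementError(RuntimeError):
    """Random placement failed within the retry budget."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One studied adhesion system.

    ``x`` is the raft area fraction, ``cR``/``cL`` receptor and ligand
    area concentrations in µm^-2, ``ligand_mode`` one of
    ``mobile | uniform | random | clustered``.  ``dc`` (nm) and
    ``n_clusters`` only apply to the clustered mode; ``n_clusters=None``
    picks the count whose total ligand number best matches ``cL``.
    """

    L: int = 60
    x: float = 0.2
    cR: float = 1000.0
    cL: float = 1000.0
    ligand_mode: str = "mobile"
    dc: float = 50.0
    n_clusters: int | None = None
    seed: int = 0
    raft_init: str = "random"

    def __post_init__(self):
        if self.L < 2:
            raise ConfigurationError("L must be >= 2")
        if self.raft_init not in ("random", "droplet"):
            raise ConfigurationError("raft_init must be 'random' or 'droplet'")
        if not 0.0 <= self.x <= 1.0:
            raise ConfigurationError("x must lie in [0, 1]")
        if self.cR < 0 or self.cL < 0:
            raise ConfigurationError("concentrations must be >= 0")
        if self.ligand_mode not in LIGAND_MODES:
            raise ConfigurationError(
                f"ligand_mode must be one of {LIGAND_MODES}, got {self.ligand_mode!r}"
            )

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def concentration_to_count(c: float, L: int, a: float) -> int:
    """Number of entities realizing concentration ``c`` (µm^-2) on an
    ``L x L`` lattice of patch size ``a`` (nm)."""
    if c < 0:
        raise ConfigurationError("concentration must be >= 0")
    area_um2 = (L * a) ** 2 / 1e6
    n = int(round(c * area_um2))
    if n > L * L:
        raise ConfigurationError(f"count {n} exceeds {L * L} available patches")
    return n


def count_to_concentration(n: int, L: int, a: float) -> float:
    """Realized concentration (µm^-2) of ``n`` entities."""
    return n / ((L * a) ** 2 / 1e6)


def _random_distinct_sites(L: int, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(L * L, size=n, replace=False)


def place_rafts_random(state: LatticeState, x: float, rng: np.random.Generator) -> LatticeState:
    """Mark ``round(x * L**2)`` distinct random membrane patches as raft."""
    L = state.L
    n = int(round(x * L * L))
    if n > 0:
        flat = state.n_plus.ravel()
        flat[_random_distinct_sites(L, n, rng)] = 1
    return state

def place_receptors_random(
    state: LatticeState, cR: float, rng: np.random.Generator, a: float = 10.0
) -> LatticeState:
    """Receptors on distinct random membrane patches, independent of rafts."""
    n = concentration_to_count(cR, state.L, a)
    if n > 0:
        flat = state.m_plus.ravel()
        flat[_random_distinct_sites(state.L, n, rng)] = 1
    return state


def rasterize_disk(dc: float, a: float) -> list[tuple[int, int]]:
    """Lattice offsets (di, dj) with ``di**2 + dj**2 <= (dc / 2a)**2``."""
    if dc < a:
        raise ConfigurationError("cluster diameter dc must be >= a")
    r = dc / (2.0 * a)
    rad = int(math.floor(r))
    r2 = r * r
    return [
        (di, dj)
        for di in range(-rad, rad + 1)
        for dj in range(-rad, rad + 1)
        if di * di + dj * dj <= r2
    ]


def default_n_clusters(cfg: ScenarioConfig, a: float = 10.0) -> int:
    """Cluster count whose total ligand number best matches ``cL``."""
    target = concentration_to_count(cfg.cL, cfg.L, a)
    per_disk = len(rasterize_disk(cfg.dc, a))
    return max(1, int(round(target / per_disk)))


def _place_uniform_grid(state: LatticeState, n: int) -> None:
    """Ligands on a maximally even grid; exact when n = s**2 with s | L."""
    L = state.L
    s = int(round(math.sqrt(n)))
    if s * s == n and L % s == 0:
        step = L // s
        state.m_minus[::step, ::step] = 1
        return
    s = int(math.ceil(math.sqrt(n)))
    placed = 0
    for i in range(s):
        for j in range(s):
            if placed >= n:
                return
            r, c = (i * L) // s, (j * L) // s
            if not state.m_minus[r, c]:
                state.m_minus[r, c] = 1
                placed += 1
    if placed < n:
        raise PlacementError(f"could not place {n} ligands on an even grid")


def _place_clusters(
    state: LatticeState, cfg: ScenarioConfig, rng: np.random.Generator, a: float
) -> None:
    offsets = rasterize_disk(cfg.dc, a)
    n_clusters = cfg.n_clusters if cfg.n_clusters is not None else default_n_clusters(cfg, a)
    L = state.L
    min_d = cfg.dc / a  # center separation in patches
    for _attempt in range(100_000):
        centers = rng.integers(0, L, size=(n_clusters, 2))
        ok = True
        for i in range(n_clusters):
            for j in range(i + 1, n_clusters):
                d = centers[i] - centers[j]
                d = (d + L // 2) % L - L // 2  # periodic minimum image
                if math.hypot(d[0], d[1]) < min_d:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        trial = np.zeros((L, L), dtype=np.uint8)
        for ci, cj in centers:
            for di, dj in offsets:
                trial[(ci + di) % L, (cj + dj) % L] = 1
        if int(trial.sum()) == n_clusters * len(offsets):  # no shared sites
            state.m_minus[:, :] = trial
            return
    raise PlacementError(
        f"could not place {n_clusters} non-overlapping clusters of dc={cfg.dc} nm"
    )


def place_ligands(
    state: LatticeState, cfg: ScenarioConfig, rng: np.random.Generator, a: float = 10.0
) -> LatticeState:
    """Place ligands according to ``cfg.ligand_mode`` and set mobility."""
    n = concentration_to_count(cfg.cL, cfg.L, a)
    mode = cfg.ligand_mode
    state.ligands_mobile = mode == "mobile"
    if mode in ("mobile", "random"):
        if n > 0:
            flat = state.m_minus.ravel()
            flat[_random_distinct_sites(cfg.L, n, rng)] = 1
    elif mode == "uniform":
        if n > 0:
            _place_uniform_grid(state, n)
    elif mode == "clustered":
        _place_clusters(state, cfg, rng, a)
    return state


def place_rafts_droplet(
    state: LatticeState, x: float, rng: np.random.Generator
) -> LatticeState:
    """Rafts pre-coalesced into one compact block at a random position.

    Alternative initialization for short equilibration budgets near the
    phase boundary: an oversized droplet dissolves quickly below the
    transition, whereas coarsening from a random distribution above it
    is slow.  Equilibrium observables are initialization-independent.
    """
    L = state.L
    n = int(round(x * L * L))
    if n == 0:
        return state
    side = int(math.ceil(math.sqrt(n)))
    i0, j0 = rng.integers(0, L, size=2)
    placed = 0
    for i in range(side):
        for j in range(side):
            if placed >= n:
                return state
            state.n_plus[(i0 + i) % L, (j0 + j) % L] = 1
            placed += 1
    return state


def build_initial_state(cfg: ScenarioConfig, params: ModelParams) -> LatticeState:
    """Initial lattice state for a scenario: separation field flat at the
    complex length, rafts random (or one droplet), receptors random,
    ligands per mode."""
    rng = np.random.default_rng(cfg.seed)
    state = LatticeState.flat(cfg.L, params.l_c)
    if cfg.raft_init == "droplet":
        place_rafts_droplet(state, cfg.x, rng)
    else:
        place_rafts_random(state, cfg.x, rng)
    place_receptors_random(state, cfg.cR, rng, params.a)
    place_ligands(state, cfg, rng, params.a)
    return state


def describe(cfg: ScenarioConfig, params: ModelParams) -> dict:
    """Realized counts and concentrations for logging / provenance."""
    state = build_initial_state(cfg, params)
    a = params.a
    return {
        "L": cfg.L,
        "area_um2": (cfg.L * a) ** 2 / 1e6,
        "n_rafts": state.n_rafts,
        "realized_x": state.n_rafts / cfg.L**2,
        "n_receptors": state.n_receptors,
        "realized_cR": count_to_concentration(state.n_receptors, cfg.L, a),
        "n_ligands": state.n_ligands,
        "realized_cL": count_to_concentration(state.n_ligands, cfg.L, a),
        "ligand_mode": cfg.ligand_mode,
        "ligands_mobile": state.ligands_mobile,
    }
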