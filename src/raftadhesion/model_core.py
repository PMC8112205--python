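"""Domain types and energy terms of the adhesion lattice model.

The adhesion zone is an ``L x L`` periodic square lattice of patches of
linear size ``a`` (nm).  Each membrane patch ``i`` carries

* a local separation ``l_i >= 0`` (nm) between the membrane and the
  apposing surface,
* a receptor occupancy ``m+_i`` in {0, 1} on the upper (cell) membrane,
* a raft occupancy ``n+_i`` in {0, 1} on the upper membrane,

and each apposed substrate patch carries a ligand occupancy ``m-_i``.

Four energy terms add up to the total configurational energy, all in
units of ``kBT``:

==================  =====================================================
bending             ``kappa / (2 a^2)  sum_i (lap l)_i^2``
binding             ``-u_b sum_i m+_i m-_i [ |l_i - l_c| < l_b/2 ]``
raft-receptor       ``-u_a sum_i n+_i m+_i``
raft-raft           ``-u sum_<ij> n+_i n+_j``  (each bond counted once)
==================  =====================================================

``lap`` is the 5-point discrete Laplacian with periodic boundaries.
A receptor-ligand complex exists at patch ``i`` iff receptor and ligand
are apposed there and the separation lies strictly inside the square
binding well, ``l_c - l_b/2 < l_i < l_c + l_b/2``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

#: neighbor offsets: up, down, left, right (row, col)
DIRS = ((-1, 0), (1, 0), (0, -1), (0, 1))


class MoveError(ValueError):
    """A move descriptor violates its contract (engine bug, not physics)."""


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the Hamiltonian, in kBT / nm internal units.

    Parameters
    ----------
    kappa : float
        Membrane bending rigidity (kBT).
    a : float
        Lattice constant (nm); one patch covers ``a**2`` nm^2.
    u_b : float
        Depth of the square-well receptor-ligand binding potential (kBT).
    l_b : float
        Width of the binding well (nm); must be smaller than ``l_c``.
    l_c : float
        Receptor-ligand complex length, i.e. the well center (nm).
    u_a : float
        Energy gain for a receptor residing on a raft patch (kBT).
    u : float
        Contact energy per nearest-neighbor raft pair (kBT).
    kT : float
        Thermal energy; fixed to 1 in internal units.
    """

    kappa: float = 10.0
    a: float = 10.0
    u_b: float = 6.0
    l_b: float = 1.0
    l_c: float = 15.0
    u_a: float = 3.0
    u: float = 1.0
    kT: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kappa", "a", "u_b", "l_b", "l_c", "u_a", "kT"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ModelParams.{name} must be > 0")
        if self.u < 0:
            raise ValueError("ModelParams.u must be >= 0")
        if not self.l_b < self.l_c:
            raise ValueError("ModelParams.l_b must be < l_c")

    def replace(self, **kwargs) -> "ModelParams":
        d = asdict(self)
        d.update(kwargs)
        return ModelParams(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls(**json.loads(s))


@dataclass
class LatticeState:
    """Configuration of the adhesion zone.

    Arrays are ``(L, L)``: ``l`` float64 separations (nm) and three
    binary uint8 occupancy fields.  ``ligands_mobile`` records whether
    the substrate ligands may hop (supported-bilayer scenario) or are
    immobilized.
    """

    l: np.ndarray
    m_plus: np.ndarray
    m_minus: np.ndarray
    n_plus: np.ndarray
    ligands_mobile: bool = True

    @property
    def L(self) -> int:
        return int(self.l.shape[0])

    @property
    def n_receptors(self) -> int:
        return int(self.m_plus.sum())

    @property
    def n_ligands(self) -> int:
        return int(self.m_minus.sum())

    @property
    def n_rafts(self) -> int:
        return int(self.n_plus.sum())

    @classmethod
    def flat(cls, L: int, l0: float, ligands_mobile: bool = True) -> "LatticeState":
        """Empty lattice with a uniform separation field ``l0``."""
        return cls(
            l=np.full((L, L), float(l0)),
            m_plus=np.zeros((L, L), dtype=np.uint8),
            m_minus=np.zeros((L, L), dtype=np.uint8),
            n_plus=np.zeros((L, L), dtype=np.uint8),
            ligands_mobile=ligands_mobile,
        )

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.l.copy(),
            self.m_plus.copy(),
            self.m_minus.copy(),
            self.n_plus.copy(),
            self.ligands_mobile,
        )

    def translated(self, di: int, dj: int) -> "LatticeState":
        """The same configuration shifted by a lattice vector (periodic)."""
        sh = (di, dj)
        return LatticeState(
            np.roll(self.l, sh, axis=(0, 1)),
            np.roll(self.m_plus, sh, axis=(0, 1)),
            np.roll(self.m_minus, sh, axis=(0, 1)),
            np.roll(self.n_plus, sh, axis=(0, 1)),
            self.ligands_mobile,
        )

    def validate(self) -> None:
        L = self.L
        for name in ("l", "m_plus", "m_minus", "n_plus"):
            arr = getattr(self, name)
            if arr.shape != (L, L):
                raise ValueError(f"LatticeState.{name} must be ({L}, {L})")
        if np.any(self.l < 0):
            raise ValueError("separation field has l < 0")
        for name in ("m_plus", "m_minus", "n_plus"):
            arr = getattr(self, name)
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"LatticeState.{name} must be binary")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies (kBT); ``e_total`` is their exact sum."""

    e_bend: float
    e_bind: float
    e_raft_receptor: float
    e_raft_raft: float

    @property
    def e_total(self) -> float:
        return self.e_bend + self.e_bind + self.e_raft_receptor + self.e_raft_raft


# ---------------------------------------------------------------------------
# move descriptors


@dataclass(frozen=True)
class HeightMove:
    """Shift ``l`` at ``site`` by ``dl`` nm."""

    site: tuple
    dl: float


@dataclass(frozen=True)
class ProteinHop:
    """Hop the protein at ``site`` on ``surface`` ('upper' receptors,
    'lower' ligands) to neighbor ``direction`` (index into DIRS)."""

    surface: str
    site: tuple
    direction: int


@dataclass(frozen=True)
class RaftHop:
    """Hop the raft patch at ``site`` to neighbor ``direction``; any
    receptor at the source stays behind."""

    site: tuple
    direction: int


# ---------------------------------------------------------------------------
# full-lattice energies


def laplacian_field(l: np.ndarray) -> np.ndarray:
    """5-point periodic discrete Laplacian of the separation field (nm)."""
    return (
        np.roll(l, 1, axis=0)
        + np.roll(l, -1, axis=0)
        + np.roll(l, 1, axis=1)
        + np.roll(l, -1, axis=1)
        - 4.0 * l
    )


def discrete_laplacian(state: LatticeState, site: tuple) -> float:
    """Discrete Laplacian of the separation field at one site (nm)."""
    L = state.L
    i, j = site
    if not (0 <= i < L and 0 <= j < L):
        raise MoveError(f"site {site} outside {L}x{L} lattice")
    l = state.l
    s = 0.0
    for di, dj in DIRS:
        s += l[(i + di) % L, (j + dj) % L]
    return s - 4.0 * l[i, j]


def binding_well_mask(l: np.ndarray, p: ModelParams) -> np.ndarray:
    """Boolean mask of patches whose separation lies strictly in the well."""
    half = 0.5 * p.l_b
    return (l > p.l_c - half) & (l < p.l_c + half)


def bending_energy(state: LatticeState, p: ModelParams) -> float:
    lap = laplacian_field(state.l)
    return float(p.kappa / (2.0 * p.a * p.a) * np.sum(lap * lap))


def binding_energy(state: LatticeState, p: ModelParams) -> float:
    pairs = (state.m_plus & state.m_minus).astype(bool)
    return float(-p.u_b * np.count_nonzero(pairs & binding_well_mask(state.l, p)))


def raft_receptor_energy(state: LatticeState, p: ModelParams) -> float:
    return float(-p.u_a * np.count_nonzero(state.n_plus & state.m_plus))


def raft_raft_energy(state: LatticeState, p: ModelParams) -> float:
    n = state.n_plus
    bonds = np.count_nonzero(n & np.roll(n, 1, axis=0)) + np.count_nonzero(
        n & np.roll(n, 1, axis=1)
    )
    return float(-p.u * bonds)


def total_energy(state: LatticeState, p: ModelParams) -> EnergyBreakdown:
    return EnergyBreakdown(
        e_bend=bending_energy(state, p),
        e_bind=binding_energy(state, p),
        e_raft_receptor=raft_receptor_energy(state, p),
        e_raft_raft=raft_raft_energy(state, p),
    )


# ---------------------------------------------------------------------------
# incremental (single-move) energy differences


def _in_well(l: float, p: ModelParams) -> bool:
    half = 0.5 * p.l_b
    return (l > p.l_c - half) and (l < p.l_c + half)


def _wrap(site, L):
    return site[0] % L, site[1] % L


def local_delta_energy(state: LatticeState, p: ModelParams, move) -> float:
    """Energy change of applying ``move``, evaluated locally.

    Equals ``total_energy(after).e_total - total_energy(before).e_total``
    but touches only the affected neighborhood.  Raises
    :class:`MoveError` when the descriptor does not match the state.
    """
    L = state.L
    if isinstance(move, HeightMove):
        i, j = _wrap(move.site, L)
        lnew = state.l[i, j] + move.dl
        d_bend = _delta_bending(state, p, i, j, move.dl)
        d_bind = 0.0
        if state.m_plus[i, j] and state.m_minus[i, j]:
            d_bind = -p.u_b * (
                int(_in_well(lnew, p)) - int(_in_well(state.l[i, j], p))
            )
        return d_bend + d_bind
    if isinstance(move, ProteinHop):
        if move.surface not in ("upper", "lower"):
            raise MoveError(f"unknown surface {move.surface!r}")
        if not 0 <= move.direction < 4:
            raise MoveError(f"bad direction {move.direction}")
        i, j = _wrap(move.site, L)
        di, dj = DIRS[move.direction]
        ti, tj = (i + di) % L, (j + dj) % L
        occ = state.m_plus if move.surface == "upper" else state.m_minus
        if not occ[i, j]:
            raise MoveError(f"no protein at {move.surface} site {(i, j)}")
        other = state.m_minus if move.surface == "upper" else state.m_plus
        d = -p.u_b * (
            int(other[ti, tj]) * _in_well(state.l[ti, tj], p)
            - int(other[i, j]) * _in_well(state.l[i, j], p)
        )
        if move.surface == "upper":
            d += -p.u_a * (int(state.n_plus[ti, tj]) - int(state.n_plus[i, j]))
        return d
    if isinstance(move, RaftHop):
        if not 0 <= move.direction < 4:
            raise MoveError(f"bad direction {move.direction}")
        i, j = _wrap(move.site, L)
        if not state.n_plus[i, j]:
            raise MoveError(f"no raft at site {(i, j)}")
        di, dj = DIRS[move.direction]
        ti, tj = (i + di) % L, (j + dj) % L
        bonds_src = sum(
            int(state.n_plus[(i + a1) % L, (j + a2) % L]) for a1, a2 in DIRS
        )
        bonds_dst = sum(
            int(state.n_plus[(ti + a1) % L, (tj + a2) % L])
            for a1, a2 in DIRS
            if ((ti + a1) % L, (tj + a2) % L) != (i, j)
        )
        d = p.u * (bonds_src - bonds_dst)
        d += p.u_a * (int(state.m_plus[i, j]) - int(state.m_plus[ti, tj]))
        return d
    raise MoveError(f"unknown move descriptor {move!r}")


def _delta_bending(state: LatticeState, p: ModelParams, i: int, j: int, dl: float) -> float:
    # changing l[i,j] shifts the Laplacian by -4*dl at the site and +dl at
    # each of its four neighbors
    L = state.L
    lap0 = discrete_laplacian(state, (i, j))
    d = (lap0 - 4.0 * dl) ** 2 - lap0 * lap0
    for di, dj in DIRS:
        lapn = discrete_laplacian(state, ((i + di) % L, (j + dj) % L))
        d += (lapn + dl) ** 2 - lapn * lapn
    return p.kappa / (2.0 * p.a * p.a) * d


def apply_move(state: LatticeState, move) -> None:
    """Mutate ``state`` by applying an (already validated) move."""
    L = state.L
    if isinstance(move, HeightMove):
        i, j = _wrap(move.site, L)
        state.l[i, j] += move.dl
        return
    if isinstance(move, ProteinHop):
        i, j = _wrap(move.site, L)
        di, dj = DIRS[move.direction]
        ti, tj = (i + di) % L, (j + dj) % L
        occ = state.m_plus if move.surface == "upper" else state.m_minus
        if not occ[i, j]:
            raise MoveError(f"no protein at {move.surface} site {(i, j)}")
        if occ[ti, tj]:
            raise MoveError(f"destination {(ti, tj)} occupied")
        occ[i, j] = 0
        occ[ti, tj] = 1
        return
    if isinstance(move, RaftHop):
        i, j = _wrap(move.site, L)
        di, dj = DIRS[move.direction]
        ti, tj = (i + di) % L, (j + dj) % L
        if not state.n_plus[i, j]:
            raise MoveError(f"no raft at site {(i, j)}")
        if state.n_plus[ti, tj]:
            raise MoveError(f"destination {(ti, tj)} already carries a raft")
        state.n_plus[i, j] = 0
        state.n_plus[ti, tj] = 1
        return
    raise MoveError(f"unknown move descriptor {move!r}")


# ---------------------------------------------------------------------------
# snapshot serialization


def save_state(path, state: LatticeState, params: ModelParams | None = None) -> None:
    """Write a lossless snapshot (npz container)."""
    meta = {"ligands_mobile": state.ligands_mobile}
    if params is not None:
        meta["params"] = json.loads(params.to_json())
    np.savez(
        path,
        l=state.l,
        m_plus=state.m_plus,
        m_minus=state.m_minus,
        n_plus=state.n_plus,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_state(path):
    """Read a snapshot; returns ``(state, params_or_None)``."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        state = LatticeState(
            l=z["l"].astype(np.float64),
            m_plus=z["m_plus"].astype(np.uint8),
            m_minus=z["m_minus"].astype(np.uint8),
            n_plus=z["n_plus"].astype(np.uint8),
            ligands_mobile=bool(meta["ligands_mobile"]),
        )
    params = ModelParams(**meta["params"]) if "params" in meta else None
    return state, params
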