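"""Mean-field theory of the mobile-ligand adhesion system.

The raft lattice gas is treated at the Bragg-Williams level and the
receptor-ligand binding enters through the contact probability ``Pb``,
the equilibrium fraction of membrane patches inside the binding well for
a homogeneous reference membrane (measured by MC).  The free energy per
patch of a region with raft density ``phi`` is

    f(phi) = (z/2) u_eff phi (1 - phi) + phi ln phi + (1-phi) ln(1-phi)
             + f_part(phi)

(the symmetric regular-solution form; it differs from the bare
Bragg-Williams energy ``-(z/2) u_eff phi^2`` only by a linear term that
cannot affect coexistence)

with a receptor partitioning / binding-mixing term

    f_part(phi) = -rho_R [ ln(1 + c*phi) - ln(1 + b*phi) ],
    b = e^{ua} - 1,   c = e^{ua} (1 + chi) - 1,
    chi = rho_L * Pb * (e^{ub} - 1),

and a fluctuation-mediated attraction between bound complexes that
renormalizes the raft contact energy,

    u_eff = u + rho_R * theta_a * ln(1 + chi),
    theta_a = (e^{ua} - 1) / (e^{ua} + 1).

``rho_R`` and ``rho_L`` are per-patch receptor and ligand occupancies.
Both binding terms vanish as ``Pb -> 0`` or ``ub -> 0``, and at
``rho_R = 0`` the model is the symmetric lattice gas with critical
contact energy u = 1 kBT at density 1/2.  Coexisting densities follow
from the common-tangent construction on f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .mc_engine import RunConfig, run_from_state
from .model_core import LatticeState, ModelParams
from .observables import contact_fraction

Z_SQUARE = 4


class SolverError(RuntimeError):
    """Self-consistent solution did not converge."""


@dataclass(frozen=True)
class MFConfig:
    """Mean-field inputs: composition, couplings and contact probability."""

    x: float = 0.2
    cR: float = 0.0
    cL: float = 1000.0
    u: float = 1.0
    ua: float = 3.0
    ub: float = 6.0
    Pb: float = 0.5
    z: int = Z_SQUARE
    a: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.x < 1.0:
            raise ValueError("x must lie in (0, 1)")
        if not 0.0 <= self.Pb <= 1.0:
            raise ValueError("Pb must lie in [0, 1]")
        if self.z != 4:
            raise ValueError("square lattice: z must be 4")

    @property
    def rho_R(self) -> float:
        return self.cR * self.a**2 / 1e6

    @property
    def rho_L(self) -> float:
        return self.cL * self.a**2 / 1e6

    @property
    def chi(self) -> float:
        return self.rho_L * self.Pb * (math.exp(self.ub) - 1.0)

    @property
    def u_eff_shift(self) -> float:
        """Binding renormalization of the raft contact energy."""
        theta_a = (math.exp(self.ua) - 1.0) / (math.exp(self.ua) + 1.0)
        return self.rho_R * theta_a * math.log1p(self.chi)

    def replace(self, **kw) -> "MFConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class MFSolution:
    """Coexisting raft densities and transition energy for one config."""

    phi_low: float
    phi_high: float
    separated: bool
    u_transition: float


def _bc(cfg: MFConfig) -> tuple[float, float]:
    b = math.exp(cfg.ua) - 1.0
    c = math.exp(cfg.ua) * (1.0 + cfg.chi) - 1.0
    return b, c


def mf_free_energy(phi: float, cfg: MFConfig) -> float:
    """Free energy per patch (kBT) of a homogeneous region at raft
    density ``phi`` in (0, 1)."""
    phi = float(phi)
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    b, c = _bc(cfg)
    u_eff = cfg.u + cfg.u_eff_shift
    f = (cfg.z / 2.0) * u_eff * phi * (1.0 - phi)
    f += phi * math.log(phi) + (1.0 - phi) * math.log(1.0 - phi)
    f += -cfg.rho_R * (math.log1p(c * phi) - math.log1p(b * phi))
    return f


def _f1(phi, cfg):
    b, c = _bc(cfg)
    u_eff = cfg.u + cfg.u_eff_shift
    return (
        (cfg.z / 2.0) * u_eff * (1.0 - 2.0 * phi)
        + math.log(phi / (1.0 - phi))
        - cfg.rho_R * (c / (1.0 + c * phi) - b / (1.0 + b * phi))
    )


def _f2(phi, cfg):
    b, c = _bc(cfg)
    u_eff = cfg.u + cfg.u_eff_shift
    return (
        -cfg.z * u_eff
        + 1.0 / phi
        + 1.0 / (1.0 - phi)
        + cfg.rho_R * ((c / (1.0 + c * phi)) ** 2 - (b / (1.0 + b * phi)) ** 2)
    )


def _f3(phi, cfg):
    b, c = _bc(cfg)
    return (
        -1.0 / phi**2
        + 1.0 / (1.0 - phi) ** 2
        - 2.0 * cfg.rho_R * ((c / (1.0 + c * phi)) ** 3 - (b / (1.0 + b * phi)) ** 3)
    )



def critical_point(cfg: MFConfig) -> tuple[float, float]:
    """(phi_c, u_c) where both f'' and f''' vanish.

    f''' is u-independent, so phi_c solves f'''(phi)=0 and u_c follows
    from f''(phi_c)=0.
    """
    phi_c = optimize.brentq(lambda p: _f3(p, cfg), 1e-6, 1.0 - 1e-6, xtol=1e-14)
    u_c = (
        1.0 / phi_c
        + 1.0 / (1.0 - phi_c)
        + cfg.rho_R
        * (
            (_bc(cfg)[1] / (1.0 + _bc(cfg)[1] * phi_c)) ** 2
            - (_bc(cfg)[0] / (1.0 + _bc(cfg)[0] * phi_c)) ** 2
        )
    ) / cfg.z - cfg.u_eff_shift
    return phi_c, u_c


def coexistence_densities(cfg: MFConfig) -> tuple[float, float] | None:
    """Common-tangent densities at ``cfg.u``; None when homogeneous.

    Works by equal-minimum construction: find the exchange chemical
    potential mu for which the two local minima of ``f(phi) - mu phi``
    (bracketed by the spinodal densities, where f'' = 0) are equally
    deep.  Equivalent to the common tangent and numerically robust down
    to the critical point.
    """
    phi_c, u_c = critical_point(cfg)
    if cfg.u <= u_c + 1e-12:
        return None
    eps = 1e-12
    s1 = optimize.brentq(_f2, eps, phi_c, args=(cfg,), xtol=1e-15)
    s2 = optimize.brentq(_f2, phi_c, 1.0 - eps, args=(cfg,), xtol=1e-15)
    mu_hi = _f1(s1, cfg)  # local maximum of f'
    mu_lo = _f1(s2, cfg)  # local minimum of f'
    if not mu_lo < mu_hi:
        raise SolverError(f"spinodal bracketing failed at u={cfg.u:g}")

    def minima(mu):
        pa = optimize.brentq(
            lambda q: _f1(q, cfg) - mu, eps, s1, xtol=1e-15, maxiter=200
        )
        pb = optimize.brentq(
            lambda q: _f1(q, cfg) - mu, s2, 1.0 - eps, xtol=1e-15, maxiter=200
        )
        return pa, pb

    def depth_gap(mu):
        pa, pb = minima(mu)
        return (mf_free_energy(pa, cfg) - mu * pa) - (
            mf_free_energy(pb, cfg) - mu * pb
        )

    margin = 1e-9 * (mu_hi - mu_lo)
    mu = optimize.brentq(
        depth_gap, mu_lo + margin, mu_hi - margin, xtol=1e-15, maxiter=200
    )
    p1, p2 = minima(mu)
    mu1, mu2 = _f1(p1, cfg), _f1(p2, cfg)
    psi1 = mf_free_energy(p1, cfg) - p1 * mu1
    psi2 = mf_free_energy(p2, cfg) - p2 * mu2
    if max(abs(mu1 - mu2), abs(psi1 - psi2)) > 1e-8:
        raise SolverError(
            f"common tangent residual ({mu1 - mu2:g}, {psi1 - psi2:g}) at u={cfg.u:g}"
        )
    return float(p1), float(p2)


def transition_u(cfg: MFConfig, u_tol: float = 1e-4, u_max: float = 20.0) -> float:
    """Smallest contact energy at which raft fraction ``x`` enters the
    coexistence region (bisection in u)."""
    phi_c, u_c = critical_point(cfg)
    if abs(cfg.x - phi_c) < 1e-9:
        return float(u_c)

    def inside(u):
        co = coexistence_densities(cfg.replace(u=float(u)))
        if co is None:
            return False
        return co[0] < cfg.x < co[1]

    lo, hi = u_c, None
    u = max(2.0 * u_c, u_c + 0.1)
    while u < u_max:
        if inside(u):
            hi = u
            break
        lo = u
        u *= 1.5
    if hi is None:
        raise SolverError(f"x={cfg.x:g} not inside coexistence up to u={u_max:g}")
    while hi - lo > u_tol:
        mid = 0.5 * (lo + hi)
        if inside(mid):
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))


def solve_self_consistent(cfg: MFConfig) -> MFSolution:
    """Coexisting densities at ``cfg.u`` plus the transition energy for
    ``cfg.x``."""
    co = coexistence_densities(cfg)
    u_t = transition_u(cfg)
    if co is None:
        return MFSolution(cfg.x, cfg.x, False, u_t)
    lo, hi = co
    return MFSolution(lo, hi, lo < cfg.x < hi, u_t)


def mf_phase_line(cfg: MFConfig, cR_grid) -> pd.DataFrame:
    """Mean-field transition line over a receptor-concentration grid,
    normalized by the zero-receptor critical energy (1 kBT)."""
    rows = []
    for cR in cR_grid:
        u_t = transition_u(cfg.replace(cR=float(cR)))
        rows.append({"x": cfg.x, "cR": float(cR), "u_transition": u_t,
                     "u_normalized": u_t / 1.0})
    return pd.DataFrame(rows)


def estimate_contact_probability(
    p: ModelParams,
    L: int = 32,
    run: RunConfig | None = None,
) -> float:
    """Contact probability Pb: time-averaged fraction of patches inside
    the binding well for a homogeneous reference membrane.

    The reference system is a fluctuating membrane bound uniformly to
    the substrate (every patch apposes a binding partner, no rafts),
    sampled with height moves only.
    """
    if run is None:
        run = RunConfig(
            n_relax_cycles=20_000, n_sample_cycles=50_000, sample_interval=50
        )
    from .mc_engine import MoveMix

    state = LatticeState.flat(L, p.l_c, ligands_mobile=False)
    state.m_plus[:, :] = 1
    state.m_minus[:, :] = 1
    series = run_from_state(state, p, run, mix=MoveMix(L * L, 0, 0))
    return contact_fraction(series)
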