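"""Measured quantities: heat capacity, 2D binding constant, raft
partitioning, and replicate statistics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import LatticeState, ModelParams, binding_well_mask


class UndefinedBindingConstantError(ValueError):
    """K is undefined because unbound receptors or ligands average to zero
    (saturated system)."""


@dataclass
class SampleSeries:
    """Recorded observables of one simulation run.

    All energy columns are in kBT; counts are per configuration sample.
    ``N`` is the number of membrane patches and ``area_um2`` the membrane
    area, so concentrations are counts / area.
    """

    cycle: np.ndarray
    e_total: np.ndarray
    e_bend: np.ndarray
    e_bind: np.ndarray
    e_raft_receptor: np.ndarray
    e_raft_raft: np.ndarray
    n_complexes: np.ndarray
    n_receptors_on_raft: np.ndarray
    n_patches_in_well: np.ndarray
    n_receptors: int
    n_ligands: int
    N: int
    area_um2: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.n_complexes < 0):
            raise ValueError("negative complex count")
        if np.any(self.n_complexes > min(self.n_receptors, self.n_ligands)):
            raise ValueError("complex count exceeds receptor or ligand total")

    @property
    def n_samples(self) -> int:
        return len(self.cycle)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "e_total": self.e_total,
                "e_bend": self.e_bend,
                "e_bind": self.e_bind,
                "e_raft_receptor": self.e_raft_receptor,
                "e_raft_raft": self.e_raft_raft,
                "n_complexes": self.n_complexes,
                "n_receptors_on_raft": self.n_receptors_on_raft,
                "n_patches_in_well": self.n_patches_in_well,
            }
        )

    def to_csv(self, path) -> None:
        header = {
            "n_receptors": self.n_receptors,
            "n_ligands": self.n_ligands,
            "N": self.N,
            "area_um2": self.area_um2,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header, sort_keys=True, default=str) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSeries":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("# "))
            df = pd.read_csv(fh)
        return cls(
            cycle=df["cycle"].to_numpy(),
            e_total=df["e_total"].to_numpy(),
            e_bend=df["e_bend"].to_numpy(),
            e_bind=df["e_bind"].to_numpy(),
            e_raft_receptor=df["e_raft_receptor"].to_numpy(),
            e_raft_raft=df["e_raft_raft"].to_numpy(),
            n_complexes=df["n_complexes"].to_numpy(),
            n_receptors_on_raft=df["n_receptors_on_raft"].to_numpy(),
            n_patches_in_well=df["n_patches_in_well"].to_numpy(),
            n_receptors=int(header["n_receptors"]),
            n_ligands=int(header["n_ligands"]),
            N=int(header["N"]),
            area_um2=float(header["area_um2"]),
            provenance=header.get("provenance", {}),
        )


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and population SD of a scalar over independent runs."""

    mean: float
    sd: float
    n_replicates: int


def heat_capacity(series: SampleSeries, kT: float = 1.0) -> float:
    """Heat capacity per lattice site, ``var(H) / (N kT^2)`` (kB units)."""
    if series.n_samples < 2:
        raise ValueError("heat capacity needs at least 2 energy samples")
    return float(np.var(series.e_total) / (series.N * kT * kT))


def count_complexes(state: LatticeState, p: ModelParams) -> int:
    """Receptor-ligand complexes: apposed pair with separation in the well."""
    pairs = (state.m_plus & state.m_minus).astype(bool)
    return int(np.count_nonzero(pairs & binding_well_mask(state.l, p)))


def binding_constant(series: SampleSeries) -> float:
    """2D binding constant ``K = <[RL]> / (<[R]> <[L]>)`` in µm^2.

    Concentrations are time-averaged counts divided by membrane area.
    Returns 0 when no complexes ever form; raises
    :class:`UndefinedBindingConstantError` when the unbound-receptor or
    unbound-ligand average vanishes (saturation).
    """
    mean_rl = float(np.mean(series.n_complexes))
    if mean_rl == 0.0:
        return 0.0
    mean_r = series.n_receptors - mean_rl
    mean_l = series.n_ligands - mean_rl
    if mean_r <= 0 or mean_l <= 0:
        raise UndefinedBindingConstantError(
            "time-averaged unbound receptor or ligand count is zero"
        )
    area = series.area_um2
    return float((mean_rl / area) / ((mean_r / area) * (mean_l / area)))


def raft_receptor_concentration(series: SampleSeries, x: float) -> float:
    """Time-averaged receptor concentration inside raft domains (µm^-2)."""
    if x <= 0:
        raise ValueError("raft area fraction x must be > 0")
    raft_area = x * series.area_um2
    return float(np.mean(series.n_receptors_on_raft) / raft_area)


def contact_fraction(series: SampleSeries) -> float:
    """Time-averaged fraction of membrane patches inside the binding well."""
    return float(np.mean(series.n_patches_in_well) / series.N)


def aggregate_replicates(values) -> ReplicateSummary:
    """Mean and population SD (ddof=0) over replicate measurements."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("aggregate_replicates needs at least one value")
    return ReplicateSummary(
        mean=float(arr.mean()), sd=float(arr.std(ddof=0)), n_replicates=arr.size
    )
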