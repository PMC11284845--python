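"""Curtin-Hammett selectivity from transition-state free energies.

Given per-pathway TS free energies (kcal/mol, relative to one shared
reference intermediate), three treatments are available:

* ``boltzmann`` — each pathway's conformers form a single freely
  interconvertible pool; the pool's ensemble free energy is its
  Boltzmann-weighted mean, and the product ratio follows from the
  difference of the two pool energies;
* ``rate_sum`` — no interconversion: every conformer is a parallel
  channel, Eyring rate constants are summed, and the ratio of the summed
  rates sets the split;
* ``cluster_resolved`` — the hybrid: conformers within a cluster are
  interconvertible (Boltzmann ensemble energy per cluster), clusters react
  in parallel (rate constants summed over cluster ensemble energies).

All exponentials are evaluated shift-stably so arbitrary absolute energy
scales are safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, ContractError

__all__ = [
    "R_KCAL",
    "KB_OVER_H",
    "T_DEFAULT",
    "PathwayEnergies",
    "SelectivityReport",
    "boltzmann_weights",
    "ensemble_free_energy",
    "ratio_from_ddg",
    "effective_barrier",
    "eyring_rate",
    "selectivity",
    "duplicate_sensitivity",
    "pathways_from_frame",
    "read_energy_table",
    "METHODS",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3
#: k_B / h in s^-1 K^-1.
KB_OVER_H = 2.083661e10
#: Default temperature (K).
T_DEFAULT = 298.15

METHODS = ("boltzmann", "rate_sum", "cluster_resolved")


def _check_T(T: float) -> None:
    if not T > 0:
        raise ContractError(f"temperature must be positive, got {T}")


@dataclass
class PathwayEnergies:
    """TS free energies for one product, grouped into interconvertible clusters.

    Every energy is in kcal/mol relative to the same reference intermediate
    shared by all pathways.
    """

    product_label: str
    clusters: list[list[float]]

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ContractError(f"pathway {self.product_label!r} has no clusters")
        for i, c in enumerate(self.clusters):
            if not c:
                raise ContractError(f"pathway {self.product_label!r} cluster {i} is empty")
            if not np.all(np.isfinite(c)):
                raise ContractError(f"pathway {self.product_label!r} cluster {i} has non-finite energy")

    def flatten(self) -> list[float]:
        return [g for c in self.clusters for g in c]

    def shifted(self, c: float) -> "PathwayEnergies":
        return PathwayEnergies(self.product_label, [[g + c for g in cl] for cl in self.clusters])


@dataclass
class SelectivityReport:
    """Result of one selectivity treatment for a pair of pathways."""

    method: str
    temperature: float
    product_a: str
    product_b: str
    barrier_a: float
    barrier_b: float
    ddg: float
    ratio: float
    percent_a: int
    percent_b: int
    cluster_energies_a: list[float] = field(default_factory=list)
    cluster_energies_b: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "temperature_K": self.temperature,
            "products": [self.product_a, self.product_b],
            "effective_barrier_kcal_mol": {
                self.product_a: self.barrier_a,
                self.product_b: self.barrier_b,
            },
            "ddg_kcal_mol": self.ddg,
            "ratio": self.ratio,
            "percent": {self.product_a: self.percent_a, self.product_b: self.percent_b},
            "cluster_ensemble_energies_kcal_mol": {
                self.product_a: self.cluster_energies_a,
                self.product_b: self.cluster_energies_b,
            },
        }


def boltzmann_weights(energies, T: float = T_DEFAULT) -> np.ndarray:
    """Normalized Boltzmann weights of a set of free energies (kcal/mol)."""
    _check_T(T)
    g = np.asarray(energies, dtype=float)
    if g.size == 0:
        raise ContractError("boltzmann_weights needs at least one energy")
    x = -(g - g.min()) / (R_KCAL * T)
    w = np.exp(x)
    return w / w.sum()


def ensemble_free_energy(energies, T: float = T_DEFAULT) -> float:
    """Boltzmann-weighted mean free energy of an interconvertible pool.

    Lies between min and max of the input, strictly above the minimum unless
    all energies are degenerate.
    """
    g = np.asarray(energies, dtype=float)
    if g.size == 0:
        raise ContractError("ensemble_free_energy needs at least one energy")
    return float(boltzmann_weights(g, T) @ g)


def effective_barrier(energies, T: float = T_DEFAULT) -> float:
    """Barrier reproducing the summed rate constants of parallel channels.

    ``-RT ln sum_j exp(-G_j / RT)``; always <= min(energies), with equality
    only for a single channel.
    """
    _check_T(T)
    g = np.asarray(energies, dtype=float)
    if g.size == 0:
        raise ContractError("effective_barrier needs at least one energy")
    rt = R_KCAL * T
    return float(-rt * logsumexp(-g / rt))


def eyring_rate(dg: float, T: float = T_DEFAULT) -> float:
    """Eyring rate constant (s^-1) for a barrier in kcal/mol."""
    _check_T(T)
    return KB_OVER_H * T * np.exp(-dg / (R_KCAL * T))


def _split_from_ratio(ratio: float) -> tuple[int, int]:
    pa = 100.0 * ratio / (1.0 + ratio)
    pb = 100.0 - pa
    ia, ib = int(round(pa)), int(round(pb))
    if ia + ib != 100:  # larger side absorbs the rounding remainder
        if ia >= ib:
            ia = 100 - ib
        else:
            ib = 100 - ia
    return ia, ib


def ratio_from_ddg(ddg: float, T: float = T_DEFAULT) -> tuple[float, tuple[int, int]]:
    """Product ratio and integer percentage split from a barrier difference.

    ``ratio = exp(-ddg / RT)`` where ``ddg = G_a - G_b``; percentages are
    rounded to integers that sum to 100 with the larger side absorbing the
    remainder.
    """
    _check_T(T)
    ratio = float(np.exp(-ddg / (R_KCAL * T)))
    return ratio, _split_from_ratio(ratio)


def duplicate_sensitivity(energies, T: float = T_DEFAULT) -> float:
    """Barrier drop caused by double-counting the lowest-energy conformer.

    Returns ``effective_barrier(E) - effective_barrier(E + [min E])``;
    positive, bounded above by RT ln 2 (attained when the minimum dominates).
    """
    g = list(np.asarray(energies, dtype=float))
    if not g:
        raise ContractError("duplicate_sensitivity needs at least one energy")
    return effective_barrier(g, T) - effective_barrier(g + [min(g)], T)


def _pathway_barrier(p: PathwayEnergies, T: float, method: str) -> tuple[float, list[float]]:
    if method == "boltzmann":
        ens = ensemble_free_energy(p.flatten(), T)
        return ens, [ens]
    if method == "rate_sum":
        return effective_barrier(p.flatten(), T), [float(g) for g in p.flatten()]
    if method == "cluster_resolved":
        cluster_energies = [ensemble_free_energy(c, T) for c in p.clusters]
        return effective_barrier(cluster_energies, T), cluster_energies
    raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")


def selectivity(
    pathway_a: PathwayEnergies,
    pathway_b: PathwayEnergies,
    T: float = T_DEFAULT,
    method: str = "cluster_resolved",
) -> SelectivityReport:
    """Two-pathway Curtin-Hammett selectivity under the chosen treatment.

    The reported ``ratio`` is ``k_eff(a) / k_eff(b)`` expressed through the
    effective barrier difference; the reference-state mole fraction is
    neglected throughout.
    """
    _check_T(T)
    ga, ca = _pathway_barrier(pathway_a, T, method)
    gb, cb = _pathway_barrier(pathway_b, T, method)
    ddg = ga - gb
    ratio, (pa, pb) = ratio_from_ddg(ddg, T)
    return SelectivityReport(
        method=method,
        temperature=T,
        product_a=pathway_a.product_label,
        product_b=pathway_b.product_label,
        barrier_a=ga,
        barrier_b=gb,
        ddg=ddg,
        ratio=ratio,
        percent_a=pa,
        percent_b=pb,
        cluster_energies_a=ca,
        cluster_energies_b=cb,
    )


def pathways_from_frame(df) -> dict[str, PathwayEnergies]:
    """Build pathway energies from a table with (product, energy_kcal_mol[, cluster]).

    The ``cluster`` column is optional; without it every product forms a
    single cluster.  Returns a mapping product label -> PathwayEnergies.
    """
    required = {"product", "energy_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"energy table is missing columns: {sorted(missing)}")
    pathways: dict[str, PathwayEnergies] = {}
    for product, grp in df.groupby("product", sort=True):
        if "cluster" in df.columns:
            clusters = [
                [float(x) for x in sub["energy_kcal_mol"]]
                for _, sub in grp.groupby("cluster", sort=True)
            ]
        else:
            clusters = [[float(x) for x in grp["energy_kcal_mol"]]]
        pathways[str(product)] = PathwayEnergies(str(product), clusters)
    return pathways


def read_energy_table(path) -> dict[str, PathwayEnergies]:
    """Load pathway energies from a CSV file (see :func:`pathways_from_frame`)."""
    import pandas as pd

    return pathways_from_frame(pd.read_csv(path))
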