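"""Thermal unfolding by constraint dilution and rigid-contact stability maps.

Unfolding is simulated by removing hydrogen-bond (and salt-bridge)
constraints from the network in order of increasing strength: the energy
cutoff ``E_cut`` sweeps downward from 0, a constraint of energy ``E``
survives while ``E < E_cut``, and covalent and hydrophobic constraints
never dilute.  A linear empirical map ``T = a * E_cut + b`` converts the
cutoff to a temperature; the phase transition temperature ``T_p`` marks
the state where the network order parameter ``P_inf`` (fraction of bodies
in the largest rigid cluster) collapses from largely rigid to largely
flexible.

The per-state decompositions also yield the rigid-contact stability map:
for every residue pair that starts out co-rigid, ``E_rc`` is the cutoff
at which the pair first ceases to share a rigid cluster — the more
negative, the more thermostable the contact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .interactions import Interaction
from .rigidity import (
    ConstraintNetwork,
    RigidDecomposition,
    build_network,
    pebble_game,
    residue_cluster_membership,
)
from .structio import ResKey, Structure


@dataclass
class TemperatureMap:
    """Linear empirical map from energy cutoff (kcal/mol) to temperature (K).

    The default (slope -20 K mol/kcal, intercept 300 K) is a placeholder
    calibration: rank orders, correlations and energy differences are
    invariant to the choice, absolute temperatures are not.
    """

    slope: float = -20.0
    intercept: float = 300.0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("slope must be negative (stronger cutoff = hotter)")


DEFAULT_TEMPERATURE_MAP = TemperatureMap()


def temperature_of(e_cut: float, tmap: TemperatureMap | None = None) -> float:
    """T = slope * E_cut + intercept."""
    tmap = tmap or DEFAULT_TEMPERATURE_MAP
    return tmap.slope * e_cut + tmap.intercept


@dataclass
class DilutionState:
    e_cut: float
    temperature: float
    decomposition: RigidDecomposition
    residue_cluster: dict[ResKey, int]

    @property
    def p_inf(self) -> float:
        return self.decomposition.p_inf

    @property
    def n_clusters(self) -> int:
        return self.decomposition.n_clusters


@dataclass
class UnfoldingTrajectory:
    states: list[DilutionState]
    network: ConstraintNetwork
    provenance: str = ""

    @property
    def p_inf(self) -> np.ndarray:
        return np.array([s.p_inf for s in self.states])

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([s.temperature for s in self.states])

    @property
    def e_cuts(self) -> np.ndarray:
        return np.array([s.e_cut for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": range(len(self.states)),
            "e_cut": self.e_cuts,
            "temperature": self.temperatures,
            "p_inf": self.p_inf,
            "n_clusters": [s.n_clusters for s in self.states],
        })


def dilute_network(
    network: ConstraintNetwork,
    grid: str = "per_bond",
    step: float = 0.1,
    tmap: TemperatureMap | None = None,
    provenance: str = "",
) -> UnfoldingTrajectory:
    """Dilution trajectory of a prebuilt constraint network.

    The ``per_bond`` grid (default) places one state at E_cut = 0 and one
    at each distinct dilutable energy; a state's network keeps dilutable
    constraints *strictly stronger* than its E_cut, so the state labelled
    E_cut = E is the first in which bonds of energy E are gone and
    separation energies are exact.  ``fixed_step`` walks a uniform grid
    instead.  Covalent and hydrophobic bars are never removed.
    """
    tmap = tmap or DEFAULT_TEMPERATURE_MAP
    energies = network.dilutable_energies()
    if not energies:
        raise ValueError("trajectory undefined: no dilutable (hbond/salt) constraints")
    if grid == "per_bond":
        # group energies equal up to numerical noise; the group minimum is the
        # state cutoff, so the strict < filter removes the whole group at once
        distinct: list[float] = []
        for e in sorted(energies):  # ascending: strongest first
            if distinct and abs(e - distinct[-1]) < 1e-6:
                continue
            group = [x for x in energies if abs(x - e) < 1e-6]
            distinct.append(min(group))
        cuts = [0.0] + sorted(distinct, reverse=True)
    elif grid == "fixed_step":
        if step <= 0:
            raise ValueError("step must be positive")
        lo = min(energies)
        n_steps = int(math.ceil(-lo / step))
        cuts = [-k * step for k in range(n_steps + 1)]
        if cuts[-1] > lo:
            cuts.append(lo)
    else:
        raise ValueError("grid must be 'per_bond' or 'fixed_step'")

    states = []
    for e_cut in cuts:
        sub = network.filtered(e_cut, strict=True)
        decomposition = pebble_game(sub)
        residue_cluster = (residue_cluster_membership(decomposition, sub)
                           if sub.ca_body or sub.backbone_bodies else {})
        states.append(DilutionState(e_cut, temperature_of(e_cut, tmap),
                                    decomposition, residue_cluster))
    return UnfoldingTrajectory(states, network, provenance)


def dilute(
    structure: Structure,
    interactions: Sequence[Interaction],
    grid: str = "per_bond",
    step: float = 0.1,
    tmap: TemperatureMap | None = None,
    e_start: float = 0.0,
) -> UnfoldingTrajectory:
    """Build the network of a structure and run the dilution."""
    network = build_network(structure, interactions, e_cut=e_start)
    return dilute_network(network, grid=grid, step=step, tmap=tmap,
                          provenance=structure.name)


# --------------------------------------------------------------------------
# phase transition
# --------------------------------------------------------------------------

@dataclass
class PhaseTransition:
    """T_p estimate; ``transition=False`` flags an undetected transition."""

    t_p: float | None
    transition: bool
    e_cut: float | None = None
    method: str = "max_drop"


MIN_TRANSITION_DROP = 0.2


def phase_transition(trajectory: UnfoldingTrajectory,
                     method: str = "max_drop") -> PhaseTransition:
    """Locate the rigid-to-flexible transition along a trajectory.

    ``max_drop`` (default, deterministic): the state with the largest
    single-step decrease of P_inf, ties broken to the lowest temperature.
    ``sigmoid_fit``: midpoint of a least-squares two-state logistic fit of
    P_inf(T).  If the trajectory has fewer than 3 states or P_inf drops
    by less than 0.2 overall, the result is flagged as no transition.
    """
    p = trajectory.p_inf
    t = trajectory.temperatures
    if len(p) < 3 or (p[0] - p[-1]) < MIN_TRANSITION_DROP:
        return PhaseTransition(None, False, method=method)
    if method == "max_drop":
        drops = p[:-1] - p[1:]
        i = int(np.argmax(drops))  # argmax takes the first (lowest T) on ties
        return PhaseTransition(float(t[i + 1]), True,
                               float(trajectory.e_cuts[i + 1]), method)
    if method == "sigmoid_fit":
        p_hi, p_lo = float(p[0]), float(p[-1])

        def logistic(x, t_mid, width):
            return p_lo + (p_hi - p_lo) / (1.0 + np.exp((x - t_mid) / width))

        drops = p[:-1] - p[1:]
        guess = float(t[int(np.argmax(drops)) + 1])
        try:
            popt, _ = curve_fit(logistic, t, p, p0=[guess, max(1.0, 0.02 * np.ptp(t))],
                                maxfev=5000)
        except RuntimeError:
            return PhaseTransition(None, False, method=method)
        return PhaseTransition(float(popt[0]), True, None, method)
    raise ValueError("method must be 'max_drop' or 'sigmoid_fit'")


# --------------------------------------------------------------------------
# stability map
# --------------------------------------------------------------------------

@dataclass
class StabilityMap:
    """Residue-pair -> rigid-contact energy E_rc (kcal/mol).

    E_rc is the E_cut of the first dilution state in which the pair no
    longer shares a rigid cluster.  Pairs co-rigid through the final
    state carry the final E_cut and ``persistent=True``; pairs never
    co-rigid are absent.  Lookup is symmetric.
    """

    e_rc: dict[tuple[ResKey, ResKey], float] = field(default_factory=dict)
    persistent: set[tuple[ResKey, ResKey]] = field(default_factory=set)

    @staticmethod
    def _key(a: ResKey, b: ResKey) -> tuple[ResKey, ResKey]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: ResKey, b: ResKey) -> float | None:
        return self.e_rc.get(self._key(a, b))

    def is_persistent(self, a: ResKey, b: ResKey) -> bool:
        return self._key(a, b) in self.persistent

    def __len__(self) -> int:
        return len(self.e_rc)

    def items(self):
        return self.e_rc.items()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), e in sorted(self.e_rc.items()):
            rows.append({"chainA": a[0], "resA": a[1], "chainB": b[0], "resB": b[1],
                         "e_rc": e, "persistent": (a, b) in self.persistent})
        return pd.DataFrame(rows, columns=["chainA", "resA", "chainB", "resB",
                                           "e_rc", "persistent"])


def stability_map(trajectory: UnfoldingTrajectory) -> StabilityMap:
    """Rigid-contact energies from the per-state residue clusters."""
    states = trajectory.states
    if not states:
        raise ValueError("empty trajectory")
    first = states[0].residue_cluster
    residues = sorted(first)
    out = StabilityMap()
    pairs = [(a, b) for a, b in itertools.combinations(residues, 2)
             if first[a] == first[b]]
    open_pairs = set(pairs)
    for state in states[1:]:
        clusters = state.residue_cluster
        separated = [pr for pr in open_pairs if clusters[pr[0]] != clusters[pr[1]]]
        for pr in separated:
            out.e_rc[StabilityMap._key(*pr)] = state.e_cut
            open_pairs.discard(pr)
        if not open_pairs:
            break
    final_cut = states[-1].e_cut
    for pr in open_pairs:
        key = StabilityMap._key(*pr)
        out.e_rc[key] = final_cut
        out.persistent.add(key)
    return out


def unfold(structure: Structure, interactions: Sequence[Interaction],
           tmap: TemperatureMap | None = None,
           method: str = "max_drop") -> tuple[UnfoldingTrajectory, PhaseTransition, StabilityMap]:
    """Convenience pipeline: dilution, T_p and stability map in one call."""
    trajectory = dilute(structure, interactions, tmap=tmap)
    return trajectory, phase_transition(trajectory, method), stability_map(trajectory)
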