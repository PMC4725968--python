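"""Aggregate rigidity statistics: interface and per-element stability,
ensemble transition temperatures, growth-temperature correlation, and
ensemble diagnostics (RMSD, radius of gyration, RMSIP).

The headline quantities are (i) the summed rigid-contact energy over
dimer-interface residue pairs — the more negative, the more stable the
interface; (ii) the per-secondary-structure-element rigid-contact energy
(cross-contacts divided by element size); and (iii) ensemble statistics
of the phase transition temperature T_p regressed on the optimal growth
temperature of the source organism, T_org.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .interactions import Interaction, detect_all
from .structio import ResKey, SSEElement, Structure
from .unfolding import (
    PhaseTransition,
    StabilityMap,
    TemperatureMap,
    dilute,
    phase_transition,
    stability_map,
)

CELSIUS_OFFSET = 273.15


@dataclass
class OrthologMeta:
    """Metadata for one ortholog: name and host growth optimum (deg C)."""

    name: str
    t_org: float
    t_m: float | None = None  # experimental melting temperature, if known

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_org):
            raise ValueError("t_org must be finite")


@dataclass
class EnsembleTpResult:
    """Moments of per-model T_p values over a conformational ensemble."""

    t_p: list[float]
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.t_p)

    @property
    def mean(self) -> float:
        return float(np.mean(self.t_p))

    @property
    def sd(self) -> float:
        return float(np.std(self.t_p, ddof=1)) if self.n > 1 else 0.0

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n) if self.n else float("nan")

    @property
    def skewness(self) -> float:
        return float(stats.skew(self.t_p)) if self.n > 2 else 0.0

    def normality(self) -> tuple[float, float]:
        """Shapiro-Wilk statistic and p-value of the T_p distribution."""
        stat, p = stats.shapiro(self.t_p)
        return float(stat), float(p)


# --------------------------------------------------------------------------
# interface and per-element stability
# --------------------------------------------------------------------------

def interface_pairs(structure: Structure, cutoff: float = 5.0) -> list[tuple[ResKey, ResKey]]:
    """Interchain residue pairs with any heavy-atom distance <= cutoff."""
    if len(structure.chains) < 2:
        raise ValueError("interface requires at least two chains")
    if cutoff <= 0:
        return []
    per_chain: list[tuple[list[ResKey], np.ndarray]] = []
    for chain in structure.chains:
        keys, coords = [], []
        for res in chain.residues:
            if not res.is_protein:
                continue
            for atom in res.atoms:
                if atom.element != "H":
                    keys.append((chain.id, res.seqnum, res.icode))
                    coords.append(atom.coord)
        per_chain.append((keys, np.asarray(coords)))
    pairs: set[tuple[ResKey, ResKey]] = set()
    for i in range(len(per_chain)):
        keys_i, coords_i = per_chain[i]
        if not keys_i:
            continue
        tree = cKDTree(coords_i)
        for j in range(i + 1, len(per_chain)):
            keys_j, coords_j = per_chain[j]
            if not len(keys_j):
                continue
            hits = tree.query_ball_tree(cKDTree(coords_j), cutoff)
            for ia, neighbours in enumerate(hits):
                for ib in neighbours:
                    pairs.add((keys_i[ia], keys_j[ib]))
    return sorted(pairs)


def interface_rigidity_energy(stability: StabilityMap,
                              pairs: Sequence[tuple[ResKey, ResKey]]) -> float:
    """Sum of rigid-contact energies over the interface residue pairs.

    Pairs absent from the map (never co-rigid) contribute zero.
    """
    total = 0.0
    for a, b in pairs:
        e = stability.get(a, b)
        if e is not None:
            total += e
    return total


def sse_rigidity_energy(stability: StabilityMap,
                        elements: Sequence[SSEElement],
                        structure: Structure) -> pd.DataFrame:
    """Per-element rigid-contact energy, normalised by element size.

    For each element: the sum of E_rc over pairs with one residue inside
    and one outside, divided by the number of residues in the element;
    the standard error comes from the per-residue cross-contact sums.
    """
    import warnings

    all_residues = [(c.id, r.seqnum, r.icode)
                    for c, r in structure.iter_residues() if r.is_protein]
    rows = []
    for element in elements:
        inside = [rk for rk in all_residues if element.contains(rk)]
        if not inside:
            warnings.warn(f"element {element.label}: no residues, skipped")
            continue
        inside_set = set(inside)
        per_residue = []
        for rk in inside:
            s = 0.0
            for other in all_residues:
                if other in inside_set:
                    continue
                e = stability.get(rk, other)
                if e is not None:
                    s += e
            per_residue.append(s)
        arr = np.asarray(per_residue)
        n = len(arr)
        rows.append({
            "label": element.label, "kind": element.kind, "chain": element.chain_id,
            "n_residues": n,
            "energy_per_residue": float(arr.sum() / n),
            "sem": float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["label", "kind", "chain", "n_residues",
                                       "energy_per_residue", "sem"])


# --------------------------------------------------------------------------
# ensemble T_p statistics
# --------------------------------------------------------------------------

def tp_statistics(t_p_values: Sequence[float], n_excluded: int = 0) -> EnsembleTpResult:
    """Moments of a list of per-model transition temperatures."""
    values = [float(t) for t in t_p_values]
    if not values:
        raise ValueError("no transition temperatures to summarise")
    return EnsembleTpResult(values, n_excluded)


def ensemble_tp(
    ensemble: Structure,
    tmap: TemperatureMap | None = None,
    method: str = "max_drop",
    detector: Callable[[Structure], Sequence[Interaction]] = detect_all,
) -> EnsembleTpResult:
    """Per-model T_p over a multi-model structure, with moments.

    Each model runs the full pipeline (interaction detection, dilution,
    transition location); models without a detectable transition are
    excluded from the moments and counted in ``n_excluded``.
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble must have at least 2 models")
    values: list[float] = []
    excluded = 0
    for k in range(ensemble.n_models):
        model = ensemble.get_model(k)
        interactions = detector(model)
        try:
            trajectory = dilute(model, interactions, tmap=tmap)
        except ValueError:
            excluded += 1
            continue
        result = phase_transition(trajectory, method)
        if result.transition:
            values.append(result.t_p)
        else:
            excluded += 1
    if not values:
        raise ValueError("no model of the ensemble shows a transition")
    return EnsembleTpResult(values, excluded)


@dataclass
class TpTorgRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def correlate_tp_torg(
    results: Sequence[tuple[OrthologMeta, EnsembleTpResult]],
    weighted: bool = False,
) -> TpTorgRegression:
    """OLS of ensemble-mean T_p (K) on host growth temperature T_org (K).

    The default is unweighted; ``weighted=True`` uses 1/SEM^2 weights.
    Both variables are converted to Kelvin, so the slope is unitless and
    the intercept is in K.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 orthologs for a regression")
    x = np.array([meta.t_org + CELSIUS_OFFSET for meta, _ in results])
    y = np.array([res.mean for _, res in results])
    if weighted:
        import statsmodels.api as sm

        w = np.array([1.0 / max(res.sem, 1e-9) ** 2 for _, res in results])
        model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        slope, intercept = float(model.params[1]), float(model.params[0])
        return TpTorgRegression(slope, intercept, float(model.rsquared),
                                float(model.pvalues[1]), len(results))
    fit = stats.linregress(x, y)
    return TpTorgRegression(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2, float(fit.pvalue), len(results))


# --------------------------------------------------------------------------
# ensemble diagnostics
# --------------------------------------------------------------------------

def kabsch_rotation(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Least-squares rotation aligning centred ``moving`` onto ``fixed``."""
    h = moving.T @ fixed
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def superpose(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of ``moving`` onto ``fixed``."""
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    rot = kabsch_rotation(moving - mc, fixed - fc)
    return (moving - mc) @ rot.T + fc


def ca_rmsd(model_a: Structure | np.ndarray, model_b: Structure | np.ndarray,
            chain_ids: Sequence[str] | None = None) -> float:
    """C-alpha RMSD after optimal (Kabsch) superposition."""
    a = model_a if isinstance(model_a, np.ndarray) else model_a.ca_coords(chain_ids)
    b = model_b if isinstance(model_b, np.ndarray) else model_b.ca_coords(chain_ids)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need matched coordinate sets of >= 3 atoms")
    aligned = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((aligned - b) ** 2, axis=1))))


def radius_of_gyration(model: Structure | np.ndarray,
                       chain_ids: Sequence[str] | None = None) -> float:
    """Unweighted radius of gyration of the C-alpha set (A)."""
    coords = model if isinstance(model, np.ndarray) else model.ca_coords(chain_ids)
    if len(coords) == 0:
        raise ValueError("no atoms selected")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred ** 2, axis=1))))


def _ensemble_ca_stack(ensemble: Structure) -> np.ndarray:
    """(M, n_ca, 3) stack of C-alpha coordinates over the models."""
    idx = [i for i, (c, r, a) in enumerate(ensemble.iter_atoms()) if a.name == "CA"]
    if ensemble.model_coords is None:
        raise ValueError("not an ensemble (single model)")
    return ensemble.model_coords[:, idx, :]


def _superpose_stack(stack: np.ndarray, fit_fraction: float) -> np.ndarray:
    """Two-pass ensemble superposition onto the least-fluctuating residues.

    Pass 1 fits every model to the first on all residues and measures
    per-residue fluctuations; pass 2 refits on the ``fit_fraction``
    fraction with the lowest RMSF.
    """
    reference = stack[0]
    pass1 = np.stack([superpose(m, reference) for m in stack])
    mean1 = pass1.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((pass1 - mean1) ** 2, axis=2), axis=0))
    n_fit = max(3, int(round(fit_fraction * stack.shape[1])))
    fit_idx = np.argsort(rmsf, kind="stable")[:n_fit]
    out = []
    for m in stack:
        mc = m[fit_idx].mean(axis=0)
        fc = mean1[fit_idx].mean(axis=0)
        rot = kabsch_rotation(m[fit_idx] - mc, mean1[fit_idx] - fc)
        out.append((m - mc) @ rot.T + fc)
    return np.stack(out)


def principal_subspace(ensemble: Structure, n_modes: int = 10,
                       fit_fraction: float = 0.8) -> np.ndarray:
    """Top eigenvectors of the C-alpha covariance matrix, shape (3N, n_modes)."""
    stack = _ensemble_ca_stack(ensemble)
    if stack.shape[0] < n_modes + 1:
        raise ValueError(f"need at least {n_modes + 1} models for {n_modes} modes")
    aligned = _superpose_stack(stack, fit_fraction)
    flat = aligned.reshape(aligned.shape[0], -1)
    centred = flat - flat.mean(axis=0)
    cov = centred.T @ centred / (flat.shape[0] - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1][:n_modes]
    return eigenvectors[:, order]


def rmsip_subspaces(v: np.ndarray, w: np.ndarray) -> float:
    """Root-mean-square inner product of two orthonormal mode sets.

    ``sqrt((1/D) * sum_ij (v_i . w_j)^2)`` with D the number of modes;
    1 for identical subspaces, 0 for orthogonal ones.
    """
    if v.shape != w.shape:
        raise ValueError("subspaces must have identical shapes")
    overlap = v.T @ w
    return float(np.sqrt(np.sum(overlap ** 2) / v.shape[1]))


def rmsip(ensemble_a: Structure, ensemble_b: Structure, n_modes: int = 10,
          fit_fraction: float = 0.8) -> float:
    """RMSIP of the leading principal-component subspaces of two ensembles."""
    v = principal_subspace(ensemble_a, n_modes, fit_fraction)
    w = principal_subspace(ensemble_b, n_modes, fit_fraction)
    return rmsip_subspaces(v, w)
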