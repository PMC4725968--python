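"""Dimer-interface engineering screens.

``disulfide_screen`` finds interchain residue pairs whose C-beta atoms sit
at native-cystine geometry (3.83 +/- 0.18 A between the C-beta atoms of
the two chains, prolines excluded), the classic empirical criterion for
placing an artificial interchain disulfide bridge; on a C2-symmetric
homodimer a symmetric hit means a single point mutation provides both
cysteines.  ``interface_report`` ranks interface residues by their summed
rigid-contact energy and flags candidates for destabilising mutations
(salt-bridge partners for charge-repulsion swaps, hydrophobic cluster
members for steric disruption).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import KIND_HYDROPHOBIC, KIND_SALT, Interaction
from .structio import ResKey, Structure, place_atom
from .unfolding import StabilityMap

DISULFIDE_CB_DISTANCE = 3.83
DISULFIDE_HALFWIDTH = 0.18


@dataclass(frozen=True)
class DisulfideCandidate:
    chain_a: str
    res_a: int
    name_a: str
    chain_b: str
    res_b: int
    name_b: str
    distance: float
    symmetric: bool  # same residue number in both chains of a homodimer


def _virtual_cb(res) -> np.ndarray | None:
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        return None
    return place_atom(n.coord, c.coord, ca.coord, 1.53, 110.5, 123.0)


def disulfide_screen(
    structure: Structure,
    center: float = DISULFIDE_CB_DISTANCE,
    halfwidth: float = DISULFIDE_HALFWIDTH,
    virtual_cb_for_gly: bool = False,
) -> list[DisulfideCandidate]:
    """Interchain C-beta pairs within ``center +/- halfwidth`` (closed window).

    Prolines are excluded; glycine (no C-beta) is skipped unless
    ``virtual_cb_for_gly`` reconstructs an ideal tetrahedral C-beta from
    the backbone.  For ensembles the first model is screened.  Candidates
    are sorted by distance; the pair identity is canonical under chain
    order swap.
    """
    if len(structure.chains) < 2:
        raise ValueError("disulfide screen requires at least two chains")
    model = structure.get_model(0) if structure.n_models > 1 else structure
    per_chain: list[tuple[str, list[tuple[int, str, str]], np.ndarray]] = []
    for chain in model.chains:
        entries, coords = [], []
        for res in chain.residues:
            if not res.is_protein or res.name == "PRO":
                continue
            cb = res.atom("CB")
            coord = cb.coord if cb is not None else (
                _virtual_cb(res) if virtual_cb_for_gly else None)
            if coord is None:
                continue
            entries.append((res.seqnum, res.icode, res.name))
            coords.append(coord)
        per_chain.append((chain.id, entries, np.asarray(coords)))
    if all(len(entries) == 0 for _, entries, _ in per_chain):
        raise ValueError("no C-beta atoms found")

    lo, hi = center - halfwidth, center + halfwidth
    out = []
    for i in range(len(per_chain)):
        cid_a, entries_a, coords_a = per_chain[i]
        for j in range(i + 1, len(per_chain)):
            cid_b, entries_b, coords_b = per_chain[j]
            if not len(coords_a) or not len(coords_b):
                continue
            d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
            for ia, ib in zip(*np.where((d >= lo) & (d <= hi))):
                seq_a, _, name_a = entries_a[ia]
                seq_b, _, name_b = entries_b[ib]
                out.append(DisulfideCandidate(
                    cid_a, seq_a, name_a, cid_b, seq_b, name_b,
                    float(d[ia, ib]), symmetric=(seq_a == seq_b)))
    out.sort(key=lambda c: (c.distance, c.chain_a, c.res_a, c.chain_b, c.res_b))
    return out


def candidates_to_frame(candidates: Sequence[DisulfideCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chainA": c.chain_a, "resA": c.res_a, "nameA": c.name_a,
          "chainB": c.chain_b, "resB": c.res_b, "nameB": c.name_b,
          "distance": round(c.distance, 3), "symmetric": c.symmetric}
         for c in candidates],
        columns=["chainA", "resA", "nameA", "chainB", "resB", "nameB",
                 "distance", "symmetric"])


def interface_report(
    structure: Structure,
    stability: StabilityMap,
    pairs: Sequence[tuple[ResKey, ResKey]],
    interactions: Sequence[Interaction] = (),
) -> pd.DataFrame:
    """Interface residues ranked by summed rigid-contact energy.

    One row per interface residue: the sum of E_rc over its interface
    pairs (most negative first), contact counts by kind from the supplied
    interaction list, and flags marking salt-bridge partners (candidates
    for charge-repulsion mutations) and hydrophobic cluster members
    (candidates for steric disruption).
    """
    if not pairs:
        return pd.DataFrame(columns=["chain", "resnum", "resname", "e_rc_sum",
                                     "n_pairs", "hbond", "salt_bridge",
                                     "hydrophobic", "repulsion_candidate",
                                     "steric_candidate"])
    e_sum: dict[ResKey, float] = {}
    n_pairs: dict[ResKey, int] = {}
    for a, b in pairs:
        e = stability.get(a, b)
        for rk in (a, b):
            n_pairs[rk] = n_pairs.get(rk, 0) + 1
            e_sum[rk] = e_sum.get(rk, 0.0) + (e if e is not None else 0.0)
    counts: dict[ResKey, dict[str, int]] = {}
    for inter in interactions:
        if not inter.interchain:
            continue
        for rk in (inter.a[:3], inter.b[:3]):
            if rk in n_pairs:
                counts.setdefault(rk, {}).setdefault(inter.kind, 0)
                counts[rk][inter.kind] += 1
    resname = {(c.id, r.seqnum, r.icode): r.name for c, r in structure.iter_residues()}
    rows = []
    for rk in sorted(n_pairs, key=lambda k: (e_sum[k], k)):
        kind_counts = counts.get(rk, {})
        rows.append({
            "chain": rk[0], "resnum": rk[1], "resname": resname.get(rk, "?"),
            "e_rc_sum": e_sum[rk], "n_pairs": n_pairs[rk],
            "hbond": kind_counts.get("hbond", 0),
            "salt_bridge": kind_counts.get(KIND_SALT, 0),
            "hydrophobic": kind_counts.get(KIND_HYDROPHOBIC, 0),
            "repulsion_candidate": kind_counts.get(KIND_SALT, 0) > 0,
            "steric_candidate": kind_counts.get(KIND_HYDROPHOBIC, 0) > 0,
        })
    return pd.DataFrame(rows)
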