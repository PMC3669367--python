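"""A simplified full-atom pairwise energy model with score12-shaped terms.

This is deliberately *not* a re-creation of any published force field: the
design protocols in this package only require an energy with the right
shapes — Lennard-Jones attraction/repulsion, a burial penalty for polar
atoms, a statistical charge-pair term, geometric hydrogen bonding, a
rotamer-probability term and per-type reference energies.  Every term is
pairwise-decomposable over residues, which lets the packer precompute
one-body and two-body energy tables.

Terms (weighted sum = total):

* ``fa_atr`` / ``fa_rep`` — 6-12 Lennard-Jones split at the minimum, with
  linear capping of the repulsive branch below 0.6 x contact distance and
  the attractive branch switched to zero at 6 A.
* ``fa_sol`` — per-neighbor burial term: each close heavy-atom contact
  penalizes polar atoms (N/O) and slightly rewards carbon.
* ``fa_pair`` — +-0.5 for like/oppositely charged side-chain pairs whose
  charged groups lie within 6.5 A.
* ``hbond_bb_sc`` / ``hbond_sc`` — geometric donor-acceptor score, ideal
  (-1) at 2.8 A collinear geometry, zero at the 2.4/3.6 A distance bounds.
* ``rotamer`` — -ln(prior probability of the nearest library rotamer).
* ``reference`` — per-residue-type constant; the design dial of the
  energy-guided protocol.

Backbone-backbone hydrogen bonds are excluded entirely: they cannot change
under fixed-backbone design.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import build, chemdata
from .structure_model import ProteinStructure, ResidueSite, Site

ENERGY_TERMS = (
    "fa_atr", "fa_rep", "fa_sol", "fa_pair",
    "hbond_bb_sc", "hbond_sc", "rotamer", "reference",
)

DEFAULT_REFERENCE_ENERGIES = {
    aa: 0.0 for aa in chemdata.CANONICAL_AA
} | {"R": -0.98, "K": -0.65, "D": -0.67, "E": -0.81}


@dataclass
class EnergyModel:
    """Term weights, reference energies and geometric parameters."""

    weights: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in ENERGY_TERMS}
    )
    reference_energies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_ENERGIES)
    )
    hbond_preserve_threshold: float = -0.5
    pair_distance_cutoff: float = 6.5   # A, charged-group centers
    pair_step: float = 0.5              # magnitude of the pair term
    atr_cutoff: float = 6.0             # A, attractive branch switched off
    atr_switch_start: float = 5.0
    rep_cap_fraction: float = 0.6       # linear capping below this x contact
    sol_cutoff: float = 5.5             # A, burial contact switched off
    sol_switch_start: float = 4.0
    sol_polar: float = 0.08             # per-contact penalty for N/O
    sol_carbon: float = -0.008          # per-contact reward for C
    hbond_min: float = 2.4
    hbond_ideal: float = 2.8
    hbond_max: float = 3.6
    lj_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(chemdata.LJ_PARAMS)
    )

    def __post_init__(self):
        missing = chemdata.CANONICAL_AA - set(self.reference_energies)
        if missing:
            raise ValueError(f"reference energies missing for {sorted(missing)}")
        if self.hbond_preserve_threshold >= 0:
            raise ValueError("hbond_preserve_threshold must be negative")

    @classmethod
    def from_config(cls, path: str | Path) -> "EnergyModel":
        """Build a model from a plain ``key value`` config file.

        Keys: term names set weights (``fa_atr 0.8``); ``refweight_<aa3>``
        set reference energies; any other key sets the matching attribute.
        """
        model = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = line.split()
            value = float(value)
            if key in model.weights:
                model.weights[key] = value
            elif key.startswith("refweight_"):
                aa3 = key.removeprefix("refweight_").upper()
                model.reference_energies[chemdata.AA3_TO_1[aa3]] = value
            elif hasattr(model, key):
                setattr(model, key, value)
            else:
                raise ValueError(f"unknown energy config key {key!r}")
        return model


def default_model() -> EnergyModel:
    return EnergyModel()


def reference_energy(aa: str, model: EnergyModel) -> float:
    if aa not in chemdata.CANONICAL_AA:
        raise ValueError(f"non-canonical residue type {aa!r}")
    return model.reference_energies[aa]


# ---------------------------------------------------------------------------
# covalent-bond separation (for excluding 1-2/1-3/1-4 interactions across
# the peptide bond between adjacent residues)

@lru_cache(maxsize=None)
def _graph_distances(aa: str) -> dict[str, dict[str, int]]:
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]
    for name, _elem, refs, *_ in chemdata.SIDECHAIN_TEMPLATES[aa]:
        bonds.append((refs[2], name))
    adj: dict[str, list[str]] = {}
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    dists = {}
    for start in adj:
        seen = {start: 0}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + 1
                    queue.append(nxt)
        dists[start] = seen
    return dists


def _excluded_pairs(res_a: ResidueSite, res_b: ResidueSite) -> set[tuple[str, str]]:
    """Atom-name pairs of covalent separation <= 3 across the a->b peptide bond."""
    da = _graph_distances(res_a.aa)
    db = _graph_distances(res_b.aa)
    out = set()
    for atom_a in res_a.atoms:
        to_c = da.get(atom_a.name, {}).get("C")
        if to_c is None:
            continue
        for atom_b in res_b.atoms:
            from_n = db.get("N", {}).get(atom_b.name)
            if from_n is None:
                continue
            if to_c + 1 + from_n <= 3:
                out.add((atom_a.name, atom_b.name))
    return out


def are_adjacent(structure: ProteinStructure, i: int, j: int) -> bool:
    """Consecutive positions in the residue list on the same chain."""
    if abs(i - j) != 1:
        return False
    return structure.residues[i].chain == structure.residues[j].chain


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass(frozen=True)
class HBond:
    """A detected side-chain hydrogen bond (weighted energy < 0)."""

    donor_site: Site
    donor_atom: str
    acceptor_site: Site
    acceptor_atom: str
    energy: float
    kind: str  # "sc_sc" or "sc_bb"

    @property
    def key(self) -> tuple:
        return (self.donor_site, self.donor_atom, self.acceptor_site, self.acceptor_atom)


def _donors(res: ResidueSite) -> list[tuple[str, str, bool]]:
    out = []
    if res.aa != "P" and res.has_atom("N") and res.has_atom("CA"):
        out.append(("N", "CA", True))
    for atom, base in chemdata.SIDECHAIN_DONORS.get(res.aa, ()):
        if res.has_atom(atom) and res.has_atom(base):
            out.append((atom, base, False))
    return out


def _acceptors(res: ResidueSite) -> list[tuple[str, str, bool]]:
    out = []
    for atom, base in chemdata.BACKBONE_ACCEPTORS:
        if res.has_atom(atom) and res.has_atom(base):
            out.append((atom, base, True))
    for atom, base in chemdata.SIDECHAIN_ACCEPTORS.get(res.aa, ()):
        if res.has_atom(atom) and res.has_atom(base):
            out.append((atom, base, False))
    return out


def _angular_factor(base: np.ndarray, center: np.ndarray, partner: np.ndarray) -> float:
    u = base - center
    v = partner - center
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cos_theta = float(np.dot(u, v) / (nu * nv))
    return max(0.0, -cos_theta) ** 2


def _distance_ramp(d: float, model: EnergyModel) -> float:
    if d <= model.hbond_min or d >= model.hbond_max:
        return 0.0
    if d < model.hbond_ideal:
        return (d - model.hbond_min) / (model.hbond_ideal - model.hbond_min)
    return (model.hbond_max - d) / (model.hbond_max - model.hbond_ideal)


def _hbonds_between(
    res_a: ResidueSite,
    res_b: ResidueSite,
    model: EnergyModel,
    adjacent: bool,
    excluded: set[tuple[str, str]] | None = None,
) -> list[HBond]:
    """Hydrogen bonds between two residues (both directions), excluding the
    backbone-backbone class and covalently close pairs."""
    bonds = []
    for donor_res, acceptor_res, flip in ((res_a, res_b, False), (res_b, res_a, True)):
        for d_atom, d_base, d_bb in _donors(donor_res):
            for a_atom, a_base, a_bb in _acceptors(acceptor_res):
                if d_bb and a_bb:
                    continue
                if excluded is not None:
                    pair = (d_atom, a_atom) if not flip else (a_atom, d_atom)
                    if pair in excluded:
                        continue
                d_pos = donor_res.coord(d_atom)
                a_pos = acceptor_res.coord(a_atom)
                dist = float(np.linalg.norm(d_pos - a_pos))
                ramp = _distance_ramp(dist, model)
                if ramp == 0.0:
                    continue
                raw = (
                    -ramp
                    * _angular_factor(donor_res.coord(d_base), d_pos, a_pos)
                    * _angular_factor(acceptor_res.coord(a_base), a_pos, d_pos)
                )
                kind = "sc_sc" if not (d_bb or a_bb) else "sc_bb"
                weight = model.weights["hbond_sc" if kind == "sc_sc" else "hbond_bb_sc"]
                energy = weight * raw
                if raw < -0.01 and weight != 0.0:
                    bonds.append(
                        HBond(donor_res.site, d_atom, acceptor_res.site, a_atom,
                              energy, kind)
                    )
    return bonds


def detect_sidechain_hbonds(
    structure: ProteinStructure, model: EnergyModel | None = None
) -> list[HBond]:
    """All side-chain-involving hydrogen bonds in the structure."""
    model = model or default_model()
    bonds = []
    residues = structure.residues
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ca_d = np.linalg.norm(residues[i].coord("CA") - residues[j].coord("CA"))
            if ca_d > 25.0:
                continue
            adjacent = are_adjacent(structure, i, j)
            excluded = _excluded_pairs(residues[i], residues[j]) if adjacent else None
            bonds.extend(
                _hbonds_between(residues[i], residues[j], model, adjacent, excluded)
            )
    return bonds


# ---------------------------------------------------------------------------
# pairwise terms

def _lj_tables(model, elems_a, elems_b):
    pa = [model.lj_params.get(e, chemdata.LJ_DEFAULT) for e in elems_a]
    pb = [model.lj_params.get(e, chemdata.LJ_DEFAULT) for e in elems_b]
    ra = np.array([p[0] for p in pa])[:, None]
    rb = np.array([p[0] for p in pb])[None, :]
    ea = np.array([p[1] for p in pa])[:, None]
    eb = np.array([p[1] for p in pb])[None, :]
    return ra + rb, np.sqrt(ea * eb)


def pair_energies(
    res_a: ResidueSite,
    res_b: ResidueSite,
    model: EnergyModel,
    adjacent: bool = False,
) -> dict[str, float]:
    """Unweighted per-term interaction energies between two residues."""
    terms = {t: 0.0 for t in ("fa_atr", "fa_rep", "fa_sol", "fa_pair",
                              "hbond_bb_sc", "hbond_sc")}
    pos_a = np.array([a.position for a in res_a.atoms])
    pos_b = np.array([a.position for a in res_b.atoms])
    elems_a = [a.element for a in res_a.atoms]
    elems_b = [a.element for a in res_b.atoms]
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)

    mask = np.ones_like(d, dtype=bool)
    excluded = _excluded_pairs(res_a, res_b) if adjacent else set()
    if excluded:
        names_a = [a.name for a in res_a.atoms]
        names_b = [a.name for a in res_b.atoms]
        for i, na in enumerate(names_a):
            for j, nb in enumerate(names_b):
                if (na, nb) in excluded:
                    mask[i, j] = False

    rm, eps = _lj_tables(model, elems_a, elems_b)
    cap = model.rep_cap_fraction * rm
    with np.errstate(divide="ignore", over="ignore"):
        ratio6 = (rm / np.maximum(d, 1e-9)) ** 6
        lj = eps * (ratio6**2 - 2.0 * ratio6)

    # repulsive branch: lj - (-eps) for d < rm, linearly capped below 0.6 rm
    inside = (d < rm) & mask
    rep = np.where(inside, lj + eps, 0.0)
    ratio_cap = (1.0 / model.rep_cap_fraction) ** 6
    e_cap = eps * (ratio_cap**2 - 2.0 * ratio_cap) + eps
    slope = eps * 12.0 / rm * (ratio_cap**2 - ratio_cap) / model.rep_cap_fraction
    capped = (d < cap) & mask
    rep = np.where(capped, e_cap + slope * (cap - d), rep)
    terms["fa_rep"] = float(np.sum(rep))

    # attractive branch: -eps inside the minimum, switched LJ outside
    switch = np.clip(
        (model.atr_cutoff - d) / (model.atr_cutoff - model.atr_switch_start), 0.0, 1.0
    )
    atr = np.where(inside, -eps, np.where((d < model.atr_cutoff) & mask, lj * switch, 0.0))
    terms["fa_atr"] = float(np.sum(atr))

    # solvation: per-contact burial, polar penalized, carbon slightly rewarded
    coef = {"N": model.sol_polar, "O": model.sol_polar, "C": model.sol_carbon}
    ca = np.array([coef.get(e, 0.0) for e in elems_a])[:, None]
    cb = np.array([coef.get(e, 0.0) for e in elems_b])[None, :]
    sol_switch = np.clip(
        (model.sol_cutoff - d) / (model.sol_cutoff - model.sol_switch_start), 0.0, 1.0
    )
    terms["fa_sol"] = float(np.sum(np.where(mask, (ca + cb) * sol_switch, 0.0)))

    # statistical charge-pair term
    qa = chemdata.FORMAL_CHARGE.get(res_a.aa)
    qb = chemdata.FORMAL_CHARGE.get(res_b.aa)
    if qa and qb:
        ga = chemdata.CHARGED_GROUP_ATOM[res_a.aa]
        gb = chemdata.CHARGED_GROUP_ATOM[res_b.aa]
        if res_a.has_atom(ga) and res_b.has_atom(gb):
            gd = float(np.linalg.norm(res_a.coord(ga) - res_b.coord(gb)))
            if gd < model.pair_distance_cutoff:
                terms["fa_pair"] = model.pair_step * (1.0 if qa * qb > 0 else -1.0)

    # hydrogen bonds (store raw = unweighted, consistent with other terms)
    for hb in _hbonds_between(res_a, res_b, model, adjacent, excluded or None):
        w = model.weights["hbond_sc" if hb.kind == "sc_sc" else "hbond_bb_sc"]
        key = "hbond_sc" if hb.kind == "sc_sc" else "hbond_bb_sc"
        terms[key] += hb.energy / w if w != 0 else 0.0
    return terms


def pair_energy_total(
    res_a: ResidueSite, res_b: ResidueSite, model: EnergyModel, adjacent: bool = False
) -> float:
    terms = pair_energies(res_a, res_b, model, adjacent)
    return sum(model.weights[k] * v for k, v in terms.items())


def rotamer_energy(res: ResidueSite, model: EnergyModel) -> float:
    """-ln(prior) of the library rotamer nearest to the observed chi angles."""
    chis = build.measure_chis(res.coords_by_name(), res.aa)
    _, prob = build.nearest_rotamer(res.aa, chis)
    return -math.log(prob)


def one_body_energies(res: ResidueSite, model: EnergyModel) -> dict[str, float]:
    return {
        "reference": model.reference_energies[res.aa],
        "rotamer": rotamer_energy(res, model),
    }


# ---------------------------------------------------------------------------
# whole-structure scoring

@dataclass
class ScoreResult:
    total: float
    terms: dict[str, float]                      # weighted per-term totals
    per_residue: dict[Site, dict[str, float]]    # weighted, includes "total"


def score_structure(
    structure: ProteinStructure, model: EnergyModel | None = None
) -> ScoreResult:
    """Total weighted energy with an exact per-residue decomposition
    (pair terms split half/half between the partners)."""
    model = model or default_model()
    residues = structure.residues
    per_res = {
        r.site: {t: 0.0 for t in ENERGY_TERMS} for r in residues
    }
    for res in residues:
        ob = one_body_energies(res, model)
        per_res[res.site]["reference"] = model.weights["reference"] * ob["reference"]
        per_res[res.site]["rotamer"] = model.weights["rotamer"] * ob["rotamer"]

    n = len(residues)
    for i in range(n):
        ca_i = residues[i].coord("CA")
        for j in range(i + 1, n):
            if np.linalg.norm(ca_i - residues[j].coord("CA")) > 22.0:
                continue
            terms = pair_energies(
                residues[i], residues[j], model, are_adjacent(structure, i, j)
            )
            for key, raw in terms.items():
                half = 0.5 * model.weights[key] * raw
                per_res[residues[i].site][key] += half
                per_res[residues[j].site][key] += half

    term_totals = {t: 0.0 for t in ENERGY_TERMS}
    for site, terms in per_res.items():
        terms["total"] = sum(terms[t] for t in ENERGY_TERMS)
        for t in ENERGY_TERMS:
            term_totals[t] += terms[t]
    total = sum(term_totals.values())
    return ScoreResult(total=total, terms=term_totals, per_residue=per_res)
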