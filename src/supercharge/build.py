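"""Side-chain construction from internal-coordinate templates.

Builds heavy-atom side chains on an existing backbone for any canonical
amino-acid type and chi-angle assignment, measures chi angles of existing
side chains, and scores steric clash for rotamer selection.
"""

from __future__ import annotations

import numpy as np

from . import chemdata
from .geometry import angular_difference, dihedral, place_atom


def resolve_torsion(spec, chis: tuple[float, ...]) -> float:
    if isinstance(spec, tuple) and spec and spec[0] == "chi":
        _, k, offset = spec
        return chis[k - 1] + offset
    return float(spec)


def build_sidechain_coords(
    aa: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    chis: tuple[float, ...] = (),
) -> list[tuple[str, str, np.ndarray]]:
    """Heavy side-chain atoms (name, element, position) built on a backbone.

    Glycine returns an empty list; alanine returns just CB.
    """
    if aa not in chemdata.SIDECHAIN_TEMPLATES:
        raise ValueError(f"unknown amino-acid type {aa!r}")
    placed: dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c}
    out = []
    for name, element, refs, bond, angle, torsion in chemdata.SIDECHAIN_TEMPLATES[aa]:
        a, b, cref = (placed[r] for r in refs)
        pos = place_atom(a, b, cref, bond, angle, resolve_torsion(torsion, chis))
        placed[name] = pos
        out.append((name, element, pos))
    return out


def n_chis(aa: str) -> int:
    return len(chemdata.CHI_ATOMS.get(aa, []))


def measure_chis(coords: dict[str, np.ndarray], aa: str) -> tuple[float, ...]:
    """Chi angles of an existing side chain; missing atoms truncate the list."""
    chis = []
    for quad in chemdata.CHI_ATOMS.get(aa, []):
        if any(a not in coords for a in quad):
            break
        chis.append(dihedral(*(coords[a] for a in quad)))
    return tuple(chis)


def nearest_rotamer(aa: str, chis: tuple[float, ...]) -> tuple[int, float]:
    """Index and prior probability of the library rotamer closest in chi space."""
    library = chemdata.ROTAMER_LIBRARY[aa]
    if not chis or not library[0][0]:
        return 0, library[0][1]
    best_i, best_d = 0, float("inf")
    for i, (rot_chis, _) in enumerate(library):
        d = sum(angular_difference(a, b) for a, b in zip(chis, rot_chis))
        if d < best_d:
            best_i, best_d = i, d
    return best_i, library[best_i][1]


def clash_score(
    atoms: list[tuple[str, str, np.ndarray]],
    env_positions: np.ndarray,
    env_elements: list[str],
) -> float:
    """Soft-sphere repulsion of candidate side-chain atoms against environment.

    Sum over pairs of ``(r_min - d)^2`` for d below the contact distance
    ``r_min = r_vdw_i + r_vdw_j``; zero for clash-free placements.
    """
    if len(env_positions) == 0 or not atoms:
        return 0.0
    env_r = np.array(
        [chemdata.LJ_PARAMS.get(e, chemdata.LJ_DEFAULT)[0] for e in env_elements]
    )
    total = 0.0
    for _, element, pos in atoms:
        r_i = chemdata.LJ_PARAMS.get(element, chemdata.LJ_DEFAULT)[0]
        d = np.linalg.norm(env_positions - pos, axis=1)
        overlap = np.maximum(0.0, (env_r + r_i) - d)
        total += float(np.sum(overlap**2))
    return total
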