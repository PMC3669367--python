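"""Surface classification: atom-based AvNAPSA values and residue-based
C-beta neighbor counts.

Two definitions of "surface" coexist in the package, mirroring their use in
the two design protocols:

* **atom-based** — the AvNAPSA value of a residue is the mean, over its
  side-chain heavy atoms, of the number of heavy atoms of *other* residues
  within 10 A.  Low values mean high solvent exposure.  Glycine (no side
  chain) has no AvNAPSA value.
* **residue-based** — the count of other residues whose C-beta lies within
  10 A of this residue's C-beta (C-alpha standing in for glycine).

Both use strict ``<`` comparisons at the distance cutoff and at the surface
classification cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedValueError, UsageError
from .structure_model import ProteinStructure, Site

NEIGHBOR_DISTANCE = 10.0  # A, both metrics

#: default surface cutoffs; "extended" variants admit peripheral/buried sites
DEFAULT_ATOM_CUTOFF = 120.0
DEFAULT_RESIDUE_CUTOFF = 16
EXTENDED_ATOM_CUTOFF = 200.0
EXTENDED_RESIDUE_CUTOFF = 30


def avnapsa_value(structure: ProteinStructure, site: Site) -> float:
    """Average number of neighboring heavy atoms per side-chain heavy atom."""
    res = structure.get(site)
    sidechain = res.sidechain_atoms
    if not sidechain:
        raise UndefinedValueError(
            f"residue {tuple(site)} ({res.aa}) has no side-chain atoms; "
            "AvNAPSA is undefined"
        )
    other = np.array(
        [a.position for r in structure.residues if r.site != res.site for a in r.atoms]
    )
    if len(other) == 0:
        return 0.0
    counts = [
        int(np.sum(np.linalg.norm(other - atom.position, axis=1) < NEIGHBOR_DISTANCE))
        for atom in sidechain
    ]
    return float(np.mean(counts))


def _cbeta_or_surrogate(res) -> np.ndarray:
    if res.has_atom("CB"):
        return res.coord("CB")
    return res.coord("CA")


def residue_neighbor_count(structure: ProteinStructure, site: Site) -> int:
    """Number of other residues with C-beta within 10 A (C-alpha for glycine)."""
    res = structure.get(site)
    center = _cbeta_or_surrogate(res)
    count = 0
    for other in structure.residues:
        if other.site == res.site:
            continue
        if np.linalg.norm(_cbeta_or_surrogate(other) - center) < NEIGHBOR_DISTANCE:
            count += 1
    return count


@dataclass
class SurfaceAnnotation:
    """Per-site exposure metrics plus surface flags under both definitions."""

    avnapsa: dict[Site, float | None]
    neighbor_count: dict[Site, int]
    atom_cutoff: float
    residue_cutoff: float

    def is_surface_atom_based(self, site: Site) -> bool:
        v = self.avnapsa[tuple(site)]
        return v is not None and v < self.atom_cutoff

    def is_surface_residue_based(self, site: Site) -> bool:
        return self.neighbor_count[tuple(site)] < self.residue_cutoff

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site, av in self.avnapsa.items():
            rows.append(
                {
                    "chain": site[0],
                    "number": site[1],
                    "icode": site[2],
                    "avnapsa": np.nan if av is None else av,
                    "neighbor_count": self.neighbor_count[site],
                    "is_surface_atom_based": self.is_surface_atom_based(site),
                    "is_surface_residue_based": self.is_surface_residue_based(site),
                }
            )
        return pd.DataFrame(rows)


def annotate_surface(
    structure: ProteinStructure,
    atom_cutoff: float = DEFAULT_ATOM_CUTOFF,
    residue_cutoff: float = DEFAULT_RESIDUE_CUTOFF,
) -> SurfaceAnnotation:
    """Compute both exposure metrics for every residue in one pass."""
    avnapsa: dict[Site, float | None] = {}
    neighbors: dict[Site, int] = {}
    for res in structure.residues:
        if res.sidechain_atoms:
            avnapsa[res.site] = avnapsa_value(structure, res.site)
        else:
            avnapsa[res.site] = None
        neighbors[res.site] = residue_neighbor_count(structure, res.site)
    return SurfaceAnnotation(avnapsa, neighbors, atom_cutoff, residue_cutoff)


def classify_surface(
    structure: ProteinStructure, mode: str, cutoff: float
) -> set[Site]:
    """Sites classified as surface under ``mode`` with a strict ``< cutoff``.

    Atom-based mode never returns glycine or other side-chain-less residues
    (their AvNAPSA value is undefined).
    """
    if cutoff <= 0:
        raise UsageError("surface cutoff must be positive")
    if mode == "atom_based":
        out = set()
        for res in structure.residues:
            if not res.sidechain_atoms:
                continue
            if avnapsa_value(structure, res.site) < cutoff:
                out.add(res.site)
        return out
    if mode == "residue_based":
        return {
            res.site
            for res in structure.residues
            if residue_neighbor_count(structure, res.site) < cutoff
        }
    raise UsageError(f"unknown surface mode {mode!r}")
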