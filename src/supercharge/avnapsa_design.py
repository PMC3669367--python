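"""The deterministic exposure-ranked supercharging protocol.

Candidate polar/charged residues are sorted by AvNAPSA value from low
(most exposed) to high, then mutated one by one until the requested net
charge is reached, or all candidates below a surface cutoff are mutated.

Mutation tables:

* positive polarity — D→K (+2), E→K (+2), N→K (+1), Q→K (+1)
* negative polarity — R→E (−2), K→E (−2), Q→E (−1), N→D (−1)

Arginine is never introduced, and aspartate is introduced only at native
asparagine sites.  The protocol contains no randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import surface_metrics
from .energy_function import default_model, score_structure
from .errors import UndefinedValueError, UnreachableChargeError, UsageError
from .results import DesignResult, Mutation
from .structure_model import ProteinStructure, Site, mutate_residue, net_formal_charge

logger = logging.getLogger(__name__)

POSITIVE_SWAPS = {"D": ("K", 2), "E": ("K", 2), "N": ("K", 1), "Q": ("K", 1)}
NEGATIVE_SWAPS = {"R": ("E", -2), "K": ("E", -2), "Q": ("E", -1), "N": ("D", -1)}


@dataclass(frozen=True)
class MutationSpec:
    site: Site
    native_aa: str
    new_aa: str
    charge_delta: int
    avnapsa: float


def _swap_table(polarity: str):
    if polarity == "positive":
        return POSITIVE_SWAPS
    if polarity == "negative":
        return NEGATIVE_SWAPS
    raise UsageError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


def candidate_list(
    structure: ProteinStructure,
    polarity: str,
    excluded: set[Site] = frozenset(),
    chain: str | None = None,
) -> list[MutationSpec]:
    """Mutation candidates sorted ascending by AvNAPSA value; ties broken by
    (chain, residue number).  Residues already carrying the desired charge are
    never candidates."""
    swaps = _swap_table(polarity)
    excluded = {tuple(s) for s in excluded}
    specs = []
    for res in structure.residues:
        if chain is not None and res.chain != chain:
            continue
        if res.aa not in swaps or res.site in excluded:
            continue
        try:
            value = surface_metrics.avnapsa_value(structure, res.site)
        except UndefinedValueError:
            logger.warning("skipping %s: no side-chain atoms for AvNAPSA", res.site)
            continue
        new_aa, delta = swaps[res.aa]
        specs.append(MutationSpec(res.site, res.aa, new_aa, delta, value))
    specs.sort(key=lambda s: (s.avnapsa, s.site[0], s.site[1]))
    return specs


def choose_mutations_to_target(
    candidates: list[MutationSpec], current_charge: int, target: int
) -> list[MutationSpec]:
    """Shortest prefix of the sorted candidates whose cumulative charge delta
    reaches (possibly overshooting by 1) the target."""
    if target == current_charge:
        raise UsageError("target net charge equals the current net charge")
    going_up = target > current_charge
    if candidates:
        delta_sign = candidates[0].charge_delta > 0
        if delta_sign != going_up:
            raise UsageError(
                "candidate polarity is inconsistent with the requested target"
            )
    chosen = []
    charge = current_charge
    for spec in candidates:
        chosen.append(spec)
        charge += spec.charge_delta
        if (going_up and charge >= target) or (not going_up and charge <= target):
            return chosen
    raise UnreachableChargeError(
        f"candidates exhausted at net charge {charge} before target {target}",
        best_achievable=charge,
    )


def choose_mutations_by_cutoff(
    candidates: list[MutationSpec], cutoff: float
) -> list[MutationSpec]:
    """All candidates strictly below the AvNAPSA surface cutoff."""
    if cutoff <= 0:
        raise UsageError("AvNAPSA cutoff must be positive")
    return [s for s in candidates if s.avnapsa < cutoff]


def apply_avnapsa_design(
    structure: ProteinStructure,
    polarity: str,
    target_charge: int | None = None,
    avnapsa_cutoff: float | None = None,
    resfile: dict | None = None,
    chain: str | None = None,
) -> DesignResult:
    """Run the full protocol: rank, select, mutate, report.

    Exactly one of ``target_charge`` / ``avnapsa_cutoff`` must be given.
    A resfile (as parsed by :func:`supercharge.rotamer_packer.read_resfile`)
    restricts which positions may mutate.
    """
    if (target_charge is None) == (avnapsa_cutoff is None):
        raise UsageError("give exactly one of target_charge or avnapsa_cutoff")
    if chain is None:
        chain = structure.chains()[0]

    excluded: set[Site] = set()
    if resfile:
        swaps = _swap_table(polarity)
        for res in structure.residues:
            entry = resfile.get((res.chain, res.number))
            if entry is None:
                continue
            if entry[0] == "NATRO":
                excluded.add(res.site)
            elif entry[0] == "PIKAA" and res.aa in swaps:
                if swaps[res.aa][0] not in entry[1]:
                    excluded.add(res.site)

    candidates = candidate_list(structure, polarity, excluded=excluded, chain=chain)
    before = net_formal_charge(structure)
    if target_charge is not None:
        chosen = choose_mutations_to_target(candidates, before, target_charge)
    else:
        chosen = choose_mutations_by_cutoff(candidates, avnapsa_cutoff)

    designed = structure
    for spec in chosen:
        designed = mutate_residue(designed, spec.site, spec.new_aa)
    after = net_formal_charge(designed)

    model = default_model()
    native_scores = score_structure(structure, model).per_residue
    designed_scores = score_structure(designed, model).per_residue
    mutations = [
        Mutation(
            site=spec.site,
            native_aa=spec.native_aa,
            new_aa=spec.new_aa,
            charge_delta=spec.charge_delta,
            avnapsa=spec.avnapsa,
            energy_delta=designed_scores[spec.site]["total"]
            - native_scores[spec.site]["total"],
        )
        for spec in chosen
    ]
    return DesignResult(
        structure=designed,
        mutations=mutations,
        net_charge_before=before,
        net_charge_after=after,
        protocol="avnapsa",
        polarity=polarity,
        surface_sites=[s.site for s in candidates],
        energy_table=_energy_table(structure, designed, native_scores, designed_scores),
        max_avnapsa_of_mutations=max((m.avnapsa for m in mutations), default=0.0),
    )


def _energy_table(native, designed, native_scores, designed_scores):
    import pandas as pd

    rows = []
    for res_n, res_d in zip(native.residues, designed.residues):
        row = {
            "chain": res_n.chain,
            "number": res_n.number,
            "native_aa": res_n.aa,
            "designed_aa": res_d.aa,
            "native_total": native_scores[res_n.site]["total"],
            "designed_total": designed_scores[res_d.site]["total"],
        }
        row["delta_total"] = row["designed_total"] - row["native_total"]
        rows.append(row)
    return pd.DataFrame(rows)
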