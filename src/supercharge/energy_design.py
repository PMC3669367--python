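"""Energy-guided supercharging: packing under adjusted reference energies.

Net charge is controlled through the reference energies of the included
charged residue types.  Two entry points:

* :func:`supercharge_with_refweights` — pack once at given reference
  energies; more negative values bias the packer toward more charged
  mutations.
* :func:`supercharge_to_target` — ramp the reference energies downward in
  fixed steps, re-packing from the native structure each iteration, until
  the target net charge is reached or the iteration cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chemdata, surface_metrics
from .energy_function import EnergyModel, default_model, score_structure
from .errors import UnreachableChargeError, UsageError
from .results import DesignResult, Mutation
from .rotamer_packer import (
    AnnealingSchedule,
    DesignTask,
    Packer,
    build_design_task,
    read_resfile,
)
from .structure_model import ProteinStructure, net_formal_charge

POSITIVE_TYPES = {"R", "K"}
NEGATIVE_TYPES = {"D", "E"}


@dataclass(frozen=True)
class DesignOptions:
    """Options of the energy-guided protocol (defaults mirror the standard
    configuration: AvNAPSA atom-based surface at 120, all preservation rules
    on, no charged type included until the user opts in)."""

    surface_mode: str = "atom_based"
    surface_atom_cutoff: float = surface_metrics.DEFAULT_ATOM_CUTOFF
    surface_residue_cutoff: float = surface_metrics.DEFAULT_RESIDUE_CUTOFF
    include_arg: bool = False
    include_lys: bool = False
    include_asp: bool = False
    include_glu: bool = False
    preserve_glyprocys: bool = True
    preserve_hbonded_sidechains: bool = True
    preserve_correct_charge: bool = True
    pre_pack: bool = False
    nstruct: int = 1
    design_chain: str | None = None
    resfile_path: str | None = None
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    ramp_step: float = 0.05
    ramp_cap: int = 60

    def included_types(self) -> set[str]:
        types = set()
        if self.include_arg:
            types.add("R")
        if self.include_lys:
            types.add("K")
        if self.include_asp:
            types.add("D")
        if self.include_glu:
            types.add("E")
        return types

    def polarity(self) -> str:
        types = self.included_types()
        if not types:
            raise UsageError(
                "energy mode requires at least one of include_arg/include_lys/"
                "include_asp/include_glu"
            )
        if types <= POSITIVE_TYPES:
            return "positive"
        if types <= NEGATIVE_TYPES:
            return "negative"
        raise UsageError(f"included charged types mix signs: {sorted(types)}")


def _surface_sites(structure, options: DesignOptions):
    cutoff = (
        options.surface_atom_cutoff
        if options.surface_mode == "atom_based"
        else options.surface_residue_cutoff
    )
    surface = surface_metrics.classify_surface(structure, options.surface_mode, cutoff)
    chain = options.design_chain or structure.chains()[0]
    return {s for s in surface if s[0] == chain}


def _make_task(structure, polarity, options, model) -> DesignTask:
    resfile = read_resfile(options.resfile_path) if options.resfile_path else None
    return build_design_task(
        structure,
        _surface_sites(structure, options),
        polarity,
        model,
        include_types=options.included_types(),
        preserve_glyprocys=options.preserve_glyprocys,
        preserve_hbonded_sidechains=options.preserve_hbonded_sidechains,
        preserve_correct_charge=options.preserve_correct_charge,
        resfile=resfile,
    )


def _diff_mutations(native, designed, per_res_native, per_res_designed):
    mutations = []
    for res_n, res_d in zip(native.residues, designed.residues):
        if res_n.aa != res_d.aa:
            delta = (
                chemdata.FORMAL_CHARGE.get(res_d.aa, 0)
                - chemdata.FORMAL_CHARGE.get(res_n.aa, 0)
            )
            mutations.append(
                Mutation(
                    site=res_n.site,
                    native_aa=res_n.aa,
                    new_aa=res_d.aa,
                    charge_delta=delta,
                    energy_delta=per_res_designed[res_d.site]["total"]
                    - per_res_native[res_n.site]["total"],
                )
            )
    return mutations


def _energy_table(native, designed, per_res_native, per_res_designed):
    rows = []
    for res_n, res_d in zip(native.residues, designed.residues):
        rows.append(
            {
                "chain": res_n.chain,
                "number": res_n.number,
                "native_aa": res_n.aa,
                "designed_aa": res_d.aa,
                "native_total": per_res_native[res_n.site]["total"],
                "designed_total": per_res_designed[res_d.site]["total"],
                "delta_total": per_res_designed[res_d.site]["total"]
                - per_res_native[res_n.site]["total"],
            }
        )
    return pd.DataFrame(rows)


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _pre_pack(packer: Packer, seed: int) -> ProteinStructure:
    """Native repack: same task sites, but only the native type allowed."""
    task = packer.task
    repack_task = DesignTask(
        designable={
            site: (packer.structure.get(site).aa,) for site in task.designable
        },
        fixed=dict(task.fixed),
    )
    repacker = Packer(packer.structure, repack_task, packer.model)
    repacked, _, _ = repacker.pack(seed=seed)
    return repacked


def supercharge_with_refweights(
    structure: ProteinStructure,
    polarity: str | None = None,
    refweights: dict[str, float] | None = None,
    options: DesignOptions = DesignOptions(),
    model: EnergyModel | None = None,
    seed: int = 0,
    _packer: Packer | None = None,
) -> DesignResult:
    """Pack the surface with the given reference energies for the included
    charged types; every other option at its configured value.

    ``refweights`` maps one-letter charged types (subset of the included
    types) to reference energies; omitted types use the model defaults.
    """
    model = model or default_model()
    inferred = options.polarity()
    if polarity is None:
        polarity = inferred
    elif polarity != inferred:
        raise UsageError(
            f"polarity {polarity!r} inconsistent with included types ({inferred})"
        )
    refweights = dict(refweights or {})
    extra = set(refweights) - options.included_types()
    if extra:
        raise UsageError(f"refweights given for non-included types: {sorted(extra)}")

    native = structure
    packer = _packer
    if packer is None:
        task = _make_task(structure, polarity, options, model)
        packer = Packer(structure, task, model)

    warnings = []
    if not packer.task.designable:
        warnings.append("no designable surface sites; returning the input unchanged")

    seeds = _derive_seeds(seed, max(1, options.nstruct) + 1)
    base = packer.structure
    if options.pre_pack:
        base = _pre_pack(packer, seeds[-1])
        packer = Packer(base, packer.task, model)

    best = None
    used_seeds = seeds[: max(1, options.nstruct)]
    for s in used_seeds:
        designed, energy, _ = packer.pack(
            seed=s, schedule=options.schedule, refweight_override=refweights
        )
        if best is None or energy < best[1]:
            best = (designed, energy)
    designed = best[0]

    default = default_model()
    per_res_native = score_structure(base, default).per_residue
    per_res_designed = score_structure(designed, default).per_residue
    mutations = _diff_mutations(base, designed, per_res_native, per_res_designed)
    final_refs = {
        aa: refweights.get(aa, model.reference_energies[aa])
        for aa in sorted(options.included_types())
    }
    return DesignResult(
        structure=designed,
        mutations=mutations,
        net_charge_before=net_formal_charge(native),
        net_charge_after=net_formal_charge(designed),
        protocol="energy",
        polarity=polarity,
        surface_sites=sorted(
            list(packer.task.designable)
            + [s for s, r in packer.task.fixed.items() if r != "not_surface"],
            key=lambda s: (s[0], s[1]),
        ),
        energy_table=_energy_table(base, designed, per_res_native, per_res_designed),
        final_reference_energies=final_refs,
        seeds=tuple(used_seeds),
        warnings=warnings,
    )


def supercharge_to_target(
    structure: ProteinStructure,
    polarity: str | None = None,
    target_charge: int = 0,
    options: DesignOptions = DesignOptions(),
    model: EnergyModel | None = None,
    seed: int = 0,
) -> DesignResult:
    """Ramp the included types' reference energies down by ``options.ramp_step``
    per iteration (both types move together, preserving their default offset),
    re-packing from the native structure, until the net charge reaches the
    target or ``options.ramp_cap`` iterations pass.

    The returned result records the final reference energies and, in
    ``ramp_history``, the (refweights, achieved charge) sequence.
    """
    model = model or default_model()
    inferred = options.polarity()
    if polarity is None:
        polarity = inferred
    elif polarity != inferred:
        raise UsageError(
            f"polarity {polarity!r} inconsistent with included types ({inferred})"
        )
    current = net_formal_charge(structure)
    if polarity == "positive" and target_charge <= current:
        raise UsageError(
            f"positive target {target_charge} must exceed current charge {current}"
        )
    if polarity == "negative" and target_charge >= current:
        raise UsageError(
            f"negative target {target_charge} must be below current charge {current}"
        )

    task = _make_task(structure, polarity, options, model)
    packer = Packer(structure, task, model)
    included = sorted(options.included_types())
    seeds = _derive_seeds(seed, options.ramp_cap + 1)

    history = []
    best_result = None
    for k in range(options.ramp_cap + 1):
        refweights = {
            aa: model.reference_energies[aa] - k * options.ramp_step for aa in included
        }
        result = supercharge_with_refweights(
            structure,
            polarity,
            refweights,
            options=replace(options, pre_pack=False, nstruct=1),
            model=model,
            seed=seeds[k],
            _packer=packer,
        )
        achieved = result.net_charge_after
        history.append((dict(refweights), achieved))
        if best_result is None or abs(achieved - current) > abs(
            best_result.net_charge_after - current
        ):
            best_result = result
        reached = (
            achieved >= target_charge if polarity == "positive" else achieved <= target_charge
        )
        if reached:
            result.final_reference_energies = refweights
            result.ramp_history = history
            result.seeds = (seed,) + result.seeds
            return result
    raise UnreachableChargeError(
        f"iteration cap {options.ramp_cap} reached at net charge "
        f"{best_result.net_charge_after} before target {target_charge}",
        best_achievable=best_result.net_charge_after,
        final_refweights=history[-1][0],
    )
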