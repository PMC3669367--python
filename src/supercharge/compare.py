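"""Protocol-comparison statistics: mutation overlap, hydrogen-bond
bookkeeping and mutations-per-charge efficiency.

The two protocols choose notably different mutation sets; this module
quantifies that divergence for a pair of designs derived from the same
native structure.  Energy deltas are always computed with the *default*
reference energies, regardless of the reference energies any design was
generated with.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy_function import EnergyModel, default_model, detect_sidechain_hbonds, score_structure
from .errors import UndefinedValueError, ValidationError
from .results import DesignResult
from .structure_model import ProteinStructure

#: hydrogen bonds weaker than this are ignored entirely (numerical dust)
WEAK_FLOOR = -0.1


def mutations_per_charge(result: DesignResult) -> float:
    """Number of mutations per unit of net-charge change."""
    delta = abs(result.net_charge_after - result.net_charge_before)
    if delta == 0:
        raise UndefinedValueError("design changed the net charge by zero")
    return len(result.mutations) / delta


@dataclass
class HBondDelta:
    """Hydrogen bonds lost/gained by one design relative to the native."""

    lost_strong: int
    lost_weak: int
    gained_strong: int
    gained_weak: int


@dataclass
class DesignComparison:
    shared_positions: set
    shared_position_fraction: float
    shared_position_and_type_fraction: float
    mutations_a: int
    mutations_b: int
    mutations_per_charge_a: float | None
    mutations_per_charge_b: float | None
    hbonds_a: HBondDelta
    hbonds_b: HBondDelta
    energy_deltas_a: dict[str, float]
    energy_deltas_b: dict[str, float]


def _classify(bonds, threshold: float):
    """Split bonds into strong (< threshold) and weak ([threshold, WEAK_FLOOR))."""
    strong = {b.key for b in bonds if b.energy < threshold}
    weak = {b.key for b in bonds if threshold <= b.energy < WEAK_FLOOR}
    return strong, weak


def _hbond_delta(native_bonds, design: DesignResult, model: EnergyModel) -> HBondDelta:
    design_bonds = detect_sidechain_hbonds(design.structure, model)
    t = model.hbond_preserve_threshold
    nat_strong, nat_weak = _classify(native_bonds, t)
    des_strong, des_weak = _classify(design_bonds, t)
    des_all = des_strong | des_weak
    nat_all = nat_strong | nat_weak
    return HBondDelta(
        lost_strong=len(nat_strong - des_all),
        lost_weak=len(nat_weak - des_all),
        gained_strong=len(des_strong - nat_all),
        gained_weak=len(des_weak - nat_all),
    )


def _check_derivation(native: ProteinStructure, design: DesignResult) -> None:
    if len(design.structure) != len(native):
        raise ValidationError("design does not derive from the given native")
    mutated = design.mutated_sites()
    for res_n, res_d in zip(native.residues, design.structure.residues):
        if res_n.site != res_d.site:
            raise ValidationError("design does not derive from the given native")
        if (res_n.aa != res_d.aa) != (res_n.site in mutated):
            raise ValidationError(
                "mutation list inconsistent with the native/design sequence diff"
            )


def _safe_mpc(design: DesignResult) -> float | None:
    try:
        return mutations_per_charge(design)
    except UndefinedValueError:
        return None


def compare_designs(
    native: ProteinStructure,
    design_a: DesignResult,
    design_b: DesignResult,
    model: EnergyModel | None = None,
) -> DesignComparison:
    """Overlap and energetic comparison of two designs of the same native.

    Shared fractions use the union of mutated positions as denominator; two
    designs with no mutations at all compare as fully shared.
    """
    model = model or default_model()
    _check_derivation(native, design_a)
    _check_derivation(native, design_b)

    sites_a, sites_b = design_a.mutated_sites(), design_b.mutated_sites()
    union = sites_a | sites_b
    shared = sites_a & sites_b
    if union:
        type_a = {(m.site, m.new_aa) for m in design_a.mutations}
        type_b = {(m.site, m.new_aa) for m in design_b.mutations}
        shared_fraction = len(shared) / len(union)
        shared_type_fraction = len(type_a & type_b) / len(union)
    else:
        shared_fraction = shared_type_fraction = 1.0

    native_bonds = detect_sidechain_hbonds(native, model)
    native_terms = score_structure(native, model).terms
    terms_a = score_structure(design_a.structure, model).terms
    terms_b = score_structure(design_b.structure, model).terms

    return DesignComparison(
        shared_positions=shared,
        shared_position_fraction=shared_fraction,
        shared_position_and_type_fraction=shared_type_fraction,
        mutations_a=len(design_a.mutations),
        mutations_b=len(design_b.mutations),
        mutations_per_charge_a=_safe_mpc(design_a),
        mutations_per_charge_b=_safe_mpc(design_b),
        hbonds_a=_hbond_delta(native_bonds, design_a, model),
        hbonds_b=_hbond_delta(native_bonds, design_b, model),
        energy_deltas_a={k: terms_a[k] - native_terms[k] for k in native_terms},
        energy_deltas_b={k: terms_b[k] - native_terms[k] for k in native_terms},
    )


def comparison_report(comparison: DesignComparison) -> str:
    """Human-readable text block summarizing a comparison."""
    lines = [
        "protocol comparison",
        "===================",
        f"mutations (a / b): {comparison.mutations_a} / {comparison.mutations_b}",
        f"shared positions: {len(comparison.shared_positions)}",
        f"shared position fraction: {comparison.shared_position_fraction:.3f}",
        "shared position+type fraction: "
        f"{comparison.shared_position_and_type_fraction:.3f}",
        f"mutations per charge (a / b): {comparison.mutations_per_charge_a} / "
        f"{comparison.mutations_per_charge_b}",
        f"hbonds lost strong/weak (a): {comparison.hbonds_a.lost_strong}/"
        f"{comparison.hbonds_a.lost_weak}  gained: "
        f"{comparison.hbonds_a.gained_strong}/{comparison.hbonds_a.gained_weak}",
        f"hbonds lost strong/weak (b): {comparison.hbonds_b.lost_strong}/"
        f"{comparison.hbonds_b.lost_weak}  gained: "
        f"{comparison.hbonds_b.gained_strong}/{comparison.hbonds_b.gained_weak}",
    ]
    return "\n".join(lines)
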