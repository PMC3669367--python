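"""Energy model: printed defaults, decomposition oracle, term properties,
hydrogen-bond geometry."""

import math

import numpy as np
import pytest

from supercharge import (
    EnergyModel,
    default_model,
    detect_sidechain_hbonds,
    mutate_residue,
    reference_energy,
    score_structure,
)
from supercharge.chemdata import CANONICAL_AA, FORMAL_CHARGE, LJ_DEFAULT
from supercharge.energy_function import (
    _distance_ramp,
    _excluded_pairs,
    are_adjacent,
    one_body_energies,
    pair_energies,
)
from supercharge.fixtures import FixtureSpec, make_structure
from conftest import rigid_transform


def test_default_reference_energies(model):
    assert reference_energy("R", model) == -0.98
    assert reference_energy("K", model) == -0.65
    assert reference_energy("D", model) == -0.67
    assert reference_energy("E", model) == -0.81
    for aa in CANONICAL_AA - {"R", "K", "D", "E"}:
        assert reference_energy(aa, model) == 0.0
    assert model.hbond_preserve_threshold == -0.5


def test_model_requires_all_reference_energies():
    refs = dict.fromkeys(CANONICAL_AA, 0.0)
    refs.pop("W")
    with pytest.raises(ValueError):
        EnergyModel(reference_energies=refs)


def test_isolated_residue_scores_reference_plus_rotamer(model):
    lone = make_structure(FixtureSpec("K", "extended"))
    result = score_structure(lone, model)
    ob = one_body_energies(lone.residues[0], model)
    assert result.total == pytest.approx(ob["reference"] + ob["rotamer"])


def test_distant_residues_only_contribute_one_body_terms(model):
    """Two residues far beyond every cutoff: all pairwise terms vanish."""
    pair = make_structure(FixtureSpec("KE", "extended"))
    a, b = pair.residues
    from dataclasses import replace

    far = tuple(
        replace(atom, position=atom.position + np.array([80.0, 0, 0]))
        for atom in b.atoms
    )
    moved = pair.with_residue(b.site, replace(b, atoms=far))
    result = score_structure(moved, model)
    expected = sum(
        sum(one_body_energies(r, model).values()) for r in moved.residues
    )
    assert result.total == pytest.approx(expected)


def naive_pair_total(structure, model):
    """Independent double-loop recomputation of all pairwise terms, scalar
    math only, no prefilters."""
    total = {k: 0.0 for k in ("fa_atr", "fa_rep", "fa_sol", "fa_pair",
                              "hbond_bb_sc", "hbond_sc")}
    residues = structure.residues
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ra, rb = residues[i], residues[j]
            adjacent = are_adjacent(structure, i, j)
            excluded = _excluded_pairs(ra, rb) if adjacent else set()
            for atom_a in ra.atoms:
                for atom_b in rb.atoms:
                    if (atom_a.name, atom_b.name) in excluded:
                        continue
                    d = float(np.linalg.norm(atom_a.position - atom_b.position))
                    pa = model.lj_params.get(atom_a.element, LJ_DEFAULT)
                    pb = model.lj_params.get(atom_b.element, LJ_DEFAULT)
                    rm, eps = pa[0] + pb[0], math.sqrt(pa[1] * pb[1])
                    lj = eps * ((rm / d) ** 12 - 2 * (rm / d) ** 6)
                    cap = model.rep_cap_fraction * rm
                    if d < cap:
                        ratio = (1 / model.rep_cap_fraction) ** 6
                        e_cap = eps * (ratio**2 - 2 * ratio) + eps
                        slope = eps * 12 / rm * (ratio**2 - ratio) / model.rep_cap_fraction
                        total["fa_rep"] += e_cap + slope * (cap - d)
                        total["fa_atr"] += -eps
                    elif d < rm:
                        total["fa_rep"] += lj + eps
                        total["fa_atr"] += -eps
                    elif d < model.atr_cutoff:
                        s = min(1.0, (model.atr_cutoff - d) /
                                (model.atr_cutoff - model.atr_switch_start))
                        total["fa_atr"] += lj * s
                    if d < model.sol_cutoff:
                        s = min(1.0, (model.sol_cutoff - d) /
                                (model.sol_cutoff - model.sol_switch_start))
                        coef = {"N": model.sol_polar, "O": model.sol_polar,
                                "C": model.sol_carbon}
                        total["fa_sol"] += (coef.get(atom_a.element, 0.0)
                                            + coef.get(atom_b.element, 0.0)) * s
            qa, qb = FORMAL_CHARGE.get(ra.aa), FORMAL_CHARGE.get(rb.aa)
            if qa and qb:
                from supercharge.chemdata import CHARGED_GROUP_ATOM

                ga, gb = CHARGED_GROUP_ATOM[ra.aa], CHARGED_GROUP_ATOM[rb.aa]
                if ra.has_atom(ga) and rb.has_atom(gb):
                    gd = float(np.linalg.norm(ra.coord(ga) - rb.coord(gb)))
                    if gd < model.pair_distance_cutoff:
                        total["fa_pair"] += model.pair_step * (
                            1.0 if qa * qb > 0 else -1.0
                        )
    for hb in detect_sidechain_hbonds(structure, model):
        key = "hbond_sc" if hb.kind == "sc_sc" else "hbond_bb_sc"
        total[key] += hb.energy
    return total


@pytest.mark.parametrize("fixture_name", ["helix16", "strand12"])
def test_decomposition_matches_naive_double_loop(fixture_name, request, model):
    structure = request.getfixturevalue(fixture_name)
    result = score_structure(structure, model)
    naive = naive_pair_total(structure, model)
    for term, value in naive.items():
        assert result.terms[term] == pytest.approx(value, abs=1e-8), term
    # per-residue decomposition sums to the total
    assert sum(v["total"] for v in result.per_residue.values()) == pytest.approx(
        result.total, rel=1e-6
    )


def test_zeroing_a_weight_removes_exactly_that_term(helix16, model):
    base = score_structure(helix16, model)
    for term in ("fa_atr", "fa_sol", "fa_pair", "reference"):
        weights = dict(model.weights)
        weights[term] = 0.0
        zeroed = score_structure(helix16, EnergyModel(weights=weights))
        assert zeroed.terms[term] == 0.0
        assert zeroed.total == pytest.approx(base.total - base.terms[term])
        for other in base.terms:
            if other != term:
                assert zeroed.terms[other] == pytest.approx(base.terms[other])


def test_pair_term_sign_convention(model):
    """Opposite charges attract (<= 0), like charges repel (>= 0)."""
    opposite = make_structure(FixtureSpec("KAE", "extended"))
    like = make_structure(FixtureSpec("KAK", "extended"))
    t_opp = pair_energies(opposite.residues[0], opposite.residues[2], model)
    t_like = pair_energies(like.residues[0], like.residues[2], model)
    assert t_opp["fa_pair"] <= 0.0
    assert t_like["fa_pair"] >= 0.0


def test_reference_energy_shift_is_linear_in_count(helix16, model):
    """Lowering a charged type's reference by delta lowers the total by
    count x delta, conformation fixed."""
    n_lys = helix16.sequence().count("K")
    assert n_lys > 0
    shifted_model = default_model()
    shifted_model.reference_energies["K"] -= 0.25
    base = score_structure(helix16, model).total
    shifted = score_structure(helix16, shifted_model).total
    assert shifted == pytest.approx(base - 0.25 * n_lys)


def test_rigid_body_invariance_of_score(helix16, model):
    rotation, translation = rigid_transform(7)
    moved = helix16.transformed(rotation, translation)
    base = score_structure(helix16, model)
    after = score_structure(moved, model)
    assert after.total == pytest.approx(base.total, abs=1e-6)
    for term in base.terms:
        assert after.terms[term] == pytest.approx(base.terms[term], abs=1e-6)


def test_hbond_distance_ramp_is_continuous(model):
    """No jumps at the 2.4/3.6 A bounds or the 2.8 A peak."""
    grid = np.linspace(2.3, 3.7, 2000)
    values = np.array([_distance_ramp(float(d), model) for d in grid])
    assert np.max(np.abs(np.diff(values))) < 5e-3
    assert _distance_ramp(2.8, model) == pytest.approx(1.0)
    assert _distance_ramp(2.4, model) == 0.0
    assert _distance_ramp(3.6, model) == 0.0
    assert _distance_ramp(5.0, model) == 0.0


def test_crafted_loop_hbond_detected_and_removed_by_mutation(loop_motif, model):
    bonds = detect_sidechain_hbonds(loop_motif, model)
    strong = [b for b in bonds if b.energy <= -0.5]
    assert len(strong) == 1
    hb = strong[0]
    assert hb.acceptor_site == ("A", 3, "")
    assert hb.kind == "sc_bb"
    # mutating the aspartate away removes the acceptor and the bond
    mutated = mutate_residue(loop_motif, ("A", 3, ""), "K")
    assert all(
        b.acceptor_site != ("A", 3, "") for b in detect_sidechain_hbonds(mutated, model)
    )


def test_nq_motif_dual_role(nq_motif, model):
    """The asparagine is donor in one bond and acceptor in another."""
    bonds = detect_sidechain_hbonds(nq_motif, model)
    site = ("A", 3, "")
    donor_bonds = [b for b in bonds if b.donor_site == site and b.donor_atom == "ND2"]
    acceptor_bonds = [
        b for b in bonds if b.acceptor_site == site and b.acceptor_atom == "OD1"
    ]
    assert len(donor_bonds) == 1 and len(acceptor_bonds) == 1
    strong = [b for b in bonds if b.energy < -0.5]
    assert len(strong) == 1


def test_far_donor_acceptor_has_no_bond(model):
    structure = make_structure(FixtureSpec("SAAAS", "extended"))
    # serine hydroxyls are ~13 A apart in the extended chain: no bond between them
    assert all(
        not (b.donor_site == ("A", 1, "") and b.acceptor_site == ("A", 5, ""))
        for b in detect_sidechain_hbonds(structure, model)
    )


def test_config_file_round_trip(tmp_path):
    cfg = tmp_path / "energy.cfg"
    cfg.write_text(
        "fa_rep 0.55\nrefweight_arg -1.34\nrefweight_lys -1.01\n"
        "hbond_preserve_threshold -0.4\n# comment\n"
    )
    model = EnergyModel.from_config(cfg)
    assert model.weights["fa_rep"] == 0.55
    assert model.reference_energies["R"] == -1.34
    assert model.reference_energies["K"] == -1.01
    assert model.hbond_preserve_threshold == -0.4
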