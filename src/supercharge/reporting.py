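"""Deliverable outputs of a design run: log file, resfile, named PDB and
the PyMOL selection string.

The log is line-oriented (``key: value`` plus fixed section headers) so it
can be parsed without a bespoke grammar.
"""

from __future__ import annotations

from pathlib import Path

from .results import DesignResult
from .structure_model import write_pdb


def pymol_selection(result: DesignResult) -> str:
    """``select mutations, chain A and resi 7+12`` — one clause per chain,
    residue numbers ascending, clauses joined with ``or``."""
    by_chain: dict[str, list[int]] = {}
    for m in result.mutations:
        by_chain.setdefault(m.site[0], []).append(m.site[1])
    if not by_chain:
        return "select mutations, none"
    clauses = [
        f"chain {chain} and resi " + "+".join(str(n) for n in sorted(numbers))
        for chain, numbers in sorted(by_chain.items())
    ]
    return "select mutations, " + " or ".join(clauses)


def _signed(value: float | int, decimals: int = 0) -> str:
    return f"{value:+.{decimals}f}"


def output_name(result: DesignResult, input_name: str) -> str:
    """Self-documenting output PDB name.

    Energy mode embeds the final reference energies and net charge; AvNAPSA
    mode embeds the net charge and the largest AvNAPSA value among mutated
    residues (integer-rounded).  Signs are always explicit.
    """
    charge = _signed(result.net_charge_after)
    if result.protocol == "energy":
        refs = result.final_reference_energies or {}
        weights = "_".join(
            f"{refs[aa]:+.2f}" for aa in "RKDE" if aa in refs
        )
        return f"{input_name}_R{weights}_netq{charge}.pdb"
    avn = int(round(result.max_avnapsa_of_mutations or 0.0))
    return f"{input_name}_A_netq{charge}_avn{avn}.pdb"


def _charged_counts(result: DesignResult) -> dict[str, int]:
    seq = result.structure.sequence()
    return {aa: seq.count(aa) for aa in "RKDE"}


def write_log(
    result: DesignResult,
    path: str | Path,
    invocation: str = "",
    compare_residue_energies_all: bool = False,
    compare_residue_energies_mut: bool = True,
) -> None:
    """Plain-text run log: invocation, surface sites, charged-residue counts,
    net charge, mutation list, PyMOL selection, optional energy table."""
    lines = [f"invocation: {invocation}", "", "[surface]"]
    lines += [
        f"surface_site: {chain} {number}{icode}"
        for chain, number, icode in result.surface_sites
    ]
    lines += ["", "[charge]"]
    for aa, count in _charged_counts(result).items():
        lines.append(f"count_{aa}: {count}")
    lines.append(f"net_charge_before: {_signed(result.net_charge_before)}")
    lines.append(f"net_charge: {_signed(result.net_charge_after)}")
    lines += ["", "[mutations]"]
    for m in result.mutations:
        extra = f" avnapsa={m.avnapsa:.1f}" if m.avnapsa is not None else ""
        lines.append(
            f"mutation: {m.native_aa} {m.site[0]} {m.site[1]}{m.site[2]} "
            f"{m.new_aa}{extra}"
        )
    lines += ["", "[pymol]", pymol_selection(result)]
    if (compare_residue_energies_all or compare_residue_energies_mut) and (
        result.energy_table is not None
    ):
        table = result.energy_table
        if compare_residue_energies_mut and not compare_residue_energies_all:
            mutated = {(s[0], s[1]) for s in result.mutated_sites()}
            table = table[
                [
                    (c, n) in mutated
                    for c, n in zip(table["chain"], table["number"])
                ]
            ]
        lines += ["", "[residue_energies]", table.to_csv(sep="\t", index=False).rstrip()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(
    result: DesignResult,
    out_dir: str | Path,
    prefix: str,
    task=None,
    invocation: str = "",
    compare_residue_energies_all: bool = False,
    compare_residue_energies_mut: bool = True,
) -> dict[str, Path]:
    """Write the three deliverables (log, resfile if a task is given, PDB);
    returns the paths keyed by kind."""
    from .rotamer_packer import write_resfile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pdb_path = out_dir / output_name(result, prefix)
    write_pdb(result.structure, pdb_path)
    paths["pdb"] = pdb_path

    log_path = out_dir / f"{prefix}_log.txt"
    write_log(
        result,
        log_path,
        invocation=invocation,
        compare_residue_energies_all=compare_residue_energies_all,
        compare_residue_energies_mut=compare_residue_energies_mut,
    )
    paths["log"] = log_path

    if task is not None:
        resfile_path = out_dir / f"{prefix}_resfile.txt"
        write_resfile(task, resfile_path)
        paths["resfile"] = resfile_path
    return paths
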