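"""Shared result containers for both design protocols."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .structure_model import ProteinStructure, Site


@dataclass(frozen=True)
class Mutation:
    """One applied mutation with its bookkeeping."""

    site: Site
    native_aa: str
    new_aa: str
    charge_delta: int
    avnapsa: float | None = None      # exposure of the native residue (AvNAPSA mode)
    energy_delta: float | None = None  # per-residue total energy change


@dataclass
class DesignResult:
    """Output of a supercharging run: structure, mutations, charges, metadata."""

    structure: ProteinStructure
    mutations: list[Mutation]
    net_charge_before: int
    net_charge_after: int
    protocol: str                     # "avnapsa" or "energy"
    polarity: str                     # "positive" or "negative"
    surface_sites: list[Site] = field(default_factory=list)
    energy_table: pd.DataFrame | None = None
    final_reference_energies: dict[str, float] | None = None
    max_avnapsa_of_mutations: float | None = None
    seeds: tuple[int, ...] = ()
    warnings: list[str] = field(default_factory=list)
    #: energy-mode ramp: list of ({type: refweight}, achieved charge) per iteration
    ramp_history: list | None = None

    @property
    def charge_change(self) -> int:
        return self.net_charge_after - self.net_charge_before

    def mutated_sites(self) -> set[Site]:
        return {m.site for m in self.mutations}
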