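"""Molecular constants used for stoichiometric unit conversion.

All internal bookkeeping is in mg; molar quantities appear only at the
reporting layer (e.g. the TCA/DCA production ratio, which is a ratio of
mmol).  Conversions between parent-compound mass and metabolite mass
always go through the molecular weights defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MolecularConstants:
    """Molecular weights (g/mol) of TCE and its tracked metabolites."""

    mw: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOLECULAR_WEIGHTS)
    )

    def __post_init__(self) -> None:
        for name, value in self.mw.items():
            if not value > 0:
                raise ValueError(f"molecular weight for {name} must be > 0, got {value}")

    def __getitem__(self, species: str) -> float:
        return self.mw[species]

    def mass_ratio(self, product: str, substrate: str) -> float:
        """mg of *product* formed per mg of *substrate* consumed (1:1 molar)."""
        return self.mw[product] / self.mw[substrate]

    def to_mmol(self, species: str, mass_mg: float) -> float:
        return mass_mg / self.mw[species]


#: g/mol; DCVG/DCVC from glutathione and cysteine S-conjugation (thiol H
#: replaced by the 1,2-dichlorovinyl group).
DEFAULT_MOLECULAR_WEIGHTS: dict[str, float] = {
    "TCE": 131.39,
    "TCA": 163.38,
    "DCA": 128.94,
    "TCOH": 149.40,
    "TCOG": 325.53,
    "DCVG": 402.24,
    "DCVC": 216.08,
}

MEASURED_METABOLITES: tuple[str, ...] = ("TCA", "DCA", "DCVG", "DCVC")
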