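"""Mass and molar-ratio bookkeeping for native-PAGE band assignment.

Monomer masses are the tag-inclusive nominal values of the recombinant
constructs (kDa); a complex specification maps protein id to monomer copy
number, e.g. a KaiC3 hexamer bound by six KaiA3 dimers and six KaiB3
monomers is {"KaiC3": 6, "KaiA3": 12, "KaiB3": 6}.
"""

from __future__ import annotations

from typing import Mapping

from .errors import DomainError

#: Tag-inclusive nominal monomer masses (kDa) of the recombinant constructs.
DEFAULT_MASSES: dict[str, float] = {
    "KaiC3": 58.0,
    "KaiA3": 35.0,
    "KaiB3": 12.0,
}


def complex_mass(spec: Mapping[str, int], masses: Mapping[str, float] = DEFAULT_MASSES) -> float:
    """Total complex mass in kDa: sum of copies * monomer mass."""
    total = 0.0
    for protein, copies in spec.items():
        if copies < 0:
            raise DomainError(f"{protein}: copy number must be >= 0")
        if protein not in masses:
            raise KeyError(f"no monomer mass for {protein!r}")
        if masses[protein] <= 0:
            raise DomainError(f"{protein}: monomer mass must be > 0")
        total += copies * masses[protein]
    return total


def molar_ratio(conc_a: float, conc_b: float, decimals: int = 1) -> float:
    """conc_b / conc_a (dimensionless), rounded half-even to ``decimals``.

    Convention: for a titration of A against a fixed B, `molar_ratio(A, B)`
    expresses the A:B stoichiometry as 1 : returned value.
    """
    if conc_a <= 0:
        raise DomainError("conc_a must be > 0")
    return round(conc_b / conc_a, decimals)
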