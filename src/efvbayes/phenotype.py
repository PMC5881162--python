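"""CYP2B6 metabolizer phenotype labels.

EM / IM / PM (extensive / intermediate / poor metabolizer) correspond to the
CYP2B6 516 GG / GT / TT genotypes and determine apparent efavirenz clearance.
"""
from __future__ import annotations

from enum import Enum


class Phenotype(str, Enum):
    """Metabolizer phenotype; ordered fast to slow clearance."""

    EM = "EM"
    IM = "IM"
    PM = "PM"

    def __str__(self) -> str:  # plain token in CSV/JSON output
        return self.value


#: Canonical display order (rows/columns of confusion matrices, etc.).
PHENOTYPES: tuple[Phenotype, ...] = (Phenotype.EM, Phenotype.IM, Phenotype.PM)

#: Tie-break preference for MAP calls: the slower metabolizer wins a tie.
#: Clinically conservative — a tied call escalates to dose-reduction review.
TIE_ORDER: tuple[Phenotype, ...] = (Phenotype.PM, Phenotype.IM, Phenotype.EM)


def coerce_phenotype(value: "str | Phenotype") -> Phenotype:
    """Parse a phenotype token, raising ``ValueError`` on anything else."""
    if isinstance(value, Phenotype):
        return value
    try:
        return Phenotype(str(value).strip().upper())
    except ValueError:
        raise ValueError(
            f"unknown phenotype {value!r}; expected one of EM, IM, PM"
        ) from None
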