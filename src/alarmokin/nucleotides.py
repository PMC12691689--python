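"""Closed nucleotide vocabulary for the shared-donor-site pyrophosphokinase model.

The enzyme transfers the β,γ-pyrophosphate of ATP (the sole PPi donor) onto the
3'-OH of an acceptor nucleotide.  Six acceptors are representable; each maps to
exactly one alarmone product.
"""

from __future__ import annotations

import enum


class NucleotideSpecies(str, enum.Enum):
    """A nucleotide that can occupy the donor and/or acceptor site."""

    ATP = "ATP"
    ADP = "ADP"
    AMP = "AMP"
    GTP = "GTP"
    GDP = "GDP"
    GMP = "GMP"

    @property
    def can_donate(self) -> bool:
        """Only ATP serves as PPi donor; GTP/CTP/UTP are not accepted donors."""
        return self is NucleotideSpecies.ATP

    @property
    def can_accept(self) -> bool:
        return True

    @property
    def product(self) -> str:
        """Name of the alarmone produced when this species is the PPi acceptor."""
        return PRODUCT_OF[self]

    @classmethod
    def from_product(cls, product: str) -> "NucleotideSpecies":
        try:
            return ACCEPTOR_OF[product]
        except KeyError:
            raise ValueError(
                f"unknown alarmone product {product!r}; known: {sorted(ACCEPTOR_OF)}"
            ) from None


#: acceptor -> alarmone product (pyrophosphorylated at the 3'-OH)
PRODUCT_OF: dict[NucleotideSpecies, str] = {
    NucleotideSpecies.ATP: "pppApp",
    NucleotideSpecies.ADP: "ppApp",
    NucleotideSpecies.AMP: "pApp",
    NucleotideSpecies.GTP: "pppGpp",
    NucleotideSpecies.GDP: "ppGpp",
    NucleotideSpecies.GMP: "pGpp",
}

ACCEPTOR_OF: dict[str, NucleotideSpecies] = {v: k for k, v in PRODUCT_OF.items()}

DONOR = NucleotideSpecies.ATP
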