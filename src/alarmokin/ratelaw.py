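"""Forward mathematics of the shared-donor-site, competing-acceptor rate law.

The velocity of pyrophosphorylation of acceptor x is

    v_x = Vmax(x) * ([x]/Km,x) / D * [ATP]/(Km,donor + [ATP])

with the competition denominator

    D = 1 + sum_i [i]/Km,i

taken over every acceptor species present.  The donor site binds only ATP and
its saturation factors out of every acceptor ratio; competing nucleotides act
exclusively through D.  Fractional site occupancies follow from the same
denominator: theta_apo = 1/D and theta_i = ([i]/Km,i)/D, which sum to one.

Units are fixed package-wide: concentrations in µM, velocities in µM/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .nucleotides import DONOR, NucleotideSpecies


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its positivity/sign constraint."""


class MissingParameterError(KeyError):
    """A species present in a condition has no entry in the parameter set."""

    def __init__(self, species: NucleotideSpecies):
        self.species = species
        super().__init__(
            f"acceptor {species.value} is present in the reaction but has no "
            f"Km/Vmax entry in the kinetic parameters"
        )


@dataclass(frozen=True)
class AcceptorParams:
    """Acceptor-site Michaelis constant (µM) and maximal velocity (µM/min)."""

    km_uM: float
    vmax_uM_per_min: float

    def __post_init__(self):
        if not self.km_uM > 0:
            raise InvalidParameterError(f"km_uM must be > 0, got {self.km_uM}")
        if self.vmax_uM_per_min < 0:
            raise InvalidParameterError(
                f"vmax_uM_per_min must be >= 0, got {self.vmax_uM_per_min}"
            )


@dataclass(frozen=True)
class KineticParameters:
    """Donor-site Km plus the per-acceptor (Km, Vmax) table.

    Parameters
    ----------
    km_donor_uM
        Michaelis constant of the ATP donor site, µM.  Assumed independent of
        which acceptor occupies the acceptor site.
    acceptors
        Mapping acceptor species -> :class:`AcceptorParams`.  A species the
        enzyme turns over with no detectable product is representable as a
        zero-Vmax entry.
    enzyme_conc_nM
        Optional catalyst concentration for kcat scaling.
    """

    km_donor_uM: float
    acceptors: Mapping[NucleotideSpecies, AcceptorParams]
    enzyme_conc_nM: float | None = None

    def __post_init__(self):
        if not self.km_donor_uM > 0:
            raise InvalidParameterError(
                f"km_donor_uM must be > 0, got {self.km_donor_uM}"
            )
        object.__setattr__(self, "acceptors", dict(self.acceptors))
        if self.enzyme_conc_nM is not None and not self.enzyme_conc_nM > 0:
            raise InvalidParameterError(
                f"enzyme_conc_nM must be > 0, got {self.enzyme_conc_nM}"
            )

    def km_acceptor(self, species: NucleotideSpecies) -> float:
        try:
            return self.acceptors[species].km_uM
        except KeyError:
            raise MissingParameterError(species) from None

    def vmax(self, species: NucleotideSpecies) -> float:
        try:
            return self.acceptors[species].vmax_uM_per_min
        except KeyError:
            raise MissingParameterError(species) from None


@dataclass(frozen=True)
class ReactionCondition:
    """Nucleotide concentration map (µM) for one reaction.

    Zero-concentration entries are allowed and ignored; the donor (ATP)
    concentration must be positive for any velocity to be nonzero.
    """

    concentrations: Mapping[NucleotideSpecies, float]
    temperature: str = "30C"
    replicates: int = 1

    def __post_init__(self):
        conc = {NucleotideSpecies(k): float(v) for k, v in self.concentrations.items()}
        for sp, c in conc.items():
            if c < 0:
                raise InvalidParameterError(f"[{sp.value}] must be >= 0, got {c}")
        object.__setattr__(self, "concentrations", conc)

    def conc(self, species: NucleotideSpecies) -> float:
        return self.concentrations.get(species, 0.0)

    @property
    def atp_uM(self) -> float:
        return self.conc(DONOR)

    def acceptors_present(self) -> list[NucleotideSpecies]:
        """Species with nonzero concentration, in a stable order."""
        return [sp for sp in NucleotideSpecies if self.conc(sp) > 0]


@dataclass(frozen=True)
class OccupancyProfile:
    """Fractional saturation of the acceptor site: empty (apo) and per ligand."""

    theta_apo: float
    theta: Mapping[NucleotideSpecies, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "theta", dict(self.theta))
        total = self.theta_apo + sum(self.theta.values())
        if not (0 < self.theta_apo <= 1):
            raise InvalidParameterError(f"theta_apo must be in (0, 1], got {self.theta_apo}")
        if abs(total - 1.0) > 1e-12:
            raise InvalidParameterError(f"occupancies must sum to 1, got {total!r}")


def donor_saturation(atp_conc_uM: float, km_donor_uM: float) -> float:
    """Fractional saturation of the donor site, [ATP]/(Km,donor + [ATP])."""
    if not km_donor_uM > 0:
        raise InvalidParameterError(f"km_donor_uM must be > 0, got {km_donor_uM}")
    if atp_conc_uM < 0:
        raise InvalidParameterError(f"atp_conc_uM must be >= 0, got {atp_conc_uM}")
    return atp_conc_uM / (km_donor_uM + atp_conc_uM)


def competition_denominator(
    condition: ReactionCondition, params: KineticParameters
) -> float:
    """D = 1 + sum_i [i]/Km,i over acceptor species present; always >= 1."""
    d = 1.0
    for sp in condition.acceptors_present():
        d += condition.conc(sp) / params.km_acceptor(sp)
    return d


def competition_velocity(
    x: NucleotideSpecies, condition: ReactionCondition, params: KineticParameters
) -> float:
    """Initial pyrophosphorylation velocity of acceptor x (µM/min).

    Reduces to the product of two Michaelis-Menten terms when x is the only
    acceptor; vanishes when [x] = 0 or [ATP] = 0.
    """
    cx = condition.conc(x)
    if cx == 0:
        # still validate that parameters cover everything present
        competition_denominator(condition, params)
        return 0.0
    d = competition_denominator(condition, params)
    sat = donor_saturation(condition.atp_uM, params.km_donor_uM)
    return params.vmax(x) * (cx / params.km_acceptor(x)) / d * sat


def occupancy_forward(
    condition: ReactionCondition, params: KineticParameters
) -> OccupancyProfile:
    """Acceptor-site occupancy profile implied by the rate-law denominator."""
    d = competition_denominator(condition, params)
    theta = {
        sp: (condition.conc(sp) / params.km_acceptor(sp)) / d
        for sp in condition.acceptors_present()
    }
    # close the sum exactly so the conservation invariant holds to machine precision
    theta_apo = 1.0 - sum(theta.values())
    return OccupancyProfile(theta_apo=theta_apo, theta=theta)
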