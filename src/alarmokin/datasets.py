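"""Shipped parameter fixtures and their (de)serialisation.

The package-wide unit convention is explicit in key names: concentrations and
Km in µM (``_uM``), velocities in µM/min, enzyme concentration in nM.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .nucleotides import NucleotideSpecies
from .ratelaw import AcceptorParams, KineticParameters


def _params_from_dict(doc: dict) -> KineticParameters:
    acceptors = {
        NucleotideSpecies(name): AcceptorParams(
            km_uM=float(entry["km_uM"]),
            vmax_uM_per_min=float(entry["vmax_uM_per_min"]),
        )
        for name, entry in doc["acceptors"].items()
    }
    return KineticParameters(
        km_donor_uM=float(doc["km_donor_uM"]),
        acceptors=acceptors,
        enzyme_conc_nM=doc.get("enzyme_conc_nM"),
    )


def paper_params() -> KineticParameters:
    """Reference constants for the exported alarmone synthetase.

    The donor-site Km (82 µM), the ATP acceptor-site Km (1.4 mM) and the
    maximal pppApp/pppGpp velocities (114 / 110 µM/min) are the study's
    fitted values; Km entries for the remaining acceptors are representative
    values chosen to respect the reported specificity pattern (see the
    fixture's description field).
    """
    text = resources.files("alarmokin").joinpath("data/paper_params.json").read_text()
    return _params_from_dict(json.loads(text))


def load_params(path: str | Path) -> KineticParameters:
    """Load a kinetic-parameter set from a JSON file with explicit-unit keys."""
    with open(path) as fh:
        return _params_from_dict(json.load(fh))


def save_params(params: KineticParameters, path: str | Path) -> None:
    doc = {
        "km_donor_uM": params.km_donor_uM,
        "enzyme_conc_nM": params.enzyme_conc_nM,
        "acceptors": {
            sp.value: {"km_uM": ap.km_uM, "vmax_uM_per_min": ap.vmax_uM_per_min}
            for sp, ap in params.acceptors.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
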