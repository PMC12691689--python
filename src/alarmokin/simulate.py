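"""Forward simulation of titration/competition designs and coupled-assay traces.

The generator reproduces the experimental design the inference expects: a
donor titration (ATP varied at fixed saturating GTP), an ATP-alone acceptor
titration, and two-acceptor competitions, with multiplicative log-normal
noise on velocities.  Noise is drawn once per reaction replicate and shared
by every product measured in that reaction, since competing products are
quantified from the same stopped aliquot.

The donor block is simulated by default from the two-parameter donor
hyperbola v = Vmax(pppGpp)·[ATP]/(Km_d+[ATP]) — the same reduced model the
donor fit assumes, so noise-free recovery is exact.  ``full_competition=True``
switches to the full competing-acceptor rate law (which needs a GTP Km) to
study the bias of that simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import EPSILON_PER_MM, AssayTrace
from .model import VelocityMeasurement, measurements_to_frame
from .nucleotides import DONOR, NucleotideSpecies
from .ratelaw import KineticParameters, ReactionCondition, competition_velocity

#: NADH supplied to each well (mM); the trace plateaus once it is consumed
NADH_BUDGET_MM = 0.5

#: A340 per mM NADH at the plate path; 2 NADH are consumed per product, so
#: this is half the per-product coefficient
EPSILON_NADH_PER_MM = EPSILON_PER_MM / 2.0


@dataclass(frozen=True)
class DesignSpec:
    """Named experimental blocks for one simulated study.

    donor_atp_grid_uM is titrated at fixed donor_gtp_uM; acceptor_atp_grid_uM
    is titrated alone; each competition maps species name -> µM and must
    contain ATP plus one other acceptor.
    """

    donor_gtp_uM: float
    donor_atp_grid_uM: tuple[float, ...]
    acceptor_atp_grid_uM: tuple[float, ...]
    competitions: tuple[dict, ...] = ()
    replicates: int = 2
    cv: float = 0.05

    def __post_init__(self):
        if not self.donor_atp_grid_uM or not self.acceptor_atp_grid_uM:
            raise ValueError("titration grids must be nonempty")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def paper_design(replicates: int = 2, cv: float = 0.05) -> DesignSpec:
    """The study's design: donor block [GTP] = 5 mM with ATP from 30 to 1000 µM
    (6 log-spaced points), acceptor block ATP from 0.5 to 10 mM (7 log-spaced
    points), and competitions of 5 mM ATP against 5 mM ADP, 5 mM AMP, or
    0.5 mM GMP, with 2 technical replicates.

    Only the range endpoints are prescribed; point counts and log spacing are
    package choices.
    """
    return DesignSpec(
        donor_gtp_uM=5000.0,
        donor_atp_grid_uM=tuple(np.geomspace(30.0, 1000.0, 6).round(3)),
        acceptor_atp_grid_uM=tuple(np.geomspace(500.0, 10000.0, 7).round(3)),
        competitions=(
            {"ATP": 5000.0, "ADP": 5000.0},
            {"ATP": 5000.0, "AMP": 5000.0},
            {"ATP": 5000.0, "GMP": 500.0},
        ),
        replicates=replicates,
        cv=cv,
    )


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, np.log1p(cv))))


def simulate_velocities(
    truth: KineticParameters,
    design: DesignSpec,
    seed: int | None = None,
    full_competition_donor_block: bool = False,
    batch: str = "batch1",
) -> list[VelocityMeasurement]:
    """Draw one noisy velocity dataset from the rate law under ``design``.

    Deterministic given ``seed``; at cv = 0 every velocity equals the exact
    rate-law value.  One noise factor is drawn per reaction replicate and
    applied to all products of that reaction.
    """
    rng = np.random.default_rng(seed)
    out: list[VelocityMeasurement] = []

    for atp in design.donor_atp_grid_uM:
        cond = ReactionCondition(
            {DONOR: atp, NucleotideSpecies.GTP: design.donor_gtp_uM}
        )
        if full_competition_donor_block:
            v = competition_velocity(NucleotideSpecies.GTP, cond, truth)
        else:
            v = truth.vmax(NucleotideSpecies.GTP) * atp / (truth.km_donor_uM + atp)
        for rep in range(design.replicates):
            out.append(
                VelocityMeasurement(
                    condition=cond,
                    product="pppGpp",
                    velocity_uM_per_min=v * _noise_factor(rng, design.cv),
                    replicate_id=str(rep + 1),
                    batch=batch,
                )
            )

    for atp in design.acceptor_atp_grid_uM:
        cond = ReactionCondition({DONOR: atp})
        v = competition_velocity(DONOR, cond, truth)
        for rep in range(design.replicates):
            out.append(
                VelocityMeasurement(
                    condition=cond,
                    product="pppApp",
                    velocity_uM_per_min=v * _noise_factor(rng, design.cv),
                    replicate_id=str(rep + 1),
                    batch=batch,
                )
            )

    for comp in design.competitions:
        cond = ReactionCondition(
            {NucleotideSpecies(k): v for k, v in comp.items()}
        )
        present = cond.acceptors_present()
        for rep in range(design.replicates):
            f = _noise_factor(rng, design.cv)  # shared within the reaction
            for sp in present:
                v = competition_velocity(sp, cond, truth)
                out.append(
                    VelocityMeasurement(
                        condition=cond,
                        product=sp.product,
                        velocity_uM_per_min=v * f,
                        replicate_id=str(rep + 1),
                        batch=batch,
                    )
                )
    return out


def simulate_velocity_frame(
    truth: KineticParameters,
    design: DesignSpec,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Same as :func:`simulate_velocities` but as the long-format table,
    with the seed recorded in a ``seed`` column."""
    df = measurements_to_frame(simulate_velocities(truth, design, seed, **kwargs))
    df["seed"] = seed
    return df


def simulate_trace(
    truth: KineticParameters,
    condition: ReactionCondition,
    duration_min: float = 30.0,
    interval_min: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    with_background: bool = False,
    background_slope_a340_per_min: float = -0.005,
    dilution_factor: float = 1.0,
    a0: float = 1.0,
    epsilon_per_mM: float = EPSILON_PER_MM,
    well_id: str = "A1",
) -> tuple[AssayTrace, AssayTrace]:
    """Simulate a paired (full, minus-myokinase) coupled-assay trace set.

    The total AMP-producing velocity — the rate-law velocity summed over all
    acceptors present, treated as constant over the initial-rate window — is
    integrated into an A340 decline of slope −ε·v; the optional background
    slope emulates ADP-producing side activities and appears in both traces.
    The decline plateaus once cumulative NADH consumption (2 per product,
    implicit in ε) exhausts the 0.5 mM supplied.
    """
    if duration_min <= 0 or interval_min <= 0:
        raise ValueError("duration_min and interval_min must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)

    v_total = sum(
        competition_velocity(sp, condition, truth)
        for sp in condition.acceptors_present()
    ) / dilution_factor  # µM/min in the well
    bg = background_slope_a340_per_min if with_background else 0.0

    # NADH consumption rates (mM/min): synthesis uses 2 per product, the
    # background slope converts through the NADH coefficient directly
    synth_nadh = 2.0 * v_total / 1000.0
    bg_nadh = abs(bg) / EPSILON_NADH_PER_MM

    def decline(t, nadh_rate_total, a340_rate):
        t_exhaust = (
            NADH_BUDGET_MM / nadh_rate_total if nadh_rate_total > 0 else np.inf
        )
        return a340_rate * np.minimum(t, t_exhaust)

    full_signal = a0 + decline(
        t, synth_nadh + bg_nadh, -(epsilon_per_mM * v_total / 1000.0) + bg
    )
    bg_signal = a0 + decline(t, bg_nadh, bg)
    if noise_sd > 0:
        full_signal = full_signal + rng.normal(0.0, noise_sd, t.size)
        bg_signal = bg_signal + rng.normal(0.0, noise_sd, t.size)

    full = AssayTrace(
        times=t, a340=full_signal, has_myokinase=True,
        dilution_factor=dilution_factor, well_id=well_id,
    )
    minus = AssayTrace(
        times=t, a340=bg_signal, has_myokinase=False,
        dilution_factor=dilution_factor, well_id=well_id + "-bg",
    )
    return full, minus


def simulate_trace_frame(
    truth: KineticParameters,
    conditions: dict[str, ReactionCondition],
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Simulate paired traces for several conditions as one long-format table
    in the schema :func:`alarmokin.assay.reduce_traces` consumes."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, (cond_id, cond) in enumerate(conditions.items()):
        sub = int(rng.integers(0, 2**31 - 1))
        full, minus = simulate_trace(
            truth, cond, seed=sub, well_id=f"W{i + 1}", **kwargs
        )
        for trace in (full, minus):
            frames.append(
                pd.DataFrame(
                    {
                        "well_id": trace.well_id,
                        "time_min": trace.times,
                        "a340": trace.a340,
                        "has_myokinase": int(trace.has_myokinase),
                        "dilution_factor": trace.dilution_factor,
                        "condition_id": cond_id,
                        "seed": seed,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
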