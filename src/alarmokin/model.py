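"""Stepwise competition-kinetics inference, statsmodels-style.

:class:`CompetitionKineticsModel` is built from a collection of initial-velocity
measurements (one titration of ATP at saturating GTP, one ATP-alone titration,
and any number of two-acceptor competitions); its :meth:`fit` runs the
sequential inference and returns a :class:`KineticsResults` holding the
per-acceptor kcat / Km / kcat/Km table with standard errors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import fitting
from .fitting import (
    DeconvolutionError,
    DesignError,
    FitEstimate,
    deconvolve_km,
    fit_dual_saturation,
    fit_michaelis_menten,
    specificity_from_ratio,
)
from .nucleotides import DONOR, NucleotideSpecies
from .ratelaw import ReactionCondition

GDP_FLAG = "co-elution, not quantifiable"


@dataclass(frozen=True)
class VelocityMeasurement:
    """One (condition, product, velocity) observation."""

    condition: ReactionCondition
    product: str
    velocity_uM_per_min: float
    replicate_id: str = "1"
    batch: str = "batch1"

    def __post_init__(self):
        if self.velocity_uM_per_min < 0:
            raise ValueError(f"velocity must be >= 0, got {self.velocity_uM_per_min}")
        acceptor = NucleotideSpecies.from_product(self.product)
        if self.condition.conc(acceptor) <= 0:
            raise ValueError(
                f"product {self.product} implies acceptor {acceptor.value}, "
                "which is absent from the reaction"
            )


# ---------------------------------------------------------------------------
# dataframe <-> measurement conversion

def _conc_col(sp: NucleotideSpecies) -> str:
    return f"conc_{sp.value}_uM"


VELOCITY_COLUMNS = (
    ["condition_id"]
    + [_conc_col(sp) for sp in NucleotideSpecies]
    + ["product", "velocity_uM_per_min", "replicate_id"]
)


def measurements_to_frame(measurements: Iterable[VelocityMeasurement]) -> pd.DataFrame:
    rows = []
    cond_ids: dict[tuple, str] = {}
    for m in measurements:
        key = tuple(sorted((sp.value, c) for sp, c in m.condition.concentrations.items()))
        cid = cond_ids.setdefault(key, f"c{len(cond_ids) + 1:03d}")
        row = {"condition_id": cid}
        row.update({_conc_col(sp): m.condition.conc(sp) for sp in NucleotideSpecies})
        row.update(
            product=m.product,
            velocity_uM_per_min=m.velocity_uM_per_min,
            replicate_id=m.replicate_id,
            batch=m.batch,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_measurements(df: pd.DataFrame) -> list[VelocityMeasurement]:
    out = []
    for _, row in df.iterrows():
        conc = {
            sp: float(row.get(_conc_col(sp), 0.0) or 0.0) for sp in NucleotideSpecies
        }
        conc = {sp: c for sp, c in conc.items() if c != 0.0}
        out.append(
            VelocityMeasurement(
                condition=ReactionCondition(concentrations=conc),
                product=str(row["product"]),
                velocity_uM_per_min=float(row["velocity_uM_per_min"]),
                replicate_id=str(row.get("replicate_id", "1")),
                batch=str(row.get("batch", "batch1")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# design-block classification

@dataclass
class _Blocks:
    donor: list[VelocityMeasurement] = field(default_factory=list)
    acceptor: list[VelocityMeasurement] = field(default_factory=list)
    competitions: dict[NucleotideSpecies, list[VelocityMeasurement]] = field(
        default_factory=dict
    )


def _classify(measurements: Sequence[VelocityMeasurement]) -> _Blocks:
    blocks = _Blocks()
    for m in measurements:
        present = set(m.condition.acceptors_present())
        if present == {DONOR, NucleotideSpecies.GTP} and m.product == "pppGpp":
            blocks.donor.append(m)
        elif present == {DONOR} and m.product == "pppApp":
            blocks.acceptor.append(m)
        elif len(present) == 2 and DONOR in present:
            (x,) = present - {DONOR}
            blocks.competitions.setdefault(x, []).append(m)
        else:
            raise DesignError(
                f"measurement with acceptors {sorted(s.value for s in present)} and "
                f"product {m.product} fits no design block (donor titration, "
                "ATP-alone titration, or ATP + one competitor)"
            )
    return blocks


def _single_batch(measurements: Sequence[VelocityMeasurement], what: str) -> None:
    batches = {m.batch for m in measurements}
    if len(batches) > 1:
        raise DesignError(
            f"{what} mixes enzyme batches {sorted(batches)}; "
            "velocities from different batches cannot enter one fit"
        )


def _mean_by_condition(
    measurements: Sequence[VelocityMeasurement], conc_of: NucleotideSpecies
) -> tuple[np.ndarray, np.ndarray]:
    """Average replicate velocities, keyed by the varied species' concentration."""
    by_conc: dict[float, list[float]] = {}
    for m in measurements:
        by_conc.setdefault(m.condition.conc(conc_of), []).append(m.velocity_uM_per_min)
    concs = np.array(sorted(by_conc))
    means = np.array([np.mean(by_conc[c]) for c in concs])
    return concs, means


# ---------------------------------------------------------------------------
# results

@dataclass(frozen=True)
class AcceptorRow:
    """One line of the kinetic table (one PPi acceptor)."""

    species: NucleotideSpecies
    product: str
    km_uM: float = np.nan
    km_se_uM: float = np.nan
    vmax_uM_per_min: float = np.nan
    vmax_se_uM_per_min: float = np.nan
    vmax_over_km_per_min: float = np.nan
    kcat_per_min: float = np.nan
    kcat_over_km_per_min_per_uM: float = np.nan
    theta_apo: float = np.nan
    theta_atp: float = np.nan
    theta_x: float = np.nan
    flag: str = ""


@dataclass(frozen=True)
class KineticsResults:
    """Fitted constants, the per-acceptor table, and reporting helpers."""

    km_donor: FitEstimate
    vmax_pppGpp: FitEstimate
    km_acceptor_atp: FitEstimate
    vmax_pppApp: FitEstimate
    rows: tuple[AcceptorRow, ...]
    enzyme_conc_nM: float | None = None
    n_measurements: int = 0
    #: pppApp turnover used as the scaling reference for the kcat column
    kcat_reference_per_min: float | None = None
    #: resampling SDs per quantity when fit(bootstrap=...) was requested
    bootstrap_se: "pd.DataFrame | None" = None

    @property
    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "acceptor": r.species.value,
                    "product": r.product,
                    "km_uM": r.km_uM,
                    "km_se_uM": r.km_se_uM,
                    "vmax_uM_per_min": r.vmax_uM_per_min,
                    "vmax_se_uM_per_min": r.vmax_se_uM_per_min,
                    "vmax_over_km_per_min": r.vmax_over_km_per_min,
                    "kcat_per_min": r.kcat_per_min,
                    "kcat_over_km_per_min_per_uM": r.kcat_over_km_per_min_per_uM,
                    "flag": r.flag,
                }
                for r in self.rows
            ]
        )
        return df.set_index("acceptor")

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def summary(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("Competition kinetics fit (shared-donor-site model)\n")
        w("=" * 58 + "\n")
        w(f"measurements: {self.n_measurements}\n")
        w(f"Km,donor (ATP)      : {self.km_donor:.4g} uM\n")
        w(f"Vmax (pppGpp)       : {self.vmax_pppGpp:.4g} uM/min\n")
        w(f"Km,acceptor (ATP)   : {self.km_acceptor_atp:.4g} uM\n")
        w(f"Vmax (pppApp)       : {self.vmax_pppApp:.4g} uM/min\n")
        if self.enzyme_conc_nM is not None:
            w(f"enzyme              : {self.enzyme_conc_nM} nM\n")
            w(f"kcat (pppApp)       : {self.kcat_reference_per_min:.3g} /min\n")
        w("-" * 58 + "\n")
        w(self.table.to_string(float_format=lambda x: f"{x:.4g}"))
        w("\n")
        return buf.getvalue()


# ---------------------------------------------------------------------------
# model

class CompetitionKineticsModel:
    """Shared-donor-site competition kinetics, fitted stepwise.

    Parameters
    ----------
    measurements
        Initial-velocity observations covering at least the donor titration
        (varying ATP at fixed saturating GTP, pppGpp product) and the
        ATP-alone titration (pppApp product).  Two-acceptor competition
        conditions contribute per-competitor Km and Vmax rows.
    enzyme_conc_nM
        Catalyst concentration; enables the kcat column.
    reference_rate_uM_per_min, reference_atp_uM
        Optional ATP-only rate observed with the quantified enzyme batch.
        When given, the pppApp turnover reference is that rate per enzyme,
        corrected to dual-site saturation at ``reference_atp_uM`` — the
        procedure used when the enzyme amount is quantified in a different
        batch than the titrations.  When absent, kcat falls back to
        Vmax(pppApp)/[E], which presumes ``enzyme_conc_nM`` refers to the
        titration batch itself.
    """

    def __init__(
        self,
        measurements: Iterable[VelocityMeasurement],
        enzyme_conc_nM: float | None = None,
        reference_rate_uM_per_min: float | None = None,
        reference_atp_uM: float | None = None,
    ):
        self.measurements = list(measurements)
        self.enzyme_conc_nM = enzyme_conc_nM
        if (reference_rate_uM_per_min is None) != (reference_atp_uM is None):
            raise ValueError(
                "reference_rate_uM_per_min and reference_atp_uM go together"
            )
        self.reference_rate_uM_per_min = reference_rate_uM_per_min
        self.reference_atp_uM = reference_atp_uM
        if not self.measurements:
            raise DesignError("no measurements supplied")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, enzyme_conc_nM: float | None = None
    ) -> "CompetitionKineticsModel":
        """Build from a long-format velocity table (see VELOCITY_COLUMNS)."""
        return cls(frame_to_measurements(df), enzyme_conc_nM=enzyme_conc_nM)

    @classmethod
    def from_csv(
        cls, path: str | Path, enzyme_conc_nM: float | None = None
    ) -> "CompetitionKineticsModel":
        return cls.from_dataframe(pd.read_csv(path), enzyme_conc_nM=enzyme_conc_nM)

    # -- stage fits, usable on their own -----------------------------------

    def fit_donor_site(self) -> tuple[FitEstimate, FitEstimate]:
        """Km,donor and Vmax(pppGpp) from the saturating-GTP ATP titration."""
        blocks = _classify(self.measurements)
        if not blocks.donor:
            raise DesignError(
                "missing donor-titration block (varying ATP at fixed GTP, pppGpp product)"
            )
        _single_batch(blocks.donor, "donor titration")
        gtps = {m.condition.conc(NucleotideSpecies.GTP) for m in blocks.donor}
        if len(gtps) > 1:
            raise DesignError(
                f"donor titration must hold [GTP] fixed; found {sorted(gtps)} uM"
            )
        concs, means = _mean_by_condition(blocks.donor, DONOR)
        return fit_michaelis_menten(concs, means)

    def fit_acceptor_atp(self, km_donor_uM: float) -> tuple[FitEstimate, FitEstimate]:
        """Km,acceptor(ATP) and Vmax(pppApp) from the ATP-alone titration."""
        blocks = _classify(self.measurements)
        if not blocks.acceptor:
            raise DesignError("missing ATP-alone titration block (pppApp product)")
        _single_batch(blocks.acceptor, "ATP-alone titration")
        concs, means = _mean_by_condition(blocks.acceptor, DONOR)
        return fit_dual_saturation(concs, means, km_donor_uM)

    # -- full pipeline ------------------------------------------------------

    def fit(self, bootstrap: int = 0, seed: int | None = None) -> KineticsResults:
        """Run the sequential inference and assemble the kinetic table.

        ``bootstrap > 0`` additionally resamples replicate velocities within
        each (condition, product) group that many times (seeded), reruns the
        pipeline, and attaches the resampling SDs as ``bootstrap_se``; the
        table's SE columns stay covariance-based.
        """
        result = self._fit_once()
        if bootstrap > 0:
            result = replace(
                result, bootstrap_se=self._bootstrap_se(bootstrap, seed)
            )
        return result

    def _bootstrap_se(self, n_boot: int, seed: int | None) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        draws: list[dict] = []
        for _ in range(n_boot):
            groups: dict[tuple, list[VelocityMeasurement]] = {}
            for m in self.measurements:
                key = (
                    tuple(sorted(
                        (s.value, c) for s, c in m.condition.concentrations.items()
                    )),
                    m.product,
                )
                groups.setdefault(key, []).append(m)
            resampled = [
                grp[i]
                for grp in groups.values()
                for i in rng.integers(0, len(grp), len(grp))
            ]
            try:
                r = CompetitionKineticsModel(
                    resampled, enzyme_conc_nM=self.enzyme_conc_nM
                )._fit_once()
            except (DesignError, fitting.FitFailureError):
                continue
            row = {
                "km_donor_uM": r.km_donor.value,
                "vmax_pppGpp_uM_per_min": r.vmax_pppGpp.value,
                "km_acceptor_ATP_uM": r.km_acceptor_atp.value,
                "vmax_pppApp_uM_per_min": r.vmax_pppApp.value,
            }
            for acc in r.rows:
                row[f"km_{acc.species.value}_uM"] = acc.km_uM
                row[f"vmax_{acc.species.value}_uM_per_min"] = acc.vmax_uM_per_min
            draws.append(row)
        df = pd.DataFrame(draws)
        return df.std(ddof=1).to_frame(name="bootstrap_se")

    def _fit_once(self) -> KineticsResults:
        """Run the sequential inference and assemble the kinetic table."""
        blocks = _classify(self.measurements)
        km_d, vmax_pppGpp = self.fit_donor_site()
        km_a, vmax_pppApp = self.fit_acceptor_atp(km_d.value)

        rows: dict[NucleotideSpecies, AcceptorRow] = {}
        rows[DONOR] = AcceptorRow(
            species=DONOR,
            product="pppApp",
            km_uM=km_a.value,
            km_se_uM=km_a.se,
            vmax_uM_per_min=vmax_pppApp.value,
            vmax_se_uM_per_min=vmax_pppApp.se,
            vmax_over_km_per_min=vmax_pppApp.value / km_a.value,
        )

        for x, ms in sorted(blocks.competitions.items(), key=lambda kv: kv[0].value):
            rows[x] = self._competitor_row(
                x, ms, km_d, vmax_pppApp, km_a
            )

        # GTP appears in the donor titration even without a competition block:
        # its Vmax is known there, its Km is not (GTP held saturating).
        if NucleotideSpecies.GTP not in rows and blocks.donor:
            rows[NucleotideSpecies.GTP] = AcceptorRow(
                species=NucleotideSpecies.GTP,
                product="pppGpp",
                vmax_uM_per_min=vmax_pppGpp.value,
                vmax_se_uM_per_min=vmax_pppGpp.se,
                flag="Km not identifiable from saturating-GTP design",
            )

        row_list, kcat_ref = self._attach_kcats(rows, km_d, km_a)
        return KineticsResults(
            km_donor=km_d,
            vmax_pppGpp=vmax_pppGpp,
            km_acceptor_atp=km_a,
            vmax_pppApp=vmax_pppApp,
            rows=tuple(row_list),
            enzyme_conc_nM=self.enzyme_conc_nM,
            n_measurements=len(self.measurements),
            kcat_reference_per_min=kcat_ref,
        )

    def _competitor_row(
        self,
        x: NucleotideSpecies,
        ms: Sequence[VelocityMeasurement],
        km_d: FitEstimate,
        vmax_pppApp: FitEstimate,
        km_a: FitEstimate,
    ) -> AcceptorRow:
        product_x = x.product
        if x is NucleotideSpecies.GDP:
            # ppGpp co-elutes with pppApp in the anion-exchange readout
            return AcceptorRow(species=x, product=product_x, flag=GDP_FLAG)
        _single_batch(ms, f"competition with {x.value}")
        conds = {
            tuple(sorted((s.value, c) for s, c in m.condition.concentrations.items()))
            for m in ms
        }
        if len(conds) > 1:
            raise DesignError(
                f"competition with {x.value} spans multiple conditions; "
                "one condition per competitor is required"
            )
        v_p = [m.velocity_uM_per_min for m in ms if m.product == "pppApp"]
        v_x = [m.velocity_uM_per_min for m in ms if m.product == product_x]
        if not v_p or not v_x:
            raise DesignError(
                f"competition with {x.value} must measure both pppApp and {product_x}"
            )
        cond = ms[0].condition
        v_p_mean, v_x_mean = float(np.mean(v_p)), float(np.mean(v_x))

        spec_const = specificity_from_ratio(
            v_x_mean, v_p_mean, cond.conc(x), cond.atp_uM,
            vmax_pppApp.value, km_a.value,
        )
        try:
            theta_apo, theta_atp, theta_x, km_x = deconvolve_km(
                v_p_mean, cond.atp_uM, cond.conc(x),
                vmax_pppApp.value, km_d.value, km_a.value,
            )
        except DeconvolutionError as exc:
            return AcceptorRow(
                species=x,
                product=product_x,
                vmax_over_km_per_min=spec_const,
                theta_apo=exc.theta_apo,
                theta_atp=exc.theta_atp,
                theta_x=exc.theta_x,
                flag=f"deconvolution failed: {exc}",
            )
        vmax_x = spec_const * km_x
        km_se, vmax_se = self._propagate_se(
            x, v_p_mean, v_x_mean, cond, km_d, vmax_pppApp, km_a
        )
        return AcceptorRow(
            species=x,
            product=product_x,
            km_uM=km_x,
            km_se_uM=km_se,
            vmax_uM_per_min=vmax_x,
            vmax_se_uM_per_min=vmax_se,
            vmax_over_km_per_min=spec_const,
            theta_apo=theta_apo,
            theta_atp=theta_atp,
            theta_x=theta_x,
        )

    @staticmethod
    def _propagate_se(
        x: NucleotideSpecies,
        v_p: float,
        v_x: float,
        cond: ReactionCondition,
        km_d: FitEstimate,
        vmax_pppApp: FitEstimate,
        km_a: FitEstimate,
    ) -> tuple[float, float]:
        """First-order propagation of the upstream fitting errors.

        The dominant error source is the fitted (Km, Vmax) constants, not the
        replicate spread, so the derivative is taken with respect to those
        three, assumed independent, each perturbed by its SE.
        """

        def recompute(kd: float, vp_max: float, ka: float) -> tuple[float, float]:
            _, _, _, km_x = deconvolve_km(
                v_p, cond.atp_uM, cond.conc(x), vp_max, kd, ka
            )
            sc = specificity_from_ratio(
                v_x, v_p, cond.conc(x), cond.atp_uM, vp_max, ka
            )
            return km_x, sc * km_x

        base = np.array(recompute(km_d.value, vmax_pppApp.value, km_a.value))
        var = np.zeros(2)
        for i, est in enumerate((km_d, vmax_pppApp, km_a)):
            if not np.isfinite(est.se) or est.se == 0:
                continue
            args = [km_d.value, vmax_pppApp.value, km_a.value]
            h = est.se * 1e-3
            args[i] += h
            try:
                hi = np.array(recompute(*args))
            except DeconvolutionError:
                continue
            var += (((hi - base) / h) * est.se) ** 2
        return float(np.sqrt(var[0])), float(np.sqrt(var[1]))

    def _attach_kcats(
        self,
        rows: dict[NucleotideSpecies, AcceptorRow],
        km_d: FitEstimate,
        km_a: FitEstimate,
    ) -> tuple[list[AcceptorRow], float | None]:
        order = [sp for sp in NucleotideSpecies if sp in rows]
        if self.enzyme_conc_nM is None:
            return [rows[sp] for sp in order], None
        if self.reference_rate_uM_per_min is not None:
            kcat_ref = fitting.kcat_from_rate(
                self.reference_rate_uM_per_min,
                self.enzyme_conc_nM,
                self.reference_atp_uM,
                km_d.value,
                km_a.value,
            )
        else:
            kcat_ref = rows[DONOR].vmax_uM_per_min / (self.enzyme_conc_nM / 1000.0)
        vmax_table = {
            sp: rows[sp].vmax_uM_per_min
            for sp in order
            if np.isfinite(rows[sp].vmax_uM_per_min)
        }
        kcats = fitting.scale_kcats(kcat_ref, vmax_table)
        out = []
        for sp in order:
            r = rows[sp]
            if sp in kcats:
                kcat = kcats[sp]
                r = replace(
                    r,
                    kcat_per_min=kcat,
                    kcat_over_km_per_min_per_uM=(
                        kcat / r.km_uM if np.isfinite(r.km_uM) else np.nan
                    ),
                )
            out.append(r)
        return out, kcat_ref


def run_full_inference(
    measurements: Iterable[VelocityMeasurement],
    enzyme_conc_nM: float | None = None,
    **kwargs,
) -> KineticsResults:
    """Functional entry point: build the model and fit in one call."""
    return CompetitionKineticsModel(
        measurements, enzyme_conc_nM=enzyme_conc_nM, **kwargs
    ).fit()
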