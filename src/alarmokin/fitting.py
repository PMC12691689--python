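"""Nonlinear fits and the occupancy algebra behind the stepwise inference.

The inference is deliberately sequential, mirroring how the experimental
design isolates each parameter:

1. donor titration (low ATP, saturating GTP, pppGpp the only product) gives
   the donor-site Km and Vmax(pppGpp) from a plain hyperbola;
2. ATP-alone titration gives the acceptor-site Km of ATP and Vmax(pppApp)
   from a dual-saturation curve with the donor Km held fixed;
3. product ratios in two-acceptor competitions give each competitor's
   specificity constant Vmax/Km, because the shared competition denominator
   and the donor factor cancel in the ratio;
4. the pppApp velocity in the same competitions, inverted through the
   fractional-saturation relations, gives the competitor's Km — and with
   step 3, its Vmax.

All fits are bounded trust-region nonlinear least squares; standard errors
come from the fit covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .nucleotides import NucleotideSpecies
from .ratelaw import InvalidParameterError, donor_saturation


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge or the design cannot identify the parameters."""


class DesignError(ValueError):
    """The measurement collection lacks a design block the inference needs."""


class DeconvolutionError(ValueError):
    """Occupancy inversion produced an inconsistent (non-physical) profile."""

    def __init__(self, message: str, theta_apo: float, theta_atp: float, theta_x: float):
        super().__init__(
            f"{message} (theta_apo={theta_apo:.4g}, theta_ATP={theta_atp:.4g}, "
            f"theta_x={theta_x:.4g})"
        )
        self.theta_apo = theta_apo
        self.theta_atp = theta_atp
        self.theta_x = theta_x


@dataclass(frozen=True)
class FitEstimate:
    """Point estimate with its standard error from the fit covariance."""

    value: float
    se: float

    def __format__(self, spec: str) -> str:
        return f"{format(self.value, spec)} ± {format(self.se, spec)}"


#: parameter convergence tolerance for all nonlinear fits
XTOL = 1e-10


def _bounded_fit(model, s, v, p0) -> tuple[np.ndarray, np.ndarray]:
    try:
        popt, pcov = curve_fit(
            model,
            s,
            v,
            p0=p0,
            bounds=(0.0, np.inf),
            method="trf",
            xtol=XTOL,
            ftol=XTOL,
            gtol=XTOL,
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"nonlinear least squares failed: {exc}") from exc
    if not np.all(np.isfinite(popt)):
        raise FitFailureError(f"fit returned non-finite parameters: {popt}")
    return popt, pcov


def fit_michaelis_menten(
    substrate_concs_uM, velocities_uM_per_min
) -> tuple[FitEstimate, FitEstimate]:
    """Fit v = Vmax*s/(Km+s); returns (Km ± SE, Vmax ± SE), both in input units.

    Requires >= 3 distinct concentrations.  Initialisation: Vmax0 = 1.2*max(v),
    Km0 = median(s).  Non-identifiable designs (no curvature information, e.g.
    all velocities zero) raise :class:`FitFailureError` with diagnostics.
    """
    s = np.asarray(substrate_concs_uM, dtype=float)
    v = np.asarray(velocities_uM_per_min, dtype=float)
    _check_titration(s, v)

    def mm(s, km, vmax):
        return vmax * s / (km + s)

    popt, pcov = _bounded_fit(mm, s, v, p0=[np.median(s), 1.2 * v.max()])
    return _estimates(popt, pcov, s)


def fit_dual_saturation(
    atp_concs_uM, velocities_uM_per_min, km_donor_uM: float
) -> tuple[FitEstimate, FitEstimate]:
    """Fit v = Vmax * ([ATP]/(Km_a+[ATP])) * ([ATP]/(Km_d+[ATP])) with Km_d fixed.

    This is the ATP-alone model: ATP feeds both the donor and the acceptor
    site, so the observed hyperbola is the product of the two saturation
    terms; only the acceptor-site Km and Vmax are free.
    Returns (Km_acceptor ± SE, Vmax ± SE).
    """
    if not km_donor_uM >= 0:
        raise InvalidParameterError(f"km_donor_uM must be >= 0, got {km_donor_uM}")
    s = np.asarray(atp_concs_uM, dtype=float)
    v = np.asarray(velocities_uM_per_min, dtype=float)
    _check_titration(s, v)

    def dual(s, km_a, vmax):
        donor = s / (km_donor_uM + s) if km_donor_uM > 0 else 1.0
        return vmax * s / (km_a + s) * donor

    popt, pcov = _bounded_fit(dual, s, v, p0=[np.median(s), 1.2 * v.max()])
    return _estimates(popt, pcov, s)


def _check_titration(s: np.ndarray, v: np.ndarray) -> None:
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("concentrations and velocities must be 1-D and equal length")
    if np.unique(s).size < 3:
        raise FitFailureError(
            f"need >= 3 distinct concentrations, got {np.unique(s).size}"
        )
    if np.any(v < 0):
        raise ValueError("velocities must be >= 0")
    if np.all(v == 0):
        raise FitFailureError("all velocities are zero: Km/Vmax not identifiable")


def _estimates(popt, pcov, s) -> tuple[FitEstimate, FitEstimate]:
    km, vmax = popt
    if not np.all(np.isfinite(pcov)):
        se_km = se_vmax = float("nan")
    else:
        se_km, se_vmax = np.sqrt(np.diag(pcov))
    if km > 50 * s.max() or km < s.min() / 50:
        raise FitFailureError(
            f"fitted Km = {km:.4g} lies far outside the sampled range "
            f"[{s.min():.4g}, {s.max():.4g}]: design does not identify it"
        )
    return FitEstimate(float(km), float(se_km)), FitEstimate(float(vmax), float(se_vmax))


def specificity_from_ratio(
    v_x: float,
    v_pppApp: float,
    conc_x_uM: float,
    conc_atp_uM: float,
    vmax_pppApp: float,
    km_acceptor_atp_uM: float,
) -> float:
    """Competitor's specificity constant Vmax/Km (min^-1) from a product ratio.

    In one reaction both products share the competition denominator and the
    donor-saturation factor, so

        v_x / v_pppApp = (Vmax_x/Km_x) [x] / ((Vmax_pppApp/Km_ATP) [ATP])

    and Vmax_x/Km_x follows without knowing either alone.
    """
    if v_pppApp <= 0:
        raise ZeroDivisionError(
            "v_pppApp must be > 0 to take the product ratio (undefined ratio)"
        )
    if conc_x_uM <= 0:
        raise InvalidParameterError(f"conc_x_uM must be > 0, got {conc_x_uM}")
    return (v_x / v_pppApp) * (vmax_pppApp / km_acceptor_atp_uM) * (conc_atp_uM / conc_x_uM)


def deconvolve_km(
    v_pppApp: float,
    conc_atp_uM: float,
    conc_x_uM: float,
    vmax_pppApp: float,
    km_donor_uM: float,
    km_acceptor_atp_uM: float,
) -> tuple[float, float, float, float]:
    """Invert a two-acceptor pppApp velocity into occupancies and the competitor Km.

    The fractional saturations of the acceptor site follow from the observed
    pppApp velocity:

        theta_ATP = (v_pppApp / Vmax_pppApp) / donor_saturation
        theta_apo = theta_ATP * Km_ATP / [ATP]
        theta_x   = 1 - theta_apo - theta_ATP
        Km_x      = (theta_apo / theta_x) * [x]

    Returns (theta_apo, theta_atp, theta_x, km_x_uM).  Raises
    :class:`DeconvolutionError`, carrying the three occupancies, whenever
    noise pushes the profile outside (0, 1) — never clamps, since clamping
    would silently fabricate a Km.
    """
    if conc_atp_uM <= 0:
        raise InvalidParameterError("deconvolution requires [ATP] > 0")
    if conc_x_uM <= 0:
        raise InvalidParameterError("deconvolution requires a competitor with [x] > 0")
    sat = donor_saturation(conc_atp_uM, km_donor_uM)
    theta_atp = (v_pppApp / vmax_pppApp) / sat
    theta_apo = theta_atp * km_acceptor_atp_uM / conc_atp_uM
    theta_x = 1.0 - theta_apo - theta_atp
    if theta_atp >= 1.0:
        raise DeconvolutionError(
            "theta_ATP >= 1: observed pppApp velocity exceeds the saturation bound",
            theta_apo, theta_atp, theta_x,
        )
    if theta_apo + theta_atp > 1.0 or theta_x <= 0.0:
        raise DeconvolutionError(
            "occupancies inconsistent: theta_x <= 0", theta_apo, theta_atp, theta_x
        )
    km_x = (theta_apo / theta_x) * conc_x_uM
    return theta_apo, theta_atp, theta_x, km_x


def kcat_from_rate(
    velocity_uM_per_min: float,
    enzyme_conc_nM: float,
    atp_conc_uM: float,
    km_donor_uM: float,
    km_acceptor_atp_uM: float,
) -> float:
    """Turnover number (min^-1) corrected to full dual-site saturation.

    The observed per-enzyme rate at finite [ATP] is divided by the product of
    the donor- and acceptor-site saturation fractions, so the result is the
    rate the enzyme would reach with both sites saturated.
    """
    if not enzyme_conc_nM > 0:
        raise InvalidParameterError(
            f"enzyme_conc_nM must be > 0, got {enzyme_conc_nM}"
        )
    if velocity_uM_per_min == 0:
        return 0.0
    enzyme_uM = enzyme_conc_nM / 1000.0
    sat = donor_saturation(atp_conc_uM, km_donor_uM) * atp_conc_uM / (
        km_acceptor_atp_uM + atp_conc_uM
    )
    return (velocity_uM_per_min / enzyme_uM) / sat


def scale_kcats(
    kcat_reference: float, vmax_table: dict[NucleotideSpecies, float]
) -> dict[NucleotideSpecies, float]:
    """Per-acceptor kcat scaled from the pppApp reference in proportion to Vmax."""
    if NucleotideSpecies.ATP not in vmax_table:
        raise ValueError("vmax_table must contain the ATP (pppApp) reference row")
    vmax_ref = vmax_table[NucleotideSpecies.ATP]
    if not vmax_ref > 0:
        raise InvalidParameterError(f"vmax(pppApp) must be > 0, got {vmax_ref}")
    return {sp: kcat_reference * vm / vmax_ref for sp, vm in vmax_table.items()}
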