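# Methods

## Model and assumptions

The rate law treats the synthetase as having two independent sites: a
pyrophosphate-donor site that binds only ATP, and a single acceptor site over
which all nucleotide substrates compete. Velocities are initial rates — no
substrate depletion, no product re-use (in particular, no modelling of the
product pppApp acting as an alternative pyrophosphate donor, which is
negligible in the initial-rate window), no Mg²⁺/Mn²⁺ or pH terms. The donor
Km is assumed independent of which acceptor is bound; this is what lets the
donor titration (at saturating GTP) calibrate the donor factor once for all
later fits. The species vocabulary is closed to ATP, ADP, AMP, GTP, GDP, GMP;
nucleotides the enzyme does not turn over are representable as zero-Vmax
entries.

Units are fixed package-wide: concentrations µM, time min, velocities µM/min,
enzyme nM, kcat min⁻¹. Converters (mM→µM, nM→µM) live only at I/O boundaries.

## Parameters

| parameter | meaning | fixture default |
|---|---|---|
| `km_donor_uM` | ATP donor-site Michaelis constant | 82 |
| `km_uM` (ATP) | ATP acceptor-site Michaelis constant | 1400 |
| `vmax_uM_per_min` (ATP→pppApp) | maximal pppApp velocity | 114 |
| `vmax_uM_per_min` (GTP→pppGpp) | maximal pppGpp velocity | 110 |
| `enzyme_conc_nM` | catalyst concentration for kcat | 0.30 |
| `epsilon_per_mM` | A340 change per mM product in the coupled assay | 3.88 |

The first four and the enzyme concentration are the reference study's fitted
constants. The remaining fixture entries (Km 50/60/1000/1200 µM and Vmax
136.8–216.6 µM/min for GMP/GTP/ADP/AMP) are representative values fixed once:
they respect the reported pattern — guanylate acceptor Kms below 100 µM,
adenylate Kms 20–30-fold higher, and turnovers proportional to the reported
kcat series (1.9/1.2/1.0/1.3/0.95 × 10⁵ min⁻¹ for pApp/ppApp/pppApp/pGpp/
pppGpp) — and are labelled `source: "representative"` in
`src/alarmokin/data/paper_params.json`.

The coupled-assay extinction coefficient 3.88 per mM product is treated as an
opaque calibration constant (it is consistent with 2 NADH oxidised per AMP at
the plate's optical path, a stoichiometry implicit in the constant and not
modelled separately); it is overridable in every API that uses it.

## kcat referencing

Turnover has two routes. If the enzyme concentration refers to the titration
batch itself, kcat(pppApp) = Vmax(pppApp)/[E]. If the quantified batch is a
different preparation — the reference study's situation — the model accepts a
`(reference_rate, reference_atp)` pair and corrects that observed per-enzyme
rate by the product of the donor and acceptor saturation fractions at that
ATP concentration. Either way the other acceptors' kcats scale with their
Vmax, so kcat ordering always matches Vmax ordering.

## Synthetic data

`paper_design()` encodes the study conditions: a donor block at [GTP] = 5 mM
with ATP from 30 to 1000 µM, an ATP-alone block from 0.5 to 10 mM, and
competitions of 5 mM ATP against 5 mM ADP, 5 mM AMP or 0.5 mM GMP, with two
technical replicates. Only the range endpoints and competition concentrations
are prescribed by the source design; the 6- and 7-point log-spaced grids are
package choices, declared here rather than inferred from any figure.

Velocity noise is multiplicative log-normal, `v·exp(ε)` with
`σ = ln(1 + CV)` and default CV = 0.05: rates span three orders of magnitude
across the design, so additive noise would be unphysical at the low end. One
draw is made per reaction replicate and shared by all products of that
reaction, because competing products are quantified from the same stopped
aliquot/chromatogram; velocities are therefore strictly positive and CV = 0
reproduces the rate law exactly. The donor block is simulated by default from
the two-parameter donor hyperbola — the same reduced model the donor fit
assumes — so noise-free recovery is exact; a flag
(`full_competition_donor_block`) switches to the full competing-acceptor law
(requiring a GTP Km) to study the bias of that simplification.

Simulated traces integrate the summed AMP-producing velocity into an A340
decline of slope −ε·v, add an optional background slope (mirrored in the
paired minus-myokinase trace) and Gaussian read noise, and plateau once
cumulative NADH consumption reaches the 0.5 mM supplied. The generator does
not emulate pathlength variation, PEP/NADH depletion curvature before the hard
plateau, per-timepoint dilution changes, or chromatographic peak shapes — so
passing round-trip tests demonstrate correctness of the reduction algebra,
not robustness to those instrument artefacts.

## Numerical choices

- Nonlinear fits: `scipy.optimize.curve_fit`, trust-region reflective with
  positivity bounds, tolerances 1e-10; initialisation Vmax₀ = 1.2·max(v),
  Km₀ = median(s). Replicates are averaged (unweighted mean) before fitting;
  standard errors come from the fit covariance.
- A fitted Km more than 50× outside the sampled concentration range raises a
  fit-failure error rather than returning an unidentified parameter.
- Deconvolved occupancies outside (0, 1) raise a hard error carrying the
  three θ values; they are never clamped, since clamping would silently
  fabricate a Km. Within the full-table fit such an error flags its row
  without aborting the others.
- Initial-slope window: "auto" takes the longest window starting at the first
  time point whose linear fit keeps r² ≥ 0.99 (minimum 3 points) — the least
  arbitrary rule given that only "linear regression of the initial phase" is
  specified; the window and r² are reported. A perfectly flat trace is
  reported as slope 0 with r² = 1.
- Net positive slopes after background subtraction map to velocity 0 with a
  `no_signal` flag, never to a negative rate.
- Full/background trace pairing is by explicit `condition_id` declaration,
  never by plate position.
- Velocities carry a batch label; any single fit refuses to mix batches,
  since Vmax is proportional to the (batch-specific) enzyme amount.
- GDP competitions are flagged "co-elution, not quantifiable" and never
  produce numbers: the readout cannot separate ppGpp from pppApp.
- Standard errors for deconvolved rows are first-order propagations of the
  three upstream fitted constants (Km,d, Vmax(pppApp), Km,ATP), treated as
  independent — the replicate spread is deliberately excluded, as the fitting
  error dominates.

## Estimator precision under the study design

A Fisher-information calculation at the design's own settings (6/7 log-spaced
points, CV = 0.10, n = 2 averaged replicates) puts the best achievable
relative standard error of the fitted Kms near 12%, and the occupancy
inversion amplifies the pppApp-velocity error into the deconvolved Km by
1 + (θ_apo+θ_ATP)/θ_x (≈ 1.9 for the 5 mM ADP condition). Single-dataset
recovery of *every* Km and Vmax to better than 15% at n = 2 is therefore a
coin-flip event rather than a typical outcome; across 200 simulated datasets
the median worst-cell error was ≈ 25% at n = 2 and ≈ 6% at n = 32. The test
suite asserts the single-seed 15%/5% check at the package's default simulation
seed and, separately, the property that actually characterises the estimator:
errors shrink with replication at the information-bound rate.

## Known limitations

- The sequential procedure is not a global fit; it inherits the conditioning
  of each stage (by design, to mirror the stepwise experimental logic).
- One dilution factor per trace: designs that change dilution mid-trace are
  not representable.
- The GTP acceptor Km is unidentifiable from the saturating-GTP donor design
  and is only estimable if a GTP-vs-ATP competition block is provided.
- Reported SEs are covariance-based; `fit(bootstrap=N, seed=...)` optionally
  adds replicate-resampling SDs, but with n = 2 technical replicates the
  resampling distribution is coarse and the covariance SEs remain primary.
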