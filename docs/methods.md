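# Methods

## Binding model

The detection reagent is a monovalent dye-labelled Fab recognising a human
IgG1 epitope present twice on the drug (a ~200 kDa dual-variable-domain
immunoglobulin). We treat the two epitopes as independent, identical sites:
the drug enters all equilibrium arithmetic as a *site* concentration, twice
its molar concentration (`effective_site_concentration`). No cooperative or
ring-forming model is offered; the monovalence of the Fab is exactly what
rules out cross-linking.

For totals *a* (Fab, nM), *x* (sites, nM) and dissociation constant
*K*<sub>D</sub> (nM), the complex concentration is the smaller root of
`(a−c)(x−c) = K_D·c`. We evaluate it as

    s = (a + x + K_D)/2;   c = a·x / (s + sqrt(s² − a·x))

rather than the textbook `s − sqrt(s² − a·x)`, because when
`K_D ≪ a, x` the subtraction cancels catastrophically; the product form is
accurate to machine precision over the whole regime (verified against
bisection root-finding to 1e−9 relative on random systems up to 10 µM).
The discriminant is clamped at zero and the root at `min(a, x)` to absorb
last-bit rounding. All internal concentrations are nM; µg/mL ↔ nM conversion
(`c_nM = c_µg/mL · 10⁶ / M_Da`) and the 1:5 serum-dilution back-conversion
happen only at the boundary, so mixed units cannot propagate silently.

The observable in the SEC titration is the complex peak's share of total
fluorescence. Since every fluorophore is on the Fab, that share is `[AB]/a`,
and the fitted signal model is `Y = F + (F_max − F)·[AB]/a` with baseline
*F* and plateau *F*<sub>max</sub>. (The share of *drug* bound, `[AB]/x`, is
a different quantity, exposed separately as `fraction_bound`; the titration
generator and fitter both use the fluorescence share, which is the one that
saturates as drug is titrated to excess.)

## K_D fitting

`fit_kd` minimises unweighted squared residuals of the signal model over
(*F*, *F*<sub>max</sub>, *K*<sub>D</sub>) with lmfit's Levenberg–Marquardt,
with a derivative-free start (*F* = min y, *F*<sub>max</sub> = max y,
*K*<sub>D</sub> = x at half-maximal y). Relative weighting is available but
off by default. Inputs must have ≥ 4 points spanning a ≥ 10-fold range.
Non-convergence is reported in the result, never raised. Because a
saturation titration only localises *K*<sub>D</sub> when the probe
concentration is comparable to it, results with `a_total > 50·K_D` carry a
weak-identifiability flag: in that regime the curve is a stoichiometric
break, not an affinity measurement. Site-doubling is always the caller's
responsibility so the fitter's x-axis is unambiguous.

## SPR kinetics

The 1:1 Langmuir model has closed-form solutions at constant analyte
concentration, so sensorgrams are simulated and fitted analytically — exact,
fast and free of ODE-solver tolerance artefacts. The global fit shares
*k*<sub>on</sub>, *k*<sub>off</sub>, *R*<sub>max</sub> across the series
(per-curve *R*<sub>max</sub> optional), optimising log-rates with
data-driven starts (*k*<sub>off</sub> from the log-linear dissociation tail,
*k*<sub>obs</sub> from the 63%-of-plateau time). Standard errors on the
linear scale come from the delta method. Mass-transport limitation, drift
and bulk refractive-index steps are out of scope; noise is additive
Gaussian. An independent equilibrium route — fitting plateau responses to
`Req = R_max·C/(C+K_D)` — is used in the tests to cross-check the kinetic
estimate.

Stoichiometry arithmetic: an immobilised ligand giving `RU_ligand` response
with *n* analyte sites saturates at `RU_ligand · n · M_analyte / M_ligand`.
For 78 RU of the 200 kDa drug and the 47.15 kDa Fab at *n* = 2 this gives
36.8 → 37 RU.

## Chromatogram model and quantification

Traces are rendered as sums of Gaussians, one per species, centred at the
species' calibrated retention time with a common width, plus optional broad
components and additive baseline noise. A species' peak area equals its
fluorescence abundance: concentration × number of Fabs it carries (the free
dye counts one fluorophore; drug, ADA and serum proteins are invisible).
Retention is calibrated **by species, never by mass**: the free dye
demonstrably elutes later than its 1 kDa mass predicts, so a mass-to-time
formula would misplace it.

Default calibration (0.3 mL/min): free dye 19.5 min, free Fab 18 min,
drug–Fab complex 15 min (anchored to observed retention), and
figure-informed placeholders for the ADA windows — 1 drug·1 ADA ≈ 13.25 min,
2 drug·1 ADA ≈ 12.35 min, larger complexes < 11.9 min, unspecific serum
peak ≈ 14 min. Window bounds are configurable (YAML) and must be disjoint.

Numerical choices: baseline is a constant, the median of the first and last
5% of the trace (no baseline-handling procedure is prescribed by the assay;
a constant is the least-assuming choice and is exact for the synthetic
fixtures). Integration is trapezoidal above that baseline; window shares
are clipped to [0, 1]. Peak width defaults to σ = 0.18 min for all species
— narrow enough that each default window captures ≥ 98% of its peak, so
windowed shares track true abundances to well under two percentage points;
width is configurable for broader columns.

The sensitivity statistic is a ratio of percentage areas: the complex
window's share of total trace area in a drug-containing run divided by the
same window's share in a drug-free control. It is scale-invariant, so
detector gain cancels. The detection limit is the lowest titrated
concentration with S/N ≥ 1.5; a zero blank share returns a flagged
infinite-S/N sentinel, and no crossing returns a not-detected sentinel.

## Synthetic-data scenarios

The generators' defaults are the study conditions, fixed once:

* **Sensitivity titration** — drug 1–2500 nM into 678 nM Fab, *K*<sub>D</sub>
  22.5 nM, free-dye carry-over 30 nM, baseline noise sd 1 AU. Every run
  (including the blank) carries a broad serum-background Gaussian
  (centre 14 min, σ 2 min, area 134 nM-equivalents) representing serum
  autofluorescence and weak nonspecific Fab binding; it is what gives the
  drug-free control its nonzero complex-window share. Its area is a one-time
  calibration encoding the assay's sensitivity claim — the S/N 1.5 crossing
  lands at 10 nM drug in assay (10 µg/mL in undiluted serum) — and is
  explicitly a calibration, not a measurement.
* **K_D titration** — 585 nM Fab, 22 log-spaced drug concentrations
  0.32–20560.8 nM (site-doubled), 2% multiplicative noise on the signal.
* **SPR series** — 12 concentrations 0.49–2000 nM (log-spaced), 300 s
  association, 600 s dissociation, *k*<sub>on</sub> 10⁵ M⁻¹s⁻¹,
  *K*<sub>D</sub> 18.2 nM, *R*<sub>max</sub> 37 RU, 0.5 RU additive noise.
* **ADA series** — 830 nM drug, 678 nM Fab, ADA 0/0.75/1.5/2/3.5 µM. The
  composition rule is a documented scenario of the generator, not a measured
  property: drug-class fractions, the precipitation curve for the largest
  complexes and their Fab retention are piecewise-linear in ADA
  concentration, calibrated once so that (i) complex detection peaks at
  1.5 µM ADA and declines at higher ADA, (ii) at 3.5 µM ADA the pellet holds
  40% of the drug, 20% of the ADA and 20% of the Fab, and (iii) free Fab
  rises at ADA excess (large ADA-rich lattices retain less Fab per drug,
  modelling steric displacement). Soluble complexes carry the equilibrium
  Fab occupancy (~0.8 Fab per drug at these totals — the Fab is *not* in
  epitope excess at 830 nM drug). Total drug (soluble + pellet) is conserved
  exactly. Densitometry lanes are forward-simulated from the pellet
  fractions with the 20%/80% volume split and 5% CV noise.
* **Study timecourse** — doses 1, 6 and 13 of a weekly-dosing study;
  samples predose and 15 min–168 h postdose (dose 13 missing the 15 min and
  168 h draws). Free drug peaks at 15 min (500 µg/mL serum) and decays
  monotonically; immune complexes appear only transiently at 15 min/4 h
  after repeat dosing, dose 13 with a larger large-complex share; a
  constant-area unspecific serum peak is present in every sample and
  excluded from drug quantification. Ligand-binding-assay values track the
  free-drug truth with 5% CV, floored at the 0.136 µg/mL quantitation limit
  and flagged (never zeroed); western intensities track total drug with
  10% CV. The broad serum background of the sensitivity scenario is omitted
  here so that windowed drug quantification is clean; the unspecific peak is
  the study scenario's serum signature.

Determinism: every generator draws from `np.random.default_rng((seed,
stream))` with a fixed stream id per generator, so identical seeds reproduce
bit-identical outputs and different generators never share a stream.

What the generators do **not** emulate: real serum matrix effects, column
tailing and drift, retention-time jitter, overlapping-peak deconvolution,
physiological pharmacokinetics or an evolving immune response. Passing
recovery tests on these fixtures demonstrates the correctness of the
arithmetic and fits under the stated noise model, not assay performance on
real chromatograms.

## Mass balance

With pellet/supernatant volume fractions `v_p + v_s = 1`, soluble protein
appears in the pellet lane in proportion `v_p`; the inversion
`soluble = S/v_s`, `precipitated = P − v_p·soluble` is exact on noiseless
forward data for any split and any precipitated fraction. Densitometry noise
can drive the precipitate estimate slightly negative; the fraction is then
clipped to [0, 1] and flagged, never silently.

## Design notes and open choices

* The ADA molecular mass defaults to 150 kDa (standard IgG) and is
  configurable; the polyclonal preparation's true mass is unknown.
* The titration observable defaults to the complex share of total
  fluorescence; peak-area-based alternatives can be fed to the same fitter.
* The stoichiometry arithmetic from 80 RU of ligand gives 37.7 RU, not 36;
  the implementation follows the formula (the measured 78 RU gives 36.8,
  rounding to the observed 37).
* At 678 nM Fab and *K*<sub>D</sub> 22.5 nM the equation gives 96.7–97.3%
  of drug Fab-bound at the detection limit — high, but short of a nominal
  "98%"; the package reports what the equation yields.
* Exact retention of the ADA complex windows is a placeholder calibration;
  real deployments must recalibrate per column and flow rate.

## Problem sizes

Replicate counts used by the tests and the acceptance script — 200 titration
fits, 100 global sensorgram fits, 6 replicate densitometry gels — are the
package's chosen defaults for stable replicate means; the full suite runs in
a few seconds.
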