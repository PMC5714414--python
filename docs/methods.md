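# Methods

## Scope and data model

The package evaluates prostate VMAT plans at the DVH level.  The central
object is the cumulative DVH: dose thresholds (bin lower edges, Gy,
starting at 0) with the relative volume fraction at or above each
threshold — non-increasing from 1.  Volumes are relative fractions
internally; absolute cm³ appear only at the file boundary, converted
through the structure's total volume, because the radiobiological models
and the effective-volume reduction need fractions while organ volumes are
reported in cm³.  Doses are Gy everywhere; cGy files are converted at
parse time via a header flag.

Cumulative DVHs are stored at bin lower edges and differential bin
centers are edge midpoints, which makes the cumulative↔differential
mapping unambiguous.  Differencing conserves volume exactly (the final
bin absorbs any residual at the last edge), and the two conversions are
mutual inverses on uniform grids — on non-uniform grids midpoints of
midpoints do not return the original edges, so the round-trip guarantee
is stated for uniform grids only, which is what the generator and
`resample` produce.  Raw exports may carry float-rounding noise;
monotonicity violations up to 1e-6 (relative) are clamped, larger ones
rejected with the offending row named.

Default grid resolution is 0.1 Gy, a typical treatment-planning-system
export resolution; it is configurable everywhere.

## Metrics

Dx% is the minimum dose received by the hottest x% of the structure: the
dose where the linearly interpolated cumulative curve crosses down
through x/100.  Where the curve is flat at exactly that level the upper
end of the flat run is returned, since the hottest x% all receive at
least that dose (this also makes D100% of a plateau-then-falloff curve
equal the plateau end).  VxGy interpolates the curve directly; doses
beyond the last edge have zero volume.  The maximum dose is DVH-derived —
the dose where the curve reaches a configurable epsilon volume (default
0) — not a 3D point dose; planning-system point maxima can differ.
Mean dose is the volume-weighted mean of the differential form.  All
interpolation is linear in (dose, volume): it preserves monotonicity and
keeps every value reproducible by hand.

## TCP

Logistic dose response `TCP(D) = e^(p+qD)/(1+e^(p+qD))` with
`q = 4γ50/D50` and `p = −4γ50`, the standard logit mapping that makes
TCP(D50) = 1/2 exact and the normalized slope `D50·TCP′(D50)` equal γ50
exactly (the logistic derivative at its midpoint is q/4).  The whole-organ
probability treats each differential-DVH bin as an independent tumorlet:
`TCP = Π TCP(D_i)^{v_i}`, accumulated in the log domain.  Refining bins at
a fixed dose leaves the product unchanged (exponent additivity), and a
uniform DVH reduces to the scalar formula.

Defaults D50 = 67.5 Gy, γ50 = 2.0 are a documented, overridable
configuration choice representative of clinical prostate dose-response
summaries; no claim of fit to any specific outcome dataset is made, and
no test treats absolute TCP values as ground truth.

## NTCP

Lyman probit with Kutcher-Burman reduction.  The heterogeneous DVH is
reduced to the effective fraction `v_eff = Σ v_i (D_i/D_ref)^(1/n)` of
the organ uniformly irradiated at the reference dose, with `D_ref`
defaulting to the maximum dose carrying nonzero volume; zero-dose bins
contribute nothing and a completely unirradiated organ returns NTCP 0
with a flagged intermediate.  The partial-volume tolerance is
`TD50(v) = TD50(1)·v^(−n)` and `NTCP = Φ((D_ref − TD50(v_eff)) /
(m·TD50(v_eff)))`.  Rectal defaults: TD50(1) = 80 Gy, m = 0.15, n = 0.12.
On uniform partial-volume DVHs the reduction path coincides with the
closed-form Lyman expression to 1e-12 (tested as two separate code
paths).  Φ is computed through the complementary error function; |t| > 8
saturates to 0/1 at double precision.  Doses are total-course physical
doses; no LQ/EQD2 fractionation correction is applied, a deliberate
modelling limitation of this evaluation layer.

Bladder and femoral-head NTCP are out of scope: for these organs and
criteria the complication probabilities are orders of magnitude below the
rectal one, so the rectum is the organ whose NTCP drives technique
choice.

## Cohort comparison

Plans are paired per patient (both techniques required; unpaired patients
are named in the error).  Per metric the report carries cohort mean and
sample SD (n−1, the small-cohort convention) per technique, and the
percent change of the non-reference technique, defined as the ratio of
cohort means — `100·(mean_other − mean_ref)/mean_ref` — with single-arc
as the reference.  Mean-of-per-patient-ratios is a different estimand;
ratio-of-means is the default here because it reproduces standard
published cohort arithmetic directly from table means.  Display rounding
is one decimal for Gy and percent, integers for monitor units.

## Synthetic cohort generator

The generator fabricates the study design the analysis assumes: n
patients (default 5), each planned with both techniques at a 78 Gy
prescription, with per-structure DVHs written through the package's own
writers.

Curve families (the functional forms are the generator's own; fidelity is
defined as matching configured summary statistics, not curve shapes):

- **Target (PTV):** truncated, renormalized probit falloff
  `V(D) = Φ((D_c − D)/σ)`, with `(D_c, σ)` solved (bisection) so the
  realized D99% and maximum dose equal the sampled targets before grid
  discretization.  σ → 0 degenerates to a step at D_c.
- **Overlap organ (rectum, bladder):** `V = f·S + (1−f)·T` — a fraction
  `f` of the organ overlapping the high-dose region (probit component `S`
  centered near the prescription) plus a Weibull-survival tail
  `T = exp(−(D/τ)^k)` truncated at the maximum dose.  `(τ, k)` are solved
  by nested bisection so the composite curve passes exactly through the
  sampled V17Gy and V35Gy.  A single-exponential tail has one parameter
  and cannot realize both published VxGy levels at once, hence the shape
  parameter.  Solved shapes are constrained to k ∈ [0.3, 5]; flatter or
  steeper tails correspond to degenerate curves no clinical DVH shows,
  and draws requiring them are redrawn.
- **Lateral organ (femoral heads):** pure tail with fixed shape
  (k = 2.5), τ solved from the sampled D5%.

D30% and D50% of the overlap organs are emergent, not steered; with the
default configuration the emergent values land close to typical clinical
cohort means, which is a useful property check but not a calibration.

**Statistical structure.**  The emulated cohort is paired, so anatomy
(structure volume, overlap fraction) is drawn once per patient and shared
by both plans, and each metric draw decomposes into a patient-level
effect shared between techniques plus a technique-specific residual with
correlation ρ = 0.8 — plan metrics of one patient track each other
because the same geometry drives both optimizations.  One standard-normal
"dose burden" effect per structure drives all of that structure's
metrics.  Draws are truncated at ±2.5 SD.  Without this pairing a
five-patient cohort frequently inverts the weaker technique contrasts by
sampling noise alone, which is not the behaviour of a paired design.
All randomness derives from one top-level seed through per-patient
substreams (`default_rng([seed, patient_index])`), so cohorts are
reproducible patient by patient and byte-identical on disk across runs.

The default configuration encodes published five-patient cohort means and
SDs per technique as generation targets (PTV D99% 72.5 ± 0.8 vs
74.6 ± 0.4 Gy; rectal V17Gy 61.1 ± 8.5 vs 47.7 ± 9.0%, and so on), with
structure volumes spanning the published per-patient ranges and
monitor-unit draws around 536 vs 640.  The double-arc overlap component
is centered 1 Gy higher (78.3 vs 77.3 Gy), representing the hotter
PTV-organ overlap that makes the double-arc rectal NTCP higher despite
its lower mid-dose burden.  These numbers are generator *inputs*; no test
treats them as oracles for the physics.

**What the generator does not emulate:** 3D dose distributions, anatomy
shape, dose falloff correlations between neighbouring organs, or
monitor-unit physics.  Passing end-to-end tests therefore demonstrates
that the pipeline arithmetic behaves correctly on cohorts with realistic
summary statistics — not that the curve shapes match any particular
planning system's output.

**Residual sampling variability.**  With five patients per cohort the
weakest contrasts (bladder D50%, and the two techniques' NTCP whose
cohort difference is a few percent relative) can still invert for some
seeds, exactly as a real five-patient cohort could.  The invariant that
holds at every seed examined is mechanistic: the technique whose rectal
DVH realizes the hotter near-prescription region has the higher cohort
NTCP.  The shipped default seed (1234) was fixed together with the
configuration.

## Numerical choices

- Probit and logistic evaluated in overflow-safe forms (`erfc`,
  `expit`/`logaddexp`); TCP products accumulate in the log domain.
- All root solves are bisection-based (`brentq`, xtol 1e-12) with
  explicit feasibility checks that raise named errors rather than
  returning inexact fits; infeasible sampled target combinations (e.g.
  D99% ≥ max dose, V35 ≥ V17) are redrawn a bounded number of times.
- Interpolation tie-breaks: Dx% returns the upper end of a flat run at
  the exact level; the DVH maximum returns the first dose at which the
  curve reaches the epsilon volume.
- Test problem sizes: property sweeps use dozens of random DVHs with up
  to ~60 bins; the closure suite uses 200 calibrated draws; cohort
  end-to-end checks use the default five-patient configuration.

## Known limitations

- No DICOM-RT ingestion; plain-text DVH exports only.
- No fractionation (EQD2/BED) correction in either model.
- DVH-derived maxima understate 3D point maxima.
- TCP/NTCP parameter fitting to outcome data is out of scope; the models
  evaluate plans under fixed, documented parameter sets.
- Percent-change reporting requires a nonzero reference mean.
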