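# Methods

## The measurement problem

A stirred batch bioreactor sparged with air reports culture activity through
the CO₂ fraction of its exhaust. For filamentous fungi the dry-weight (DW)
record is sparse — a handful of manual samples — while the off-gas is sampled
every few minutes, so phase boundaries and growth rates are best derived from
the gas signal and the DW record is used where it suffices. `fermprof`
operationalises that analysis and ships a simulator that generates the same
kind of data with known ground truth.

## Gas balance

A steady-state molar balance over the head space gives the CO₂ evolution
rate per litre of broth:

    CER [mmol/L/h] = vvm · 60 · (co2% − inlet%) / 100 / V_m · 1000

with `vvm` the airflow in volumes of air per volume of liquid per minute and
V_m = 24.465 L/mol the molar gas volume at the cultivation temperature
(25 °C, 1 atm — the exhaust leaves near broth temperature, so V_m at 25 °C
rather than STP). The working volume cancels. Inlet CO₂ defaults to the
atmospheric 0.04 % v/v and is configurable, including 0 for uncorrected
analyses. Negative rates (noise below inlet) are floored at zero.
Accumulated CO₂ is the running trapezoidal integral, exact for piecewise
linear rates; at the ≤ 5 min sampling used here the scheme choice is
immaterial (closure tested at 0.33 % against a 200 000-point reference
integral).

## Phase boundaries are defined by their detectors

Each boundary is the output of an explicit procedure, and this matters for
how recovery can be assessed:

* **Lag end** — first sample of the earliest run of ≥ k consecutive samples
  with exhaust CO₂ strictly above a threshold (package default 6 %,
  k = 3; k is a robustness choice against single-sample sensor noise).
* **Exponential window** — ordinary least squares of ln(accumulated CO₂) vs
  time; the accepted window starts at the first usable sample after the lag
  end and extends to the farthest end with R² ≥ 0.99 and ≥ 3 points. The
  slope is the maximum CO₂ production rate (1/h): with CER = y_CX µX + mX
  both terms are proportional to X during balanced growth, so the log-slope
  equals µ (verified to < 1 % on noise-free simulations with the window
  inside the exponential region).
* **CO₂ maximum** — argmax of the 1 h moving-average-smoothed CO₂ trace,
  earliest sample on ties.
* **Non-exponential duration** — CO₂-maximum time minus fit-end time,
  floored at zero (the fit end is clamped to the CO₂ maximum).

Two numerical properties of the R²-threshold window rule, established
analytically and by simulation, shaped the design:

1. **Bend read-through.** Extending a qualifying window past any bend in
   ln(acc CO₂) costs R² only gradually: even if CER drops to zero instantly,
   the window end overshoots the latent bend by ≈ 18 % of the window length
   (2.5 h for a 14 h window), and the slope over the longest window is biased
   about −6 % from the latent µ. The "end of the exponential fit" is
   therefore a property of the procedure, not an unbiased estimator of a
   latent regime-switch time. Accordingly, the simulator's ground-truth
   ledger records *both* the latent model times (transition, exhaustion) and
   the procedure-consistent values obtained by running the identical
   detection on the noise-free signal; recovery statements are made against
   the latter, which is what noise robustness can meaningfully mean for an
   operationally defined quantity.
2. **Anchoring.** If the window start may float freely after the lag end,
   a long maintenance-driven post-transition segment — nearly log-linear for
   tens of hours — out-lengths the true exponential window and wins the
   "longest window" competition, placing the fit in the wrong phase.
   `segment_run` therefore pins the window start at the first usable sample
   after the detected lag end. The floating-start exhaustive search remains
   available (`fit_exponential_window(..., fixed_start=False)`) and is
   verified against brute-force enumeration of all O(n²) windows.

All reported times are sample timestamps; no sub-sample interpolation.

## Growth kinetics

µ_max is the OLS slope of ln(DW) vs time over samples inside the exponential
window, accepted with ≥ 3 points and R² ≥ 0.96; otherwise it is *absent with
a flag*, never imputed — short exponential phases routinely leave fewer than
three DW samples, which is exactly when the CO₂ production rate stands in.
Y_sx is (DW_end − DW_start)/(S_start − S_end) between the samples nearest
the growth-window endpoints (lag end to CO₂ maximum, nearest-sample matching
within 2 h) and requires measurable consumption. Replicate summaries use the
sample SD (n−1); absent values are excluded but counted.

## The simulator

The growth model is piecewise and closed-form — biomass constant at x₀
through the lag; dX/dt = µX in the exponential phase; dX/dt = r (constant
accretion, the simplest stand-in for diffusion-limited pelleted growth)
after an optional transition time; growth stops when S = 0 with
dS/dt = −(1/Y_sx)dX/dt. CO₂ couples as CER = y_CX·dX/dt + m·X, decaying
exponentially after exhaustion; the exhaust fraction inverts the gas balance
under the ramped airflow (0.1 → 0.9 vvm over the first 1200 min). Because
every phase integrates in closed form, trajectories are evaluated exactly at
the sampling times; an independent `solve_ivp` integration is the oracle in
the tests (no fixed-step scheme of our own is needed).

Default conditions emulate the cultivation setting the package models:
0.9 L working volume, 15 g/L glucose, 25 °C, inoculation at 10⁹ spores/L
(≈ 10 pg dry mass per conidium → x₀ = 0.01 g/L), µ = 0.20 h⁻¹, lag 8 h,
Y_sx = 0.5 g/g, y_CX = 0.9 g CO₂ per g DW (carbon balance for biomass of
≈ 0.45 gC/g grown on glucose), maintenance m = 0.01 g CO₂/g DW/h, off-gas
every 5 min, DW and glucose every 3 h, 2 % multiplicative lognormal off-gas
noise, 0.1 g/L additive truncated-Gaussian DW/glucose noise, 5 % between-
replicate CV on µ and lag. Replicates share one config-driven sampling grid
(sized from the unperturbed trajectory with headroom for slow replicates)
and derive independent random streams from (seed, replicate index), so runs
are byte-reproducible.

Two scenario families need care:

* **Detection threshold for synthetic gas.** Under these airflow/volume
  settings a 15 g/L glucose batch peaks near 1.5 % CO₂ in the exhaust, so
  the package-default 6 % lag threshold can never fire on synthetic runs;
  bundled scenarios use 0.15 % (a tenth of the signal span, ≈ 4× the inlet
  level and ≈ 75 noise SDs above it).
* **Pelleted scenarios.** With constant-rate accretion, CER drops at the
  transition by y_CX(µX_p − r); the CO₂ trace then only regains its maximum
  before exhaustion if maintenance picks up the difference,
  m(X_final − X_p) > y_CX(µX_p − r). The pelleted templates therefore place
  the transition at modest biomass (X_p ≈ 1.35 g/L) and use m = 0.05 g/g/h,
  the high end of the realistic fungal range — pellet cores respiring
  without net growth are precisely that regime. The long-transition
  ("vulpinum-like") scenario is *calibrated*: a deterministic fixed-point
  iteration adjusts the latent transition time and accretion rate until the
  noise-free detected fit end lands at 36 h and the detected CO₂ maximum at
  110 h, because those observables — themselves detector outputs — define
  the scenario; the latent transition ends up ≈ 1.5 h earlier than the fit
  end (bend read-through, above).

The feature-table generator plants known compounds at the [M+H]⁺ m/z of
their library mass (uniform jitter below the match tolerance, shared
retention time per compound), adds unknown features rejection-sampled at
least 30 ppm away from every library adduct mass, and applies per-replicate
dropout; its ledger is the ground truth for counting and dereplication
tests.

### What the simulator does not emulate

Morphology itself (pellet geometry, oxygen limitation mechanics), substrate
consumption by maintenance (maintenance CO₂ is not charged to S, a small
carbon-balance inconsistency growing with m), pH/base dynamics, O₂ uptake,
instrument drift, and chromatographic artefacts (isotopologues, in-source
fragments, RT drift). Passing recovery tests therefore demonstrates
correctness of the computations and robustness to sensor-scale noise, not
validity of the linear-accretion stand-in for real pelleted kinetics.

## Metabolite counting and dereplication

Candidates are features of the latest sample with area strictly
> 500 000 counts and intensity strictly > 10 000 counts; candidates are then
searched in all other samples with *no* threshold on the search side, and a
compound counts as reproducible when matched in ≥ 2 of 3 biological
replicates. Matching tolerances default to 10 ppm m/z and 0.1 min retention
time (quadrupole-TOF-appropriate) and are configurable; every reported match
carries its signed ppm error so tolerance sensitivity is auditable.
Dereplication checks [M+H]⁺, [M+Na]⁺ and [M+NH₄]⁺ adducts (positive
electrospray); isobaric ambiguity is reported, not resolved, and identities
are mass matches only — confirmation against reference standards is outside
computational scope, so reports carry the library's `standard_confirmed`
flag as a confidence label. The built-in demo library of ten well-known
fungal secondary metabolites has no cross-adduct collisions within 10 ppm.

## Numerical choices and degenerate inputs

Windowed OLS statistics use centred prefix sums (O(1) per window); R² is
defined as 1 for zero-variance windows. ln requires positive accumulated
CO₂, so the integral's leading zero(s) are excluded from candidate windows.
Lag detection uses strict inequality ("above"), matching the counting rules'
strict "higher than". Ties at the CO₂ maximum break to the earliest sample.
Empty feature tables yield empty candidate lists, not errors; fewer than two
replicate tables reject. Zero or negative DW inside a fit window is a data
error and rejects; absent kinetics are flagged, and single-replicate
summaries report SD 0 with an `n=1` flag.

## Known limitations

The noisy detected CO₂-maximum time scatters by hours on maintenance-plateau
signals (the trace is flat to ≪ 1 % over its final hours while sensor noise
is 2 %); medians across replicates remain centred on the noise-free value.
The window rule's bend read-through means fit ends systematically trail
latent transitions; comparisons across studies should compare procedure
outputs, not latent times. µ from dry weight is unstable when the detected
window straddles a pellet transition — the R² ≥ 0.96 gate does not reliably
reject a three-point fit with one post-transition sample — which is the
documented reason to prefer the CO₂ production rate there.
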