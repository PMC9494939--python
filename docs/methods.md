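# Methods

## The physical picture

The system is a suspension of oil-in-water emulsion droplets coated by
regenerated cellulose: a micron-scale oil core, a thick (≥0.2 μm) porous
water-swollen cellulose hydrogel shell, and a thin dense cellulose coat,
in water.  On the measured window (7.5×10⁻³ < q < 0.264 Å⁻¹, pinhole
collimation, absolute units via a glassy-carbon standard) the scattering is
attributed to the nanoscale porous structure *inside* the shell: the
droplet envelope is too large to contribute there, and the cross term
between envelope and internal fluctuations is negligible when the
inhomogeneities are much smaller than the particle.  The analysis therefore
(1) fits the internal-structure signal with a one-level unified model,
(2) integrates the invariant, and (3) converts it into the cellulose volume
fraction of the shell.

## Unified model and fitting

One structural level: I(q) = G exp(−q²Rg²/3) + B erf(q·Rg/√6)^{3P} q^{−P} + bkg.
Multi-level evaluation is supported (each higher level's power law damped by
the next-smaller level's Guinier factor; level 1 undamped), but the analysis
default is a single level, which describes all thirteen samples.

Parameters and defaults:

| parameter | meaning | bounds/default |
|---|---|---|
| G (cm⁻¹) | Guinier prefactor (forward intensity of the level) | ≥ 0 |
| Rg (Å) | radius of gyration of the compact structural unit | [10, 2000] |
| B (cm⁻¹·Å⁻ᴾ) | power-law prefactor | ≥ 0 |
| P | fractal exponent | (1, 4) |
| bkg (cm⁻¹) | residual flat background | ≥ 0, floats by default |

Residuals are taken in log intensity by default (uniform weight across the
many-decade dynamic range; per-point uncertainties are used instead when the
curve carries them; plain-intensity residuals are available).  G and B are
fitted in log space — they are positive scale parameters spanning many
orders of magnitude, and the log parametrization keeps the trust-region
(TRF) steps conditioned; tolerances are 1e-14 with a relative
finite-difference step of 1e-6.

The automatic initial guess takes P from the median local log–log slope of
the upper half of the window, Rg/G from a Guinier fit over the lowest-q
window refined twice to q·Rg ≤ 1.3, the background from the minimum tail
intensity (halved), and B from the tail given P.  Two degeneracies are
handled explicitly: (a) a pure power law through the window start — detected
when the apparent Rg collapses between two low-q windows *and* the low-q
log–log slope equals the high-q exponent; Rg is then pegged to its upper
bound and flagged; (b) a knee at or just below q_min — additional
deterministic starts probe larger Rg values.  Remaining starts are seeded
log-normal jitters; the lowest-chi-square converged start wins, ties broken
toward the smallest Rg so reporting is deterministic.  Non-convergence is
flagged, never silent.

## Invariant and tails

Q = ∫ I q² dq in Å⁻⁴ internally (1 cm⁻¹ = 1e-8 Å⁻¹; the common tabulation
unit cm⁻¹·Å⁻³ is the same number divided by 1e-8).  The measured-range part
is a trapezoid on the native grid.  Below q_min a Guinier extrapolation is
integrated in closed form (error-function antiderivative, with a series
branch for Rg → 0); if the low-q window shows no measurable decay the
extrapolation degrades gracefully to a flat continuation with a warning,
and an upward-curving Guinier plot (aggregation signature) attaches a
warning rather than failing.  Above q_max the Porod constant K_p is the
least-squares constant of I·q⁴ over the top 20% of the window (log-spaced),
the tail is K_p/q_max, and a window log–log slope far from −4 attaches a
mismatch warning.  Net-negative intensities beyond −3σ are an error;
smaller negative excursions are clipped to zero with the clipped fraction
reported.

## Composition

For a sharp two-phase structure occupying the whole sample,
Q = 2π²Δρ²φ(1−φ).  When the structure occupies a volume fraction f of the
irradiated volume while the intensity is normalized to the total volume,
Q = 2π²Δρ² f φ(1−φ).  With the volume balance f·φ_cell = φ_total (the
overall cellulose volume fraction, 0.0067 for 1 wt% cellulose at densities
1.5/1.0 g/cm³):

    φ_cell = 1 − Q/(2π²Δρ²φ_total),  f = φ_total/φ_cell.

Values of φ_cell outside [0,1] are clamped **and flagged** (`out_of_range`),
never silently.

SLD convention: composition defaults use the conventionally quoted values
1.45e-5 Å⁻² (cellulose, 1.5 g/cm³) and 9.47e-6 Å⁻² (water); the package also
computes SLDs by electron counting (r_e·N_A·ρ·ΣZ/M), which gives ≈1.35e-5
for cellulose and ≈9.43e-6 for water.  The cellulose discrepancy
(1.45 vs 1.35e-5) cannot be reproduced from the stated density; both routes
are exposed and reported.

**Known inconsistency surfaced, not patched:** applying the relation above
verbatim to the tabulated per-sample invariants with the quoted SLDs and
φ_total = 0.0067 yields 1−φ_cell about 1.5× larger than the tabulated
"% cellulose" column implies (e.g. Q = 1.84e-4 cm⁻¹·Å⁻³ → φ_cell ≈ 0.45,
printed 18%).  The printed column is internally linear in Q but uses an
effective constant that is not derivable from the stated inputs.  The
package implements the formula as written; the printed percentages are
treated as non-reproducible and the composition stage is validated instead
by algebraic properties (exact round trip, monotonicity, volume balance)
and by recovery of known synthetic compositions.

## Synthetic data: what it emulates, and what it does not

The tabulated thirteen samples give only Rg and P; the prefactors are not
published.  Fixtures therefore adopt the convention **G = 1 cm⁻¹** with
**B placed so the Guinier/power-law crossover falls at the geometric
mid-point of the instrument grid** (200 log-spaced points over
[7.5e-3, 0.264] Å⁻¹).  Default noise is 2% multiplicative Gaussian with
per-point uncertainties attached (typical of absolute-calibrated pinhole
SAXS; a Poisson counting mode is available); every fixture records its
generating values and seed and is regenerable bit-for-bit.

Consequences of the convention worth keeping in mind:

- Fixture intensities and invariants live on an arbitrary scale ~10³–10⁶
  below the real measurements (the real power-law prefactor implied by the
  tabulated invariants is ≈1.7e-4 cm⁻¹·Å⁻ᴾ against the fixtures'
  ≈3e-10).  Parameter recovery (Rg, P) and all ratio/property tests are
  scale-invariant; tabulated Q values are *inputs* to the composition
  stage, not quantities the fixtures reproduce.
- The synthetic droplet profile used for shape-term studies
  (`droplet_profile`: 0.5 μm oil core, shell to 0.8 μm, 200 Å dense coat,
  decane/hydrogel/cellulose SLDs in water) carries a default number
  density of 5e-20 Å⁻³: the droplet concentration implied by the oil
  content (≈2.6e-14 Å⁻³) scaled down by the same factor that maps the
  real-scale power-law prefactor onto the fixture convention, so envelope
  and internal-structure terms live on one consistent scale.
- On that consistent scale the smeared droplet envelope is below the 2%
  noise floor everywhere in the window, reproducing the study's working
  assumption.  **Limitation:** at the sample's true absolute scale the
  same envelope is 10–70% of the reconstructed signal near q_min — an
  order of magnitude above a 2% noise band — so for real data the neglect
  of the shape term is quantitatively safe only above roughly twice q_min,
  and a low-q upturn from the droplet envelope should be expected.  A unit
  test pins this honest-scale behavior.
- Passing tests on fixtures demonstrate correctness of the estimators
  under the stated noise model; they do not certify instrument effects the
  generator omits (no resolution smearing, no detector artifacts, no
  inter-droplet structure factor).

Size smearing for shape-term verdicts is a lognormal distribution of a
common scale factor (default σ/μ = 0.2, motivated by the broad 0.1–4 μm
droplet-size range) integrated by a deterministic trapezoid whose node
count tracks the fastest form-factor oscillation (phase ≈ q·R·σ), so
verdicts reflect the envelope, not a form-factor null.  The verdict
monotonicity under droplet growth holds at fixed material volume fraction
for sharp core–shell profiles; a thin coat adds a q⁻² thin-shell term that
can grow with size, which is physical and intentionally not hidden.

## Numerical choices

- Sphere kernel 3(sin x − x cos x)/x³ switches to its series below
  |x| < 1e-4 to avoid cancellation.
- Unified fit: multi-start count 3 by default; equal-cost ties (rel. 1e-9)
  break toward smaller Rg.
- Guinier-window fallback keeps at least 5 points; Porod window needs ≥ 5.
- The end-to-end emulsion recovery test uses a core–shell droplet at
  number density 2e-21 Å⁻³, for which the envelope is ≤1% of the internal
  signal in-window — the recovery contract is conditional on that premise.
- Problem sizes: 200-point grids for fitting studies, 2000–4000-point wide
  grids (1e-4–2 Å⁻¹) for invariant oracles; 10 noise replicates per sample
  in recovery studies.

## Known limitations

- One structural level only in the analysis path (matching the study);
  hierarchical multi-level fitting is evaluated but not auto-selected.
- No instrument resolution smearing or 2-D reduction.
- The water-filled-pore assumption behind the SLD contrast is imported,
  not tested (it would require contrast variation).
- The tabulated "% cellulose" column is not an accepted reference, for the
  reason documented above.
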