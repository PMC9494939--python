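# poroshell

Small-angle X-ray scattering (SAXS) analysis of suspensions whose signal is
dominated by a porous polymer phase — specifically, the regenerated-cellulose
hydrogel shell that coats oil-in-water emulsion droplets produced from
cellulose dissolved in cold aqueous NaOH.  The package is a library first
(importable API plus runnable `examples/`), with a thin `poroshell` command
for shell use.

## What it computes

**Unified Guinier/power-law fit (one structural level).**  Measured curves
show a Guinier knee and a power-law tail; both are captured by the unified
(Beaucage) intensity

    I(q) = G exp(−q²Rg²/3) + B [erf(q·Rg/√6)]^(3P) q^(−P) + bkg,

where `Rg` is the radius of gyration of the compact structural unit of the
porous network and `P` its fractal exponent (P < 3: mass fractal;
3 < P < 4: surface fractal; P = 4: smooth Porod interface).  The fitter uses
bounded trust-region least squares on log-intensity residuals from an
automatic initial guess, with deterministic multi-start.

**Scattering invariant with tail extrapolation.**  Q = ∫ I q² dq over all
reciprocal space, assembled from a trapezoidal integral over the measured
window (7.5×10⁻³ < q < 0.264 Å⁻¹), a Guinier extrapolation below q_min and a
Porod (K_p q⁻⁴) extrapolation above q_max.

**Modified-invariant composition.**  When the two-phase structure occupies
only a fraction *f* of the irradiated volume, Q = 2π² Δρ² f φ(1−φ); with the
volume balance f·φ = φ_total (overall polymer fraction known from the
preparation) the polymer fraction of the porous phase is

    φ_cell = 1 − Q / (2π² Δρ² φ_total),   f = φ_total / φ_cell.

**Droplet shape-term check.**  A Stuhrmann-style split justifies ignoring
the droplet envelope: the smeared form factor of a micron-scale layered
sphere is compared against a noise floor over the instrument window.

**Synthetic data.**  Because no raw curves are published, a generator
reproduces the thirteen tabulated samples (their Rg and P, with the
convention G = 1 cm⁻¹ and B at mid-grid crossover), plus dilute-sphere
systems of known closed-form invariant for validating the composition
stage.

## Worked example

```
$ python examples/fit_published_sample.py
sample: 1:1 decane 70
generating values: Rg = 144 A, P = 2.60
fitted:            Rg = 144.0 A, P = 2.600  (reduced chi^2 = 0.876)
```

A curve generated with the tabulated parameters of the 1:1 cellulose/decane
emulsion (70 MPa homogenization) and 2% noise is refit; the fitted radius of
gyration and fractal exponent recover the generating values within the noise.

```
$ python examples/invariant_composition.py
overall cellulose volume fraction (1 wt%, 1.5/1.0 g/cm^3): 0.0067
Q = 1.84e-4 cm^-1 A^-3  ->  phi_cell = 0.449, shell volume fraction f = 0.0149
```

Applying the modified-invariant relation to that sample's published
invariant says the porous shell is ≈45 vol% cellulose and occupies ≈1.5% of
the sample volume.  (The source table prints 18% for this row; the printed
percentage column is not reproduced by the stated formula and inputs — see
`docs/methods.md`.)

The same chain is available from the shell:

```
poroshell simulate --table1 --outdir curves --noise-mode multiplicative --noise-level 0.02
poroshell report --indir curves --out summary.tsv
```

## Layout

- `src/poroshell/models.py` — unified, layered-sphere and Stuhrmann forward models
- `src/poroshell/fitting.py` — initial guess, bounded multi-start fit, log–log slope
- `src/poroshell/invariant.py` — tails, invariant, SLDs, composition
- `src/poroshell/synthetic.py` — fixtures, noise models, sphere systems
- `src/poroshell/curves.py` — curve container, file I/O, background/calibration
- `src/poroshell/cli.py` — the `poroshell` command
- `docs/methods.md` — model assumptions, conventions, limitations
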