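# Methods

## Scope and model

`hemoquant` treats plasma photometry as a linear mixture problem. A measured
spectrum is

```
A(λ) = L/DF · [ ε_heme(λ)·c_heme + ε_Hb(λ)·c_Hb + ε_bili(λ)·c_bili ]
     + τ(λ)·T/DF · L/L_ref + interaction term + ε_noise(λ)
```

with pathlength `L` (cm), dilution factor `DF`, concentrations in µM
(hemoglobin in tetramer µM throughout; total heme bookkeeping is
`4·c_Hb + c_labile`), a dimensionless turbidity index `T`, and i.i.d. Gaussian
noise per wavelength. Scalar assay readouts are generated by per-channel
forward models that are the exact inverses of the corresponding evaluation
equations, so `quantify ∘ simulate` is the identity on noise-free data — the
property the test suite leans on.

## Component spectra

The four component shapes are parametric Gaussian-band approximations, not
digitized measured curves:

| species      | bands (center, σ in nm)                  | amplitude calibration |
|--------------|------------------------------------------|-----------------------|
| labile heme  | Soret 380, σ ≈ 31.7 (solved); CT 610, σ 20, 2.5 % | ε(380)·L_ref = 0.029 AU/µM, the direct-curve slope |
| hemoglobin   | Soret 410, σ 16; Q bands 541/577 (10/10.5 %) | solved so the Harboe equation is exact at L_ref |
| bilirubin    | 455, σ ≈ 37.2 (solved)                   | ε(455) = 0.055 AU/µM/cm |
| turbidity    | (700/λ)⁴ Rayleigh-like baseline          | index 1 → 1.0 AU at 700 nm undiluted |

Two deliberate design choices:

* **Harboe-blind widths.** The heme and bilirubin σ are solved numerically
  (Brent's method, |f| ≲ 1e−13) so that `2·g(415) − g(380) − g(450) = 0`.
  The three-wavelength correction is then exactly blind to labile heme and to
  bilirubin, mirroring the empirical robustness of the Harboe method to added
  heme and its applicability to icteric samples, and making zero-noise
  pipeline recoveries exact.
* **Printed intercepts are instrument blanks.** The direct calibration curves
  carry small negative intercepts (−0.170 AU at 380 nm, −0.007 AU at 405 nm)
  that a homogeneous Beer–Lambert spectrum cannot produce (zero composition
  must give a zero spectrum). The spectral amplitudes therefore match only
  the slopes; the printed curves invert exactly against the `direct` readout
  channels, whose forward models include the intercepts (clamped at 0 AU).
  Quantifying *from a spectrum* is exact through a calibration curve fitted
  on simulated standards.

Because the hemoglobin amplitude is anchored to the Harboe constants (which
absorb protocol factors), absolute ε values are self-consistent within the
package rather than literature values; relative band positions and the
ordering of interferences are what the simulator preserves.

## Assay forward models

* **Kit (400 nm):** `A400 = (c_labile + 2.59·c_Hb − 4.85)/25.64`, clamped at
  0 AU. Dilution acts on the assay-side concentration, not linearly on the
  signal: `A400(DF) = ((c_labile + 2.59·c_Hb)/DF − 4.85)/25.64`.
* **Pyridine hemochromogen:** the reduced 556 nm channel encodes total heme
  equivalents exactly, `A556 = 34.1·(4·c_Hb + c_labile)/1000` (1 cm cuvette);
  the 557 nm shoulder is 0.98 of the peak, the oxidized channel 0.30, and the
  540 nm channel is fixed by the published 557−540 difference coefficient
  (23.98 mM⁻¹cm⁻¹). Consequence: the per-tetramer ε(556) = 80.4 mode reads
  high on this generator (it encodes the empirically observed ~1:2.2
  Hb:heme response, an assay artifact, while the simulator's ground truth is
  the stoichiometric 1:4); that mode is validated arithmetically, not by
  round trip.
* **SLS (shifted Soret):** slopes 0.022 AU/µM (heme, 395 nm) and 0.150 AU/µM
  (Hb, 413 nm) with Gaussian-tail cross terms (σ 25 nm → 0.017 and
  0.116 AU/µM), reproducing the known overestimation of hemoglobin in the
  presence of heme.
* **apoHRP:** `signal[nM] = 3.629·c_Hb[nM] + 21.86 + c_labile[nM]`. The
  published hemoglobin cross-reactivity intercept (21.86 nM) is present even
  at zero hemoglobin, so the identity-mapping quantifier recovers labile heme
  only after subtracting that blank; the round-trip test does exactly that.
  Channel noise converts at 100 nM per AU.
* **Harboe triplet:** sampled from the zero-noise mixture spectrum at
  380/415/450 nm (so bilirubin and turbidity flow into it), noise added per
  channel.

The plumbing constants above (557/556 ratio, oxidized ratio, SLS slopes,
apoHRP noise scale) are not published anywhere; they were chosen once as
plate-reader-realistic values and are used only by the generator.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| noise σ | 0.005 | AU | typical plate-reader precision |
| pathlength | 0.58 (200 µL), 0.29 (100 µL) | cm | well-geometry estimates; configurable |
| dilution grid | {1, 2, 4, …, 128} | — | powers of two covering reported factors up to ~72 |
| dilution target | max A(340–700) < 1.0 | AU | photometric linearity |
| linearity tolerance | 15 | % | ICH-style acceptance; exactly-15 % passes |
| hemolysis grades | < 5 non-hemolytic, > 100 severe | µM Hb | strict outer inequalities; 5 and 100 are mild |
| lipemia threshold | 0.3 | AU at 700 nm, undiluted scale | qualitative "milky/turbid" criterion made operational |
| icterus rule | strict local max in 445–465 nm after 5 nm smoothing, prominence ≥ 0.02 AU | — | the prominence floor guards the strict-neighbor rule against flat noisy baselines |
| LOD/LOQ | 3.3σ/S, 10σ/S | analyte units | ICH Q2 convention |

Panel generator states (log-uniform µM ranges): non-hemolytic Hb 0.3–5 /
heme 1–20; mild Hb 5–100 / heme 20–250; severe Hb 100–1080 / heme 154–1056;
icteric Hb 0.3–3 / heme 30–44 / bilirubin 50–300; lipemic turbidity 0.5–3.
These are the study conditions, not tuning dials.

## The combined estimator and its parse

`c_labile = DF·25.64·A400 − 2.59·c_Hb/DF + 4.85` is ambiguous about what DF
multiplies. The `printed` parse implements it exactly as written under
standard precedence and is the default; the `bracketed` parse,
`DF·(25.64·A400 + 4.85) − 2.59·c_Hb`, is the exact inverse of the diluted kit
response and is the one that recovers truth exactly for DF > 1. Both coincide
at DF = 1, where all canonical tests and the spiked-recovery experiment run
(the kit channel is measured undiluted there; the <1.0 AU dilution rule is
applied to plasma spectra and, in panel analysis, to the kit channel with its
own recorded DF). The +4.85 µM intercept means a blank sample still reports
4.85 µM; the estimate is reported with a below-range flag rather than being
blank-subtracted or clamped, and negative estimates are flagged, never
zeroed (truncation would bias recovery statistics).

## Numerical choices

* Band-width solves: `scipy.optimize.brentq`, xtol 1e−13; residual Harboe
  leakage of non-Hb species is below 1e−9 µM per µM.
* Linearity boundary: deviation ≤ tolerance + 1e−9 % (floating-point guard);
  ties between equally long compliant runs go to higher concentrations;
  verdict requires ≥ 3 compliant levels.
* Mean-recovery SD is the sample (n−1) standard deviation; a single pair
  returns 0.
* "Exact" zero-noise identities are asserted at 1e−9…1e−12 relative
  (floating-point arithmetic, not analytic equality).
* All randomness flows through `numpy.random.default_rng` from a single seed;
  panel samples get child seeds drawn from the master generator, so outputs
  are bit-reproducible.

## What the generator does and does not emulate

It emulates: multicomponent Soret-region overlap, hemoglobin interference in
the kit and apoHRP channels, the heme-blindness of the Harboe combination,
bilirubin and turbidity interference, dilution behavior with non-zero
intercepts, and seeded plate-reader noise. It does **not** emulate: real
(non-Gaussian) band shapes or pH/matrix shifts, hemoglobin autoxidation or
degradation products, haptoglobin/hemopexin binding, chromatograms or mass
spectra, enzyme kinetics of peroxidase substrates, or turbidity effects on the
scalar kit channel (lipemic samples are excluded from quantification anyway).
Passing tests therefore demonstrate internal consistency of the evaluation
equations and pipeline logic under the stated noise model — not the field
performance of the assays on real plasma.

## Known limitations

* The hyperchromic Hb–heme interaction is an opt-in additive cross term at
  405 nm with a free coefficient (magnitude unquantified); it defaults to off.
* The Harboe 0.155 factor is treated as an opaque printed constant (whether it
  encodes a protocol dilution or a unit conversion is not stated).
* HPLC registry ranges are stored in the printed pmol units although the
  stated µM equivalents imply nmol; the discrepancy is flagged in the entry
  note rather than resolved.
* The pyridine operation takes a single reduced-state reading; the choice of
  time point within the reduction series is left to the caller.
* Semi-quantitative strip results are three bins with closed bounds; no
  attempt is made to model color intensity.
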