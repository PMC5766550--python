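# Methods

## Scope and data flow

`predose` implements the standard preclinical-to-clinical dosimetry chain
for a ⁶⁴Cu-labelled antibody: biodistribution quantification (%ID/g),
trapezoidal time-integrated activity, relative-organ-mass extrapolation to
an adult-male phantom, MIRD S-value dose weighting, ICRP-26/60 summary
doses, and administrable-activity limits. Radiochemistry, image
reconstruction and ROI segmentation are upstream of this package: it
consumes ROI-derived or gamma-counter tables, and S-values are consumed as
data, never re-derived.

## Synthetic cohort generator

The generator emulates two study designs: an NSG mouse bearing an
hPD-1-expressing 293T xenograft (PET ROIs, reported decay-corrected) and a
humanized (hPBMC-engrafted) NSG mouse bearing an A375 melanoma infiltrated
by hPD-1⁺ lymphocytes (reported non-decay-corrected). Each has a
receptor-blocked (`blk`) and non-blocked (`nblk`) arm, n = 4/group,
7.4 MBq injected into a 23 g mouse, PET sampling at {1, 2, 4, 18, 24, 48} h
and ex-vivo sampling at {1, 12, 24, 48} h.

**Kinetic form.** Each organ follows a two-rate rise-and-decay curve
`u(t) = β^[blocked]·A·(e^(−λ_c t) − e^(−λ_u t))/peak`, normalised so `A`
is the peak biological uptake in %ID/g. This is the simplest form that
rises and then clears monotonically, matching published organ profiles.
Physical decay (T½ = 12.7 h) multiplies by `2^(−t/T½)` when values are
reported non-decay-corrected.

**Calibration.** The shipped kinetics are anchored to published uptake
values at their reporting times and conventions; amplitudes are derived by
inverting the unit-amplitude curve at the anchor, so noise-free curves hit
the anchors exactly (e.g. humanized-model heart/liver/spleen
1.62/1.10/1.18 %ID/g at 24 h non-decay-corrected; xenograft 8.2 and
14.8 %ID/g decay-corrected at 24/48 h). Time constants encode the expected
physiology: the heart ROI is a clearing blood pool (fast uptake,
λ_c ≈ 0.02–0.035 h⁻¹), the liver retains (slow clearance), and spleen/tumor
accumulate via receptor binding (slow uptake). Blocking factors β are the
published blocked/non-blocked ratios per organ; organs without a receptor
component keep β = 1. One known limitation: the single rise-and-decay form
cannot simultaneously satisfy the xenograft's 4 h value and its sustained
24→48 h growth, so the curve is calibrated to the 24/48 h anchors and
underestimates the 4 h point (~1.5 vs 2.9 %ID/g) — late times dominate the
dose integral, so this does not affect the dosimetry conclusions.

**Noise.** Multiplicative lognormal with shape σ = 0.10 by default, chosen
so the coefficient of variation matches the ~5–15% SD/mean ratios typical
of %ID/g data. %ID/g is positive with roughly proportional error, which an
additive model would violate at low uptake.

**What the generator does not emulate:** partial-volume effects (an
optional per-organ recovery coefficient is accepted but defaults to 1),
inter-animal kinetic heterogeneity (noise is per-measurement, not
per-animal), ROI segmentation error, and any immune-cell population
dynamics. Passing tests therefore demonstrate the correctness of the
computational chain under known kinetics, not the biological fidelity of
any particular curve.

## Quantification conventions

%ID/g is `100·(counts − background)/(injected-dose counts · organ mass)`;
the occasionally-seen shorthand "injected dose divided by organ weight" is
read this way as the only dimensionally consistent definition. Decay
correction and un-correction are exact inverses (`2^(±t/T½)`) and every
value carries its state as a flag; published ex-vivo conventions are
ambiguous between the two states, so both are supported and tracked rather
than assumed. Group comparisons use the classical pooled-variance
(Student) unpaired two-tailed t test, not Welch, matching the stated
analysis of the anchor data. Tumor volumes use the ellipsoid
`V = πhwl/6`, with `h = 2l/3` when height cannot be measured.

## Time-integrated activity

Integration runs over `[(0,0)] ∪ samples` of the non-decay-corrected
fraction curve. The (0,0) anchor reflects intravenous injection (organ
activity starts at zero); it makes the rule first-order accurate in the
first sampling interval, which the tests account for. Three tail modes are
exposed because the behaviour beyond the last sample (48 h) is not
observable: `physical_decay` (default — biological retention assumed,
conservative in the sense of over-estimating dose), `zero` (truncation,
lower bound), and `fitted_exp` (log-linear biological rate from the last
≥2 points, floored at zero). For non-increasing late-time data
`zero ≤ fitted_exp ≤ physical_decay` always holds. Residence times are
bounded by T½/ln2 = 18.32 h, enforced at construction.

## Interspecies scaling

The relative-organ-mass method:
`(%ID/organ)_human = (%ID/g)_mouse · M_body,mouse · M_organ,human / M_body,human`.
The scaling is isolated in one operation so an alternative convention
(e.g. without the body-mass ratio) can be swapped. Scaling is applied per
time point and then integrated; both operations are linear so the order is
immaterial (asserted by test). The packaged phantom is the classical
73.7 kg adult male with standard organ masses. The heart ROI of an intact
antibody is blood-pool dominated, so it feeds the `heart_contents` source
(not the heart wall); a separate ex-vivo blood sample would double-count
that pool and is excluded from scaling, as is the tumor (no phantom
counterpart) — both are reported separately rather than dropped silently.

## Dose engine

`D_T = Σ_S τ_S·S(T←S)`, linear in the residence times, with missing
(target, source) pairs raising rather than being dropped. For tests and
qualitative end-to-end runs a *synthetic* Cu-64 S-value generator is
shipped (production work should load a published table): non-penetrating
energy (0.125 MeV/decay) absorbed in the source organ, with a 0.10
absorbed fraction from heart contents into the wall; penetrating energy
(0.186 MeV/decay, dominated by annihilation photons) with self-absorbed
fraction `min(0.35, 0.0137·m_g^⅓)` and a uniform whole-body cross-fire
term (whole-body photon absorbed fraction 0.30). These first-order values
reproduce the qualitative structure of phantom S-value tables (self-dose
dominance, liver over spleen once residence times are mass-scaled) without
claiming Monte Carlo accuracy.

**ICRP-60 effective dose:** gonads = testes (adult-male reporting),
colon = mass-weighted ULI/LLI combination, thymus as esophagus surrogate,
remainder = 0.05 × mass-weighted mean over
{adrenals, brain, small intestine, kidneys, muscle, pancreas, spleen,
thymus, uterus} (intersected with available doses). **ICRP-26 effective
dose equivalent:** named tissues (gonads 0.25, breasts 0.15, red marrow
0.12, lungs 0.12, thyroid 0.03, bone surfaces 0.03) plus 0.06 for each of
the five highest-dosed remaining organs; skin, the gonad organs and
whole-body summary rows are not remainder candidates. Weights must sum to
exactly 1, enforced at load.

Applied to the packaged reference coefficient table, these conventions
recompute the published summary rows within 1.5% (ED) and 3.3% (EDE)
across all four columns; the residual reflects the unpublished remainder
bookkeeping of the original phantom software. Note that the table's prose
context swaps the "effective dose" and "effective dose equivalent" labels
relative to the table itself; this package follows the table (ED ≈ 2.4,
EDE ≈ 4.3 µSv/MBq for the PET/CT blocked arm).

## Limits and administrable activity

Defaults: 50 mSv annual / 30 mSv single-study for whole body (applied to
the effective dose) and 150 mSv annual / 50 mSv single-study for other
organs (applied to the maximum organ dose). All four limit/coefficient
quotients are reported plus the binding minimum; the widely quoted
1.42/1.33 GBq values arithmetically equal the *single-study organ* limit
over the liver coefficient even when described as annual, so the package
reports every combination and leaves the label to the user. A
`scans_per_year` figure at a configurable per-scan activity (default
185 MBq) is included.

## Problem sizes and determinism

Default runs use n = 4 animals/group, 6 (PET) or 4 (ex-vivo) time points,
and 5–8 organs per model; convergence tests refine pure-decay curves up to
2·10⁴ samples. Everything is seeded through `numpy.random.default_rng`;
identical config + seed gives byte-identical tables. The full test suite
runs in a few seconds on one CPU.

## Known limitations

* The synthetic S-matrix is first-order physics, not phantom Monte Carlo;
  absolute synthetic-pipeline doses are indicative (liver ~15–19 µSv/MBq)
  rather than matching published coefficients (~33–38 µSv/MBq).
* No allometric time-scaling: only amplitudes are scaled to the human, as
  in the relative-organ-mass method; antibody kinetics in humans are
  slower, which this method does not capture.
* Single-compartment organ kinetics; no compartmental ODE or voxel-level
  modelling.
* The remainder-of-body source is zero unless a whole-body curve is
  supplied (warned, never silently assumed).
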