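# Methods

## Model

The package implements a microdosimetric-kinetic description of radiation
action.  The nucleus is partitioned into spherical domains (radius `r_d`,
density `rho`, water by default).  Potentially lethal lesions are produced in
proportion to the specific energy per domain and either convert to lethal
lesions (LLs) — first-order misrepair, or second-order pairwise interaction —
or are repaired, with the repair/first-order conversion rates entering only
through the composite `a_plus_c` (h⁻¹).  Solving the lesion kinetics yields
the mean LL count

    <w>(D) = (alpha0 + z1dstar * beta0) * D + F * beta0 * D**2,
    S = exp(-<w>),  F_MN = h_mn * <w>.

The micronucleus extension is the single parameter `h_mn`: the probability
that an LL transformation leaves a micronucleus.  It makes the MN frequency
exactly proportional to −ln S — an identity the code preserves to machine
precision because `mn_frequency` is literally `h * mean_lethal_lesions`.
Everything the model says about MN therefore reduces to that
proportionality plus the survival model; the MN-based RBE (initial-slope
ratio) is independent of `h_mn` by construction, while the D10-based
survival RBE is *not* invariant under joint rescaling of (alpha0, beta0) by
1/h — the two agree only in the alpha-dominated limit.

### Radiation quality

`z1dstar = k * ystar / (rho * pi * r_d**2)` with `k = 1.602176634e-16 J/keV`
(exposed as `microdosimetry.JOULE_PER_KEV`), and

    ystar = y0**2 * Int[1 - exp(-(y/y0)**2)] f(y) dy / Int y f(y) dy.

Defaults: `y0 = 150 keV/um`, `r_d = 0.42 um`, `rho = 1000 kg/m^3`.  Spectra
are tabulated; all integrals use the trapezoidal rule on the supplied grid
(no functional form is promised by microdosimetry files), and single-line
spectra are treated as point masses so the closed form
`ystar = y0**2 (1-exp(-(y/y0)**2))/y` is reproduced exactly.  Note that
`ystar(LET)` rises roughly linearly below `y0`, peaks near `1.1*y0` and then
*declines* — the decline is the overkill effect, and RBE-versus-LET curves
built from it correctly rise and fall.

The parametric spectrum generator is a lognormal in `y` with median tied to
the nominal LET and relative spread `width`.  It is test scaffolding
standing in for transport-code tallies: only low-order moments of `f(y)`
enter the saturation integral, so any positive unimodal family suffices.
It does not emulate track-structure physics, energy straggling, or the
photon/ion shape differences of real tallies — conclusions about absolute
LET placement of predictions should not be drawn from it.

### Dose protraction

For piecewise-constant dose rates the Lea–Catcheside factor is evaluated in
closed form per segment pair:

* within a segment: `R^2 T^2 g(kT)/2` with `g(x) = 2(x + e^-x - 1)/x^2`;
* between ordered segments separated by a beam-off gap `G`:
  `R_i R_j (1-e^{-kT_i})(1-e^{-kT_j}) e^{-kG} / k^2`.

`g` switches to its series `1 - x/3 + x^2/12` below `x = 1e-4` to avoid
cancellation; the acute limit `F -> 1` as `T -> 0` is exact.  Instantaneous
fractions are represented as short finite segments (the `acute` constructor
uses 1 ms), keeping a single code path; the textbook split-dose form
`(1 + e^{-k dt})/2` and a brute-force numerical double integral serve as
independent oracles in the tests.  Fractionated regimens carry an explicit
`t_end` so the average dose rate includes the trailing interval (a 4 Gy,
0.05 Gy/fraction regimen averages exactly 0.05 Gy/min); `t_end` never
affects `F`, which sees only beam-on segments.

Iso-effect doses use the rationalised quadratic root
`D = 2 S* / (sqrt(alpha^2 + 4 beta S*) + alpha)`, stable for `beta -> 0`.

## Inference

The likelihood is Gaussian on the fitting scale: −ln S for survival data,
the expected count for MN data (MN-bearing-cell *fractions* are fitted only
through the opt-in Poisson link `F_MN = -ln(1 - fraction)`; the transform is
never applied silently because absolute MN frequencies are assay-protocol
dependent).  Sampling is plain Metropolis under uniform priors (defaults:
alpha0 ∈ [0,2] Gy⁻¹, beta0 ∈ [0,0.5] Gy⁻², a+c ∈ [0.05,10] h⁻¹, h ∈ [0,1]),
10³ burn-in and 10⁴ retained samples.

Noise model (`sigma_policy`):

* `"pooled"` (default) — one constant sigma on the fitting scale, estimated
  from preliminary weighted-least-squares residuals with a degrees-of-freedom
  correction.  This matches homoscedastic log-scale scatter, which is what
  multiplicative (constant-CV) survival noise produces on −ln S.
* `"relative"` — sigma_i proportional to the fitted mean (floored at 5% of
  the curve maximum), the correct weighting when scatter is a constant
  coefficient of variation, as in MN scoring.
* `"per-point"` — experimental SDs as given.  Use with caution: SDs
  estimated from very few replicates are chi-square-noisy weights and can
  bias the fit substantially (observed up to several posterior SD with
  3 replicates).
* Naming `"sigma"` in the priors samples the noise scale jointly with the
  model parameters (it multiplies the policy's shape vector).  This is the
  configuration used by the reference recovery studies: treating sigma as
  known-but-estimated makes posteriors slightly anti-conservative, whereas
  sampling it restores near-nominal frequentist calibration of the
  2-posterior-SD interval.

Proposal: Gaussian random walk by default, with per-parameter steps sized
`2.38/sqrt(k)` times the Gauss–Newton posterior SD estimate from a weighted
least-squares pre-fit (clipped to [1e-6, 0.5] of the prior width; 5% of the
width where the covariance is singular).  The chain starts at the pre-fit
point.  An independence sampler drawing candidates from the prior itself is
available (`proposal="prior-independence"`); it is exact and convenient for
prior-recovery checks, but on realistic dose-response posteriors it accepts
~10⁻³–10⁻⁴ of proposals and cannot traverse the posterior within 10⁴
iterations, which is why it is not the default.  Chains are bit-reproducible
given the seed; a chain that accepts nothing raises a diagnostics error
rather than returning a frozen posterior.

`estimate_h` fits the through-origin proportionality `F_MN = h * w` either
by closed-form weighted least squares or by the same Metropolis machinery
(default, for SD parity with the dose-response fits).  `calibrate_rd` is a
deterministic grid search: for each candidate radius it recomputes `z1dstar`
for every dataset's spectrum and accumulates the residual sum of squares at
the base-fit coefficients; ties break toward the smaller radius, and a flat
profile (photon-only data, where `z1dstar ≈ 0` regardless of radius) is
reported with a warning rather than a spurious argmin.  Credible bands are
pointwise equal-tailed quantiles of the prediction evaluated over all
posterior draws.

## Synthetic data

The generators emulate the assays the model is normally fitted to:

* survival — lognormal multiplicative noise on S, CV 15% by default
  (typical clonogenic-assay scatter), i.e. Gaussian noise on −ln S;
* MN — Gaussian relative noise, CV 10% by default, or Poisson sampling of
  MN counts over a configurable number of scored cells (default 200 per
  culture);
* 3 replicate cultures per dose point; the tabulated value is the replicate
  mean and the recorded SD its standard error;
* dose-zero rows are normalisation controls and are emitted noiseless
  (S ≡ 1, MN ≡ 0), mirroring how survival is normalised to unirradiated
  controls;
* default dose grid 0–8 Gy in 1 Gy steps, covering the range where both LQ
  coefficients are identifiable;
* the four dose-rate regimens (continuous 1 Gy/min; 0.5 Gy/fraction with
  30 s on/30 s off; 0.1 Gy/fraction, 6 s/54 s; 0.05 Gy/fraction, 3 s/57 s)
  are built exactly, all delivering the requested total dose.

What the generators do *not* emulate: plating-efficiency drift, cell-cycle
redistribution, bystander signalling, inverse dose-protraction effects, or
assay-protocol differences in MN scoring.  Passing recovery tests therefore
demonstrates internal consistency of model + sampler at realistic noise,
not robustness to those biological confounders.

## Reference recovery studies (`imkmn.studies`)

Each study simulates data from a published parameter set and refits it with
the full sampler (10³ burn-in, 10⁴ samples; sigma sampled jointly):

* pooled MN-formation probability `h = 0.275` from 50 (−ln S, MN) pairs
  spanning −ln S ∈ [0.1, 4] with 10% noise;
* HSG photon survival (alpha0, beta0) from 9 doses × 3 replicates, CV 15%;
* HSG repair rate (a+c = 2.19 h⁻¹) from continuous exposures over
  0.05–4 h at 0/4/8 Gy (the protraction factor of a continuous exposure
  depends on duration only, so one schedule serves all doses of a duration);
* WI-38 repair rate (a+c = 0.371 h⁻¹) from the four dose-rate regimens plus
  2/6/12 h continuous exposures, all at 4 Gy total;
* MN-side HSG coefficients (alpha_m0 = 0.0375, beta_m0 = 0.0113) from
  9 doses × 3 replicates, CV 10%, relative sigma policy.

A known limitation, reported as measured: the WI-38 study design fixes the
total dose at 4 Gy, so rescaling beta0 absorbs almost the entire
protraction pattern across schedules and the repair rate is only weakly
identified — with noiseless data the posterior collapses onto the
generating value (verifying the machinery), but at 15% CV the (a+c)
posterior is dominated by the prior (mean ≈ 5–7 h⁻¹, SD ≈ 2), typically
2–4 posterior SD from the generating 0.371 h⁻¹.  Identifying a slow repair
rate from survival data requires dose variation under protraction, not
dose-rate variation at a single dose.

Credible-band calibration is checked on a small tractable design (six
doses, known Gaussian noise on −ln S, 200 seeded replicates); the
design-averaged pointwise coverage of the 68%/95% bands sits within five
points of nominal (per-dose estimates carry ~3-point Monte-Carlo noise at
200 replicates).

## Numerical and design choices

* Unit handling is explicit: keV/µm → Gy conversion uses the CODATA
  elementary charge; doses in Gy, times in hours, rates in Gy/h.
* Spectra are renormalised on construction; dose-weighted d(y) input is
  converted via `f ∝ d/y` behind an explicit flag (both dialects circulate).
* The fitting minimum of three records applies to the joint fit problem
  (datasets fitted together), since dose-rate designs contribute one
  measured dose per schedule.
* The survival level of the iso-effect RBE is configurable
  (`rbe_sf(..., survival=...)`); 10% is the default convention.
* Workflows embed the seed, a config hash and the package version in every
  report; all stage seeds derive from the one top-level seed.

## Known limitations

* Single-chain sampling with acceptance-rate diagnostics only; no
  Gelman–Rubin machinery (export the draws to `arviz` for more).
* The stochastic (domain-by-domain specific energy distribution) variant of
  the model and bystander terms are out of scope.
* Absolute `h_mn` values are MN-assay-protocol dependent; cross-protocol
  predictions should re-estimate `h_mn` rather than reuse a published value.
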