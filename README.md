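# imkmn — microdosimetric-kinetic modelling of cell survival and micronuclei

`imkmn` implements an extended integrated microdosimetric-kinetic (IMK) model
for radiation biology: a mechanistic dose-response model that predicts both
clonogenic cell survival and the frequency of radiation-induced micronuclei
(MN) from one set of cell-line parameters, across absorbed dose, radiation
quality (LET) and dose rate.  It is aimed at radiobiologists and medical
physicists who fit survival or MN assay data, compute relative biological
effectiveness (RBE), or plan dose-rate/fractionation analyses.

## The model

The cell nucleus is divided into sub-micrometre domains of radius *r*_d.
Radiation induces potentially lethal lesions in proportion to the specific
energy deposited in each domain; these convert into lethal lesions (LLs) by
misrepair or pairwise interaction, or are repaired at composite rate
(*a*+*c*).  The mean number of LLs per nucleus after dose *D* is

    <w> = (α₀ + z₁D* β₀) D + F β₀ D²,        S = exp(−<w>)

where

* **z₁D\*** = *y*\*/(ρ π *r*_d²) is the saturation-corrected dose-mean
  specific energy carrying radiation quality, with
  *y*\* = y₀² ∫[1−exp(−y²/y₀²)] f(y) dy / ∫ y f(y) dy computed from the
  lineal-energy distribution f(y); the saturation parameter y₀
  (150 keV/µm by default) expresses the overkill effect at very high LET;
* **F** is the Lea–Catcheside dose-protraction factor, computed in closed
  form for arbitrary piecewise-constant delivery schedules (continuous,
  split-dose, multi-fraction), which discounts the quadratic term when
  sublethal damage is repaired during protracted delivery.

Micronuclei are assumed to form during LL transformation with probability
*h*, so the expected MN count per cell is exactly proportional to the
lethal-lesion count:

    F_MN = h <w>,   with α_m0 = h α₀ and β_m0 = h β₀.

Consequently the MN-based RBE (initial-slope ratio, independent of *h*) and
the survival RBE (ratio of 10%-survival doses D₁₀) probe the same underlying
quantity.  Parameters are estimated by Metropolis MCMC with uniform priors
and a Gaussian likelihood on −ln S (or on the MN count), and posterior draws
are propagated into pointwise credible bands for any derived prediction.

## Worked example

```python
import numpy as np
from imkmn import (cell_lines, generate_spectrum, compute_ystar, compute_z1dstar,
                   DomainGeometry, RadiationQuality, surviving_fraction, mn_frequency,
                   rbe_mn, d10, FitConfig, mcmc_fit, simulate_survival_dataset, NoiseModel)

hsg = cell_lines.HSG                          # published HSG parameter set
geom = DomainGeometry(r_d=hsg.r_d)            # 0.42 um water domain, y0 = 150 keV/um
spec = generate_spectrum("ion-like", let=100.0, width=0.3)
ystar = compute_ystar(spec, geom.y0)
carbon = RadiationQuality(compute_z1dstar(ystar, geom), label="100 keV/um carbon")
photon = RadiationQuality(0.0)

print(f"y* = {ystar:.1f} keV/um, z1D* = {carbon.z1dstar:.2f} Gy")
print(f"S(2 Gy, photon) = {surviving_fraction(hsg, photon, 2.0):.3f}")
print(f"S(2 Gy, carbon) = {surviving_fraction(hsg, carbon, 2.0):.3f}")
print(f"F_MN(2 Gy, photon) = {mn_frequency(hsg, photon, 2.0):.3f} MN/cell")
print(f"RBE_MN = {rbe_mn(hsg, carbon, photon):.2f}")
print(f"D10(photon) = {d10(photon.alpha(hsg), hsg.beta0):.2f} Gy")

# fit synthetic clonogenic data back with the Metropolis sampler
data = simulate_survival_dataset(hsg, noise=NoiseModel("lognormal_s", 0.15, 3, seed=7))
cfg = FitConfig(priors={"alpha0": (0, 2), "beta0": (0, 0.5), "sigma": (1e-3, 1.0)}, seed=7)
post = mcmc_fit(data, cfg, "survival")
for name, s in post.summary().items():
    print(f"{name}: {s['mean']:.4f} +/- {s['sd']:.4f}")
```

Output:

```
y* = 82.3 keV/um, z1D* = 23.81 Gy
S(2 Gy, photon) = 0.615
S(2 Gy, carbon) = 0.067
F_MN(2 Gy, photon) = 0.134 MN/cell
RBE_MN = 8.41
D10(photon) = 5.60 Gy
alpha0: 0.1654 +/- 0.0277
beta0: 0.0458 +/- 0.0042
sigma: 0.0928 +/- 0.0309
```

Reading the numbers: a 100 keV/µm carbon-like beam deposits z₁D\* ≈ 24 Gy of
saturation-corrected specific energy per unit dose in a 0.42 µm domain,
boosting the effective linear coefficient from 0.150 to ≈ 1.26 Gy⁻¹ — at
2 Gy survival drops from 61.5% (photons) to 6.7%, an initial-slope RBE of
8.4 (the *maximum* RBE; the D₁₀-based survival RBE is lower).  The MN
frequency is h = 0.275 times the lethal-lesion count: 0.134 MN per cell at
2 Gy of photons.  The Metropolis fit of a noisy synthetic survival
experiment (9 doses × 3 replicates, 15% CV) recovers the generating
parameters (α₀ = 0.150 Gy⁻¹, β₀ = 0.0467 Gy⁻²) within one posterior SD.

## Command line

```bash
imkmn simulate --params hsg.json --endpoint sf --seed 1 --out sf.csv
imkmn fit --data sf.csv --endpoint sf --out report.json
imkmn predict --params hsg.json --spectrum carbon.txt --doses 0:10:0.5
imkmn rbe --params hsg.json --spectrum carbon.txt --endpoint mn
imkmn workflow-sf2mn --data sf.csv --h 0.275 --outdir out/
```

Exit codes: 0 success, 2 validation failure, 3 numerical failure.

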