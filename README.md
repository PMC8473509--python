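# spectiq

A fully synthetic, testable re-creation of an absolute-quantification
phantom study on a CZT-detector SPECT/CT system: how do acquisition
parameters (photopeak energy window, acquisition time per frame) and
reconstruction parameters (OSEM iterations and subsets, Gaussian
post-filter width, attenuation / scatter / resolution-recovery
corrections) change the measured activity concentration of hot spheres in
the NEMA IEC body phantom?

It is aimed at nuclear-medicine physicists and image-reconstruction
researchers who want a deterministic, seedable desk-scale sandbox for
quantitative SPECT protocol questions — no scanner, no vendor workstation,
every stage inspectable.

## What it computes

For each hot sphere *j* of the phantom (inner diameters 37, 28, 22, 17, 13
and 10 mm, filled at target-to-background ratios 32:1, 16:1, 8:1 or 4:1):

```
RC_j   = 100 % · C_H,j / a_H                      recovery coefficient
Q_H,j  = 100 % · (C_H,j/C_B,j − 1)/(a_H/a_B − 1)  percent contrast
N_j    = 100 % · SD_j / C_B,j                     background variability
```

where `C_H,j` is the mean reconstructed concentration in the sphere VOI,
`a_H`/`a_B` the true hot/background concentrations, and `C_B,j`, `SD_j`
the mean and standard deviation of NEMA NU 2-style background ROI means.
The reconstruction is OSEM — maximum-likelihood estimation of the Poisson
count model `y ~ Poisson(A x + s)` via the multiplicative update
`x ← x/(Aᵀ1) · Aᵀ(y/(Ax+s))` cycled over angular view subsets — where the
system operator `A` optionally contains the attenuation map (AC) and the
depth-dependent collimator response (RR), and `s` is a dual-energy-window
scatter estimate `k·(W_pp/W_sc)·C_sc` (SC).

The pipeline is: digital NEMA IEC phantom (activity, μ-map, labels) →
rotation-based projector with Beer–Lambert attenuation and depth-dependent
Gaussian blur → stationary-kernel scatter plus Poisson noise in photopeak
and scatter energy windows → OSEM with switchable corrections and Fourier
Gaussian post-filter → VOI/ROI quantification → parameter sweeps with
Pearson correlation, linear regression, paired t-tests and convergence
detection.

## Worked example

```python
import spectiq as sq

phantom = sq.build_phantom(sq.desk_spec(tb_ratio=32.0, sphere_concentration=0.20))
proj = sq.simulate(phantom, sq.AcquisitionConfig(bin_size=5.5, seed=1))
cfg = sq.ReconConfig(iterations=16, subsets=12)   # corrections default AC+SC+RR
result = sq.OSEMModel(proj, phantom.mu_map, cfg, phantom.spec.voxel_size).fit()
print(sq.quantify(result.volume, phantom).summary())
```

prints (seed 1):

```
Quantification results
======================
a_H = 0.2 MBq/ml   a_B = 0.00625 MBq/ml   T/B = 32
 diameter_mm    RC     Q   COV  mean   sd
       37.00 90.20 88.67  8.52  0.18 0.05
       28.00 88.45 86.98 11.08  0.18 0.06
       22.00 80.02 77.75 13.38  0.16 0.07
       17.00 81.51 78.77 15.63  0.16 0.06
       13.00 71.39 68.46 21.81  0.14 0.02
       10.00 49.07 45.01 21.29  0.10 0.01
```

Reading: the 37 mm sphere recovers ~90 % of its true 0.20 MBq/ml
concentration at this partially converged setting, while the 10 mm sphere
recovers only ~50 % — the partial-volume effect. Percent contrast `Q`
tracks RC closely for hot spheres on a cold-ish background, and the
background variability `COV` grows as iterations amplify noise.

The same chain is scriptable from a shell:

```
spectiq phantom --tb-ratio 32 --sphere-conc 0.20 --voxel 5.5 --grid 64 64 32 --out ph/
spectiq simulate --phantom ph/ --window 15 --time 120 --seed 1 --out pr/
spectiq reconstruct --proj pr/ --phantom ph/ --iterations 16 --subsets 12 --out re/
spectiq quantify --recon re/ --phantom ph/ --out quant.csv
spectiq run-study --seed 7 --out study/     # six-step sequential protocol
```

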