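# petfda

Nonparametric, compartment-model-free quantification of dynamic PET
scans by functional principal component analysis (FPCA) and
deconvolution against a known arterial input function.

## The problem

A dynamic PET scan measures, in every voxel *i*, a noisy time–activity
curve driven by the arterial tracer concentration *I(t)*:

    C_i(t) = (I ⊗ M_i)(t) = ∫₀ᵗ I(t−s) M_i(s) ds,

where *M_i* is the tissue impulse-response function (IRF).  The
quantity of clinical interest is the volume of distribution

    V_T(i) = ∫₀^τ M_i(t) dt,

a proxy for receptor availability.  Conventional analyses assume
first-order compartmental kinetics; this package instead recovers
*M_i* nonparametrically, which is both more robust to model
misspecification and dramatically cheaper than voxel-by-voxel
deconvolution: the sample of decay-corrected curves is expanded in a
multiplicative Karhunen–Loève model

    C_i(t) = A_{i0} μ(t) + Σ_k A_{ik} φ_k(t),

and because convolution is linear, only the mean μ and a handful of
eigenfunctions φ_k ever need to be deconvolved — a few triangular
least-squares solves for a whole brain volume.  Voxelwise IRFs and V_T
maps then follow by linear combination of the deconvolved basis.

The pipeline comprises

1. **presmoothing** — local-linear kernel smoothing over space and
   time with a locally adaptive temporal bandwidth, calibrated by
   leave-one-voxel-out cross-validation;
2. **multiplicative FPCA** — unsmoothed cross-sectional mean,
   per-voxel multiplicative coefficients A_{i0}, eigen-decomposition of
   the residual covariance, per-voxel scores, and an R²-increment rule
   (threshold 0.025) that picks each voxel's number of components;
3. **deconvolution** — the convolution integral discretized as a
   lower-triangular matrix on an equispaced grid (m = 250 by default),
   solved once for the mean and once per eigenfunction;
4. **V_T mapping** — V_T(i) = A_{i0}·∫μ̂ᵈ + Σ_k A_{ik}·∫φ̂_kᵈ.

The package also ships the comparator baselines used in benchmarking
(curve-by-curve deconvolution and NNLS spectral analysis on an
exponential basis) and two synthetic-data generators (a 1D functional
simulation and a 2D kinetic phantom with compartmental or
survival-function IRFs, PSF blur and signal-proportional noise), so the
entire workflow can be exercised without any measured data.

## Worked example

```python
import petfda as pf

# simulate a noisy two-region dynamic phantom (2 mm pixels, 32 frames)
regions = [pf.RegionSpec(2, 2048, alphas=(0.0060,), betas=(0.0030,)),
           pf.RegionSpec(3, 1200, alphas=(0.0040, 0.0023), betas=(0.0008, 0.0103))]
cfg = pf.PhantomConfig(grid_shape=(64, 64), regions=regions, seed=7)
scan, truth = pf.simulate_phantom_scan(cfg)

aif = pf.synthetic_input_function(tau=scan.frame_times[-1])
pipe = pf.PipelineConfig(scan=scan, input_function=aif,
                         smoother=pf.SmootherConfig(n_replicates=50, seed=7),
                         seed=7)
res = pf.run_pipeline(pipe)

print(f"retained eigenfunctions : {res.log['n_components_retained']}")
print(f"deconvolutions performed: {res.log['n_deconvolutions']}")
print(f"calibrated (h_z, beta)  : ({res.log['h_z']}, {res.log['beta']})")
labels = truth.labels[scan.mask]
for r in (2, 3):
    sel = labels == r
    print(f"region {r}: mean V_T = {res.result.vt[sel].mean():.3f} "
          f"(simulated truth {truth.vt[scan.mask][sel].mean():.3f})")
```

prints

```
retained eigenfunctions : 10
deconvolutions performed: 11
calibrated (h_z, beta)  : (6.0, 0.75)
region 2: mean V_T = 2.238 (simulated truth 1.994)
region 3: mean V_T = 5.016 (simulated truth 5.144)
```

Eleven deconvolutions quantified 3248 voxels.  The above-mean-V_T
region is recovered to ~2.5%; the below-mean region shows the upward
shrinkage that per-voxel component truncation induces at this noise
level (see `docs/methods.md`, *Known limitations*).

Real scans enter the same way through the command line:

```sh
petfda run --scan scan.nii.gz --frames frames.tsv --aif aif.tsv \
           --mask mask.nii.gz --out results/ --seed 1
petfda simulate-phantom --out simdata/ --seed 1
petfda baseline spectral --scan scan.nii.gz --frames frames.tsv \
           --aif aif.tsv --out results/
```

`frames.tsv` holds `frame_start_s`/`frame_end_s` columns; `aif.tsv`
holds `time_s`/`activity`.  Outputs are NIfTI maps (V_T, A0, L, R²),
TSV tables of the raw and deconvolved basis, and a JSON run log with
every resolved parameter.

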