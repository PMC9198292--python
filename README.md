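# npvreg

Non-rigid multimodal image registration by maximizing normalized mutual
information (NMI), with joint histograms estimated by partial-volume (PV)
interpolation or its improved cubic-kernel variant (NPV).

## The problem

CT, MRI and PET show the same anatomy with unrelated — often non-monotone —
intensity mappings, so intensity-difference measures cannot align them.
Information-theoretic similarity can: if `p_RF` is the joint gray-level
distribution of a reference image R and a transformed floating image F,
registration maximizes

    NMI(R, F) = (H(R) + H(F)) / H(R, F),        H(·) Shannon entropy,

which ranges from 1 (independence) to 2 (perfect functional dependence).

The joint histogram is accumulated without interpolating intensities: each
sample point p of the floating image maps to q = T(p) in the reference frame,
and its unit mass is split over the integer neighbors n of q with separable
kernel weights,

    h[bin R(n), bin F(p)] += prod_axes f(n_axis - q_axis).

Classical PV uses the linear (triangle) kernel f(x) = 1 - |x|; the NPV
variant uses a cubic kernel satisfying f >= 0 and the partition of unity
`sum_m f(m - eta) = 1`, which makes the NMI surface smoother in the
transform parameters and the optimization better behaved.

The transform hierarchy is an affine matrix (coarse stage, initialized by
aligning the intensity centroids) followed by a cubic B-spline free-form
deformation (fine stage, control points every λ voxels). Both stages are
optimized by a Davidon–Fletcher–Powell (DFP) quasi-Newton scheme with Armijo
backtracking and central finite-difference gradients.

A synthetic phantom generator produces multimodal pairs — shared anatomy,
per-class intensity permutation, known affine/FFD ground-truth warp,
additive noise — so every claim is testable without any data download.

## Worked example

```python
import numpy as np
import npvreg as nv

case = nv.make_registration_case(
    shape=(64, 64), transform_kind="rigid", magnitude=8.0,
    noise_sigma=2.0, seed=2,
)
result = nv.register(case.reference, case.floating, nv.RegistrationConfig())
metrics = nv.evaluate_case(result, case)
print(f"NMI {result.reports['initial'].NMI:.3f} -> {result.reports['final'].NMI:.3f}")
print(f"rotation error {metrics['rotation_error_deg']:.3f} deg, "
      f"mean field error {metrics['mean_field_error']:.3f} voxels")
```

Output:

```
NMI 1.433 -> 1.539
rotation error 0.276 deg, mean field error 0.147 voxels
```

The floating image here is the reference with its gray classes permuted
(a synthetic "other modality"), rotated 8° about the image center, and
degraded with σ=2 gray-level noise. Registration raises NMI from 1.433 to
1.539 and recovers the rotation to within 0.28°; the remaining mean
displacement error over the anatomy is 0.15 voxels.

The same pipeline is available from the shell:

```sh
npvreg phantom -o case --transform rigid --magnitude 8 --seed 2
npvreg register case/reference.nii.gz case/floating.nii.gz -o out --interp npv
npvreg measure case/reference.nii.gz case/floating.nii.gz --interp pv
```

`npvreg register` writes the estimated transforms (`result.json`), the warped
floating image, a green/magenta false-color fusion PNG (2-D), and the
optimizer traces.

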