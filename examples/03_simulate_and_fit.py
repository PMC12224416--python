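"""Simulate the default noisy phantom and run the regularized two-step fit.

Generates a 16x16x8 two-region phantom (curved WM tube in GM background)
at SNR 20 with the 10-direction scheme at 0/60/120 Hz, fits it with and
without the base regularization, and reports voxelwise K_perp RMSE
against ground truth.
"""

import numpy as np

from axdki import phantom
from axdki.model import derived_metrics
from axdki.workflow import FitConfig, fit_dataset

spec = phantom.PhantomSpec(shape=(16, 16, 8), snr=20.0, seed=0)
data = phantom.generate(spec)
print(f"phantom: {spec.shape} grid, {len(data.scheme)} volumes "
      f"(3 frequencies x [2 b0 + 10 dirs x 2 shells]), Rician noise at SNR {spec.snr:g}")

truth = derived_metrics(data.true_params(0.0))

for label, cfg in (
    ("unregularized (gamma=0)", FitConfig(gamma_dt=0.0, gamma_dk=0.0)),
    ("base regularization (gamma_DT=0.5, gamma_DK=0.075)", FitConfig()),
):
    result = fit_dataset(data.volume, data.scheme, cfg)
    m = result.metrics[0.0]  # the PGSE (0 Hz) frequency
    err = m.k_perp - truth.k_perp
    rmse = np.sqrt(np.nanmean(err**2))
    blackened = int(np.sum(m.k_perp < 0))
    print(f"\n{label}")
    print(f"  K_perp RMSE vs truth : {rmse:.4f}")
    print(f"  blackened voxels     : {blackened}  (negative fitted kurtosis)")

print()
print("The spatial penalty couples neighboring voxels, suppressing the")
print("noise amplification inherent to kurtosis fitting: lower RMSE and")
print("no non-physical negative-kurtosis voxels, without losing the")
print("WM/GM contrast (see 05_regularization_vs_smoothing.py).")
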