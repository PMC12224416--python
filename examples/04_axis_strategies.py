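"""Compare the three symmetry-axis pooling strategies (AFAB/SFAB/SFLB).

The axisymmetric fit fixes a per-voxel symmetry axis first.  Pooling all
frequencies and b-values (AFAB) assumes the fiber axis does not change
with oscillation frequency and buys a more robust axis estimate; SFAB
and SFLB estimate it per frequency.  On a noisy phantom with a
frequency-invariant orientation field, AFAB shows the smallest
cross-frequency axis disagreement.
"""

import numpy as np

from axdki import dti, phantom
from axdki.evaluation import median_pair_angle

angles = {s: [] for s in dti.STRATEGIES}
for seed in range(5):
    spec = phantom.PhantomSpec(shape=(8, 8, 4), snr=15.0, seed=seed)
    data = phantom.generate(spec)  # 0/60/120 Hz
    wm = data.labels[data.volume.mask] == 1
    for strategy in dti.STRATEGIES:
        bundle = dti.compute_axes(data.volume, data.scheme, strategy, gamma_dt=0.0)
        axes = {f: a.axes for f, a in bundle.axes.items()}
        angles[strategy].append(median_pair_angle(axes, select=wm))

print("median central angle between per-frequency axes in the WM tube")
print("(mean over 5 noise seeds at SNR 15):\n")
for strategy in dti.STRATEGIES:
    print(f"  {strategy}: {np.mean(angles[strategy]):6.2f} deg")
print()
print("AFAB shares one pooled axis across frequencies (0 deg by")
print("construction); SFLB, which discards the high-b shell, has the")
print("noisiest per-frequency axes.  The same ordering drives the map")
print("quality differences between strategies.")
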