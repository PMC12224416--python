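"""The axisymmetric DKI forward model for a single white-matter-like voxel.

Evaluates the log-signal model log(S/S0) = -b D(theta) + (b^2/6) Dbar^2 W(theta)
along, across and oblique to the fiber axis, and derives the scalar metrics.
"""

import numpy as np

from axdki.model import AxisymmetricParams, derived_metrics, predict_log_signal

params = AxisymmetricParams(
    log_s0=0.0, d_perp=0.4, d_par=1.5,  # um^2/ms
    w_perp=1.6, w_par=0.6, w_mean=1.0,  # dimensionless tensor kurtosis
    axis=(0.0, 0.0, 1.0),
)

print("white-matter-like voxel: D_par=1.5, D_perp=0.4 um^2/ms,")
print("W_par=0.6, W_perp=1.6, Wbar=1.0\n")
print(f"{'theta':>8} {'b=1.0':>10} {'b=2.5':>10}   (log signal)")
for deg in (0, 45, 90):
    th = np.radians(deg)
    s1 = predict_log_signal(params, 1.0, th)
    s2 = predict_log_signal(params, 2.5, th)
    print(f"{deg:>7}deg {s1:>10.4f} {s2:>10.4f}")
print()
print("Signal decays fastest along the axis (theta=0, large D) but the")
print("positive-kurtosis upturn (b^2 term) is strongest across it, where")
print("restricted diffusion makes the decay non-Gaussian (W_perp > W_par).")

m = derived_metrics(params)
print()
print("derived metrics:")
print(f"  Dbar  = {float(m.d_mean):.4f} um^2/ms   (mean diffusivity)")
print(f"  FA    = {float(m.fa):.4f}            (fractional anisotropy)")
print(f"  K_par = {float(m.k_par):.4f}            (axial kurtosis, W_par*Dbar^2/D_par^2)")
print(f"  K_perp= {float(m.k_perp):.4f}            (radial kurtosis, W_perp*Dbar^2/D_perp^2)")
print(f"  Wbar  = {float(m.w_mean):.4f}            (mean kurtosis tensor)")
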