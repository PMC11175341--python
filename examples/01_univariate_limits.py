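"""Classical single-signal LOD/LOQ: k factors, blank threshold, calibration.

Builds a small hand-made calibration (one sensor, five levels, triplicate)
and walks through every zeroth-order limit formula.
"""

import numpy as np

import enoselod as el

rng = np.random.default_rng(0)
conc = np.repeat([0.0, 0.5, 1.0, 2.0, 4.0], 3)  # ppm, blank included
signal = 2.0 * conc + 0.3 + rng.normal(0, 0.25, conc.size)  # slope 2, noise sd 0.25

# Detection multipliers: alpha = beta = 0.05 under normality, Student t for 9 blanks
k_normal = el.k_factor(0.05, 0.05, "normal")
k_t = el.k_factor(0.05, 0.05, "student_t", n_blanks=9)
print(f"k (normal, 0.05/0.05)      = {k_normal.value:.4f}  (prints as {k_normal.value:.1f})")
print(f"k (Student t, 9 blanks)    = {k_t.display()}")
print(f"alpha=beta implied by k=3  = {el.error_probability(3.0):.4f}")

blanks = el.blank_statistics(signal[conc == 0])
print(f"\nblank mean {blanks.mean:.3f}, blank SD {blanks.sd:.3f} (n={blanks.count})")
print(f"signal threshold y_LOD     = {el.signal_threshold(blanks, k_normal):.3f}")

curve = el.fit_calibration(conc, signal)
print(f"\ncalibration: slope {curve.slope:.3f} per ppm, intercept {curve.intercept:.3f}, "
      f"residual SD {curve.residual_sd:.3f}, leverage h0 {curve.leverage:.3f}")

lod = el.lod_from_slope(k_normal, blanks.sd, curve)
lod_lev = el.lod_with_leverage(k_normal, curve.residual_sd, curve)
adj = el.adjusted_lod(k_normal, blanks.sd, curve, blanks)
loq = el.lod_from_slope(el.loq_factor(), blanks.sd, curve)
print(f"\nLOD (slope form, s_blank)  = {lod.value:.3f} ppm")
print(f"LOD (leverage, RMSE)       = {lod_lev.value:.3f} ppm")
print(f"LOD (adjusted intercept)   = {adj.value:.3f} ppm")
print(f"LOQ (k = 10)               = {loq.value:.3f} ppm")
print("\nThe LOD is the smallest concentration distinguishable from the blank at "
      "the chosen error probabilities; the LOQ is where 10% relative precision begins.")
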