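"""Spatially-aware uncertainty of stratum means and differences.

Model errors are spatially autocorrelated, so the standard error of a
stratum mean shrinks slower than 1/sqrt(n). An exponential correlogram is
fitted to a residual raster and fed into the exact pair-count evaluation
of Var(mean) = sigma^2/n^2 * sum_ij rho(d_ij).
"""

import numpy as np
from scipy import ndimage

from firecarb import (compose_two_step_error, difference_variance,
                      fit_correlogram, stratum_mean_se)

rng = np.random.default_rng(0)
# synthetic residual raster with ~2-cell correlation length
res = ndimage.gaussian_filter(rng.normal(size=(50, 50)), 2.0, mode="wrap")
res = 30.0 * (res - res.mean()) / res.std()

rho = fit_correlogram(res, cell_size_m=30.0)
print(f"fitted correlogram range phi = {rho.phi_m:.0f} m")

mask = np.zeros((50, 50), bool)
mask[10:30, 10:30] = True
se_corr = stratum_mean_se(30.0, mask, rho)
se_iid = 30.0 / np.sqrt(mask.sum())
print(f"stratum of {mask.sum()} cells: SE {se_corr:.2f} Mg/ha "
      f"(naive iid would claim {se_iid:.2f})")

sigma = compose_two_step_error(31.76, 38.52)
print(f"two-step relRMSE composition: sqrt(31.76^2 + 38.52^2) = {sigma:.1f}%")
var_d = difference_variance(se_corr**2, se_corr**2, 0.6 * se_corr**2)
print(f"difference of two correlated maps (r=0.6): SE {np.sqrt(var_d):.2f}")
# Autocorrelation inflates the stratum SE several-fold over the iid value;
# correlated pre/post errors partially cancel in the difference.
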