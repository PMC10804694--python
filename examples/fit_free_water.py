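"""Fit the single-shell free-water model to a simulated voxel population.

Builds 300 voxels with known free-water fractions and tissue anisotropy,
simulates the 64-direction b=1000 acquisition with Rician noise at SNR 30,
inverts the bi-tensor model, and prints how well the planted parameters come
back. The printed bias/RMSE say how trustworthy voxelwise FW estimates are
at clinical SNR; the noiseless line shows the inversion itself is exact.
"""

import numpy as np

from fwtract import fit_free_water, simulate_dwi
from fwtract.synthetic import (
    BiTensorGroundTruth,
    eigenvalues_for_fa,
    make_gradient_scheme,
)

rng = np.random.default_rng(0)
n = 300
scheme = make_gradient_scheme(64, b=1000.0, seed=0)

f_true = rng.uniform(0.0, 0.6, n)
fa_true = rng.choice([0.2, 0.5, 0.7], n)
evals = np.array([eigenvalues_for_fa(fa, 0.7e-3) for fa in fa_true])
truth = BiTensorGroundTruth(
    f_true.reshape(n, 1, 1),
    evals.reshape(n, 1, 1, 3),
    rng.standard_normal((n, 1, 1, 3)),
    np.full((n, 1, 1), 400.0),
)

for label, snr in [("noiseless", None), ("SNR 30 (Rician)", 30)]:
    dwi = simulate_dwi(truth, scheme, snr=snr, seed=7)
    fit = fit_free_water(dwi, scheme, regularization_weight=0.0)
    err = fit.fw.data.reshape(-1) - f_true
    print(f"{label:16s}  FW bias {err.mean():+.4f}   RMSE {np.sqrt((err**2).mean()):.4f}"
          f"   max|err| {np.abs(err).max():.4f}")

fa_t = fit.fa_t.data.reshape(-1)
print(f"\ntissue FA at SNR 30: mean abs error {np.nanmean(np.abs(fa_t - fa_true)):.4f}")
print("FW is the free-water volume fraction per voxel; FA_T is the anisotropy")
print("of the tissue compartment after the free-water signal is removed.")
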