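"""Charge-density diagnostics: QTAIM bond critical points and residual maps.

Analyses the multipole density of the built-in crystal: covalent and
hydrogen-bond critical points (the standard rho, Laplacian, eigenvalue and
ellipticity table), then a residual-density fractal analysis of a noisy
dataset against the refined model.
"""

import numpy as np

from mbit import (SFCalculator, make_fixture, qtaim_report,
                  simulate_intensities, fourier_map, henn_meindl)
from mbit.refine import optimal_scale
from mbit.scattering import ReflectionSet

st, truth = make_fixture("serine_like")

pairs = [("C1", "N1"),   # covalent C-N
         ("O3", "H7"),   # covalent O-H
         ("H7", "O1")]   # intermolecular O-H...O hydrogen bond
table = qtaim_report(st, truth, pairs)
print(table.round(4).to_string(index=False))
print("\nThe covalent bonds show large rho_cp with negative Laplacian;")
print("the hydrogen bond is a (3,-1) point in the closed-shell regime:")
print("small rho_cp (~0.1 e/A^3) and positive Laplacian.\n")

data = simulate_intensities(st, truth, d_min=0.8, rel_sigma=0.02, seed=4)
fc = SFCalculator(st, truth).compute(data.hkl)
refl = ReflectionSet(hkl=data.hkl, fo2=data.fo2, sigma=data.sigma, fc=fc)
k = optimal_scale(data.fo2, np.abs(fc) ** 2, 1.0 / data.sigma ** 2)
dmap = fourier_map(st, refl, kind="residual", grid=(64, 64, 64), scale=k)
fa = henn_meindl(dmap, n_bins=30)
i = int(np.nanargmax(fa.df))
print(f"residual map: egross = {fa.egross:.2f} e, "
      f"rho in [{fa.rho_min:.3f}, {fa.rho_max:.3f}] e/A^3")
print(f"fractal dimension peaks at d^f = {fa.df[i]:.2f} near rho0 = {fa.rho0[i]:+.3f}")
print("A parabola-shaped d^f curve peaking near 3 at rho0 = 0 is the")
print("signature of featureless (noise-dominated) residual density.")
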