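"""The full iterative refinement loop.

Starts from a structure perturbed by 0.03 A RMS, lets the synthetic
density backend (standing in for a periodic electronic-structure code)
respond to each refined geometry, and iterates multipole generation +
coordinate/ADP refinement until the RMS coordinate change phi_diff drops
below 0.1 mA.
"""

import numpy as np

from mbit import (MbitConfig, SyntheticOracleBackend, make_fixture, run_mbit,
                  simulate_intensities)

st, truth = make_fixture("serine_like")
data = simulate_intensities(st, truth, d_min=0.8, rel_sigma=0.0, seed=3)

rng = np.random.default_rng(5)
pert = st.copy()
disp = rng.normal(size=(len(st.sites), 3))
disp *= 0.03 / np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
inv = st.cell.cart_to_frac
for i, s in enumerate(pert.sites):
    s.xyz = (s.xyz + inv @ disp[i]) % 1.0

backend = SyntheticOracleBackend(st, truth, mode="relaxed")
# the data are noise-free, so pure 1/sigma^2 weighting is the exact scheme
result = run_mbit(pert, data, backend, MbitConfig(max_cycles=8, weight_a=0.0))

print("cycle  phi_diff (A)   R1 (%)   tMMP-fit R1 (%)")
for c in result.report.cycles:
    print(f"{c.cycle:4d}   {c.phi_diff:10.2e}   {c.refine_stats.r1:6.3f}"
          f"   {c.tmmp_stats.r1:6.3f}")
print(f"\nterminated: {result.report.termination}")

err = max(
    np.linalg.norm(st.cell.frac_to_cart
                   @ ((result.structure.site(s.label).xyz - s.xyz)
                      - np.rint(result.structure.site(s.label).xyz - s.xyz)))
    for s in st.sites)
print(f"largest coordinate error vs the generating structure: {err:.2e} A")
print("phi_diff below 1e-4 A from the second cycle onwards ends the loop;")
print("on noise-free data the generating geometry is recovered exactly.")
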