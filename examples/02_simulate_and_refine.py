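"""Spherical (IAM) vs multipole refinement of the same simulated data.

Simulates a noisy diffraction experiment on the built-in 14-atom
orthorhombic crystal (whose ground truth carries bond-directed hydrogen
dipoles), refines it once with conventional spherical atoms and once with
the true multipole model held fixed, and compares the X-H bond lengths:
the spherical model systematically foreshortens them because it places
each hydrogen at its electron-density centroid, which is pulled into the
bond.
"""

import numpy as np

from mbit import make_fixture, simulate_intensities
from mbit.refine import iam_protocol, lsq_refine, three_step_coordinate_protocol

st, truth = make_fixture("serine_like")
data = simulate_intensities(st, truth, d_min=0.8, rel_sigma=0.02, seed=1)
print(f"simulated {len(data)} unique reflections to 0.8 A with 2% noise")

iam = lsq_refine(st, None, data, iam_protocol(st), model="iam")
mm = lsq_refine(st, truth, data, three_step_coordinate_protocol(st),
                model="multipole")
print(f"IAM refinement:       {iam.stats}")
print(f"multipole refinement: {mm.stats}")

a = st.cell.frac_to_cart
print("\nbond      multipole   IAM      difference")
for s in st.sites:
    if s.element != "H":
        continue
    partner = min(
        ((np.linalg.norm(a @ ((o.xyz - s.xyz) - np.rint(o.xyz - s.xyz))), o.label)
         for o in st.sites if o.element != "H"))[1]

    def dist(struct):
        d = struct.site(s.label).xyz - struct.site(partner).xyz
        d -= np.rint(d)
        return np.linalg.norm(struct.cell.frac_to_cart @ d)

    print(f"{partner}-{s.label:3s}  {dist(mm.structure):8.4f} {dist(iam.structure):8.4f}"
          f"  {dist(iam.structure) - dist(mm.structure):+8.4f} A")
print("\nNegative differences: the spherical model shortens every X-H bond,")
print("the effect that aspherical refinement methods exist to remove.")
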