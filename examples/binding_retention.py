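"""Ion retention and the immobile-ion classification on a synthetic binding system.

Generates ions binding to a protein-like scaffold with two-state Markov
kinetics (stationary bound fraction 0.75), measures per-ion minimum distances
to the protein surface, and classifies ions as immobile when they sit within
the first contact cutoff for strictly more than half of the frames.
"""

import numpy as np

import fibrion as fb

kin = fb.BindingKinetics(p_on=0.3, p_off=0.1, n_ions=20, seed=1)
traj, truth = fb.generate_binding_trajectory(kin, n_frames=2000)

protein = fb.select_group(traj, "protein_heavy")
ions = fb.select_group(traj, "ion:NA")
series = fb.min_distances(traj, ions, protein)
records = fb.retention_fractions(series, fb.CutoffSet(species="NA", cutoff1=2.8))

f1 = np.array([r.f1 for r in records])
print(f"stationary bound fraction (ground truth): {kin.stationary_bound_fraction:.3f}")
print(f"mean estimated retention fraction:        {f1.mean():.3f}")
print(f"immobile ions (f1 > 0.5):                 {sum(r.immobile for r in records)}/20")
print(f"max |estimate - realized truth|:          {np.abs(f1 - truth.realized_retention).max():.2e}")
# The retention estimate recovers the Markov chain's stationary occupancy; the
# immobile count shows the strict >50% residence rule applied per ion.
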