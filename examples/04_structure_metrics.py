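"""RMSF, hinge angle, and a hydrogen-bond distance series on one ensemble."""

import numpy as np

import allokit

top, ref = allokit.make_toy_topology(20, seed=6)
spec = allokit.PlantedEnsembleSpec(n_residues=20, n_frames=2000,
                                   base_variance=0.25, seed=7)
ensemble = allokit.sample_gaussian_ensemble(top, ref, spec)

aligned, rmsd = allokit.superpose(ensemble)
values = allokit.rmsf(aligned)
print(f"mean per-frame RMSD to the ensemble mean: {rmsd.mean():.2f} Å")
print(f"RMSF: mean {values.mean():.2f} Å  (expected ~ sqrt(3)*0.5 = 0.87 Å "
      f"before rigid-body removal)")

labels = top.labels
angle = allokit.hinge_angle(ensemble, (labels[0], labels[10], labels[19]))
print(f"hinge angle at {labels[10]}: {angle.mean:.1f} ± {angle.sd:.1f} deg")

hb = allokit.hbond_series(ensemble, f"{labels[5]}:N", f"{labels[3]}:O",
                          cutoff=3.5)
print(f"H-bond {hb.donor} ... {hb.acceptor}: mean {hb.mean:.2f} Å, "
      f"occupancy {hb.occupancy:.2f}")
# Occupancy is the fraction of frames with the donor-acceptor distance under
# the 3.5 Å cutoff.
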