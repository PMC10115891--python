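"""Build a mutual-information correlation network and locate a planted coupling.

Generates a 40-residue ensemble whose residues 5 and 25 fluctuate with a
per-axis correlation of 0.7, estimates r_MI for every residue pair, and shows
that the planted pair tops the adjacency while the eigenvector centrality of
the coupled residues stands out.
"""

import numpy as np

import allokit

top, ref = allokit.make_toy_topology(40, seed=1)
spec = allokit.PlantedEnsembleSpec(
    n_residues=40, n_frames=10000, planted_pairs={(5, 25): 0.7}, seed=2)
ensemble = allokit.sample_gaussian_ensemble(top, ref, spec)

net = allokit.build_network(ensemble, estimator="gaussian")
i, j = np.unravel_index(np.argmax(net.matrix), net.matrix.shape)
print(f"strongest edge: {net.nodes[i]} -- {net.nodes[j]} "
      f"r_MI = {net.matrix[i, j]:.3f}   (planted rho = 0.7)")

profile = allokit.eigenvector_centrality(net)
top3 = np.argsort(profile.centrality)[::-1][:3]
print("highest-centrality residues:",
      ", ".join(f"{profile.nodes[k]} ({profile.centrality[k]:.3f})"
                for k in top3))
# The two coupled residues carry most of the network's communication, so they
# should dominate the leading eigenvector.
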