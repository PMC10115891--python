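# allokit

Ensemble analysis of allosteric communication in two-subunit enzymes.

Allosteric regulation — a ligand or a temperature change at one site altering
activity at a distant site — leaves fingerprints in the *correlated motions*
of a protein's conformational ensemble. `allokit` implements the network
machinery used to read those fingerprints from sampled ensembles (e.g. MD
trajectories of an IGPS-like HisF/HisH two-subunit enzyme, with residues
labelled `fL63`, `hG50`, …), together with a synthetic-ensemble generator
that plants known couplings so every stage can be validated against ground
truth. It is a library first (`import allokit`), with narrative scripts under
`examples/` and a thin `allokit` CLI for shell use.

## What it computes

**Correlation networks and eigenvector centrality.** For residues *i*, *j*
with 3-D Cα displacement vectors *x\_i*, *x\_j* (after iterated Kabsch
superposition), the mutual information
*I*[*x\_i*, *x\_j*] = *S*[*x\_i*] + *S*[*x\_j*] − *S*[*x\_i*, *x\_j*] (nats;
Gaussian closed form by default, Kraskov k-NN optionally) maps to the
generalized correlation coefficient

    r_MI = (1 − exp(−(2/3) I))^(1/2)  ∈ [0, 1],

which fills a symmetric adjacency matrix **A**. The leading eigenvector **c**
of **A** (A c = ε c, Perron–Frobenius, unit L2 norm) scores each residue's
centrality to the communication network; ΔEC between two states localizes
what a perturbation (effector analog, heating) changes.

**Signalling pathways.** Edges weighted w\_ij = −ln r\_MI turn maximal
correlation into shortest paths: Dijkstra for the optimal residue-to-residue
channel (multi-source via a zero-weight super-source), Yen's loopless
k-shortest for the suboptimal bundle. Merged path residues are classified
internal/buried vs external/solvent-exposed by relative SASA (Shrake–Rupley,
probe 1.4 Å) on the mean structure.

**Perturbation contact networks (DPCN).** w\_ij = mean number of heavy-atom
contacts (< 5 Å) per frame between residues i and j (or, asymmetrically, the
backbone NH group of i against everything else). Δw\_ij between two states,
thresholded at w\_t = 6, is the DPCN; Spearman rank correlation over the
supra-floor pair union compares two DPCNs (e.g. heating vs effector
binding).

**Structure metrics.** Kabsch superposition with reflection guard, per-residue
RMSF, a simplified Kabsch–Sander 3-class secondary-structure assigner
(helix/sheet/coil) with per-residue persistency, hinge angles at Cα triples,
and distance-based hydrogen-bond series with occupancy.

**Essential dynamics.** Dense PCA of aligned Cα/backbone coordinates, standard
variance-explained and a separately labelled cumulative squared-eigenvalue
metric, and a joint (concatenated) basis to project several states into one
low-dimensional space.

**NMR thermometry.** Amide-proton temperature coefficients ∂δ(HN)/∂T (ppb/K)
in two windows (292.92–302.73 K and 307.62–322.41 K), curvature detection by
the extra-sum-of-squares F-test (linear null vs quadratic,
F = (RSS\_lin − RSS\_quad) / (RSS\_quad/(n−3))), and computed-vs-experimental
shift agreement (Pearson r with per-residue residuals).

**Synthetic ensembles.** All inputs can be generated with planted truth:
compact self-avoiding toy folds, multivariate-Gaussian displacement ensembles
(block, elastic-network, or custom covariance; a temperature scale emulating
heating), two-state pairs with planted coupling/contact perturbations and
machine-checkable ground-truth tables, and shift tables with planted
linear/quadratic temperature profiles.

## Worked example

```python
import numpy as np, allokit

top, ref = allokit.make_toy_topology(40, seed=1)
spec = allokit.PlantedEnsembleSpec(
    n_residues=40, n_frames=10000, planted_pairs={(5, 25): 0.7}, seed=2)
ens = allokit.sample_gaussian_ensemble(top, ref, spec)

net = allokit.build_network(ens)                 # r_MI adjacency
prof = allokit.eigenvector_centrality(net)
i, j = np.unravel_index(np.argmax(net.matrix), net.matrix.shape)
print(net.nodes[i], net.nodes[j], round(net.matrix[i, j], 3))
```

prints

```
fQ6 hM6 0.652
```

— the planted pair (residues 5 and 25, labelled `fQ6`/`hM6`) is the strongest
edge, with r\_MI ≈ 0.65 for a planted per-axis correlation of 0.7 (rigid-body
removal on a 40-residue fold absorbs a little of the correlation). The same
two residues top the centrality profile. `examples/` holds one such script
per capability; `examples/07_full_pipeline.py` (or `allokit run --out out/`)
runs the whole chain on a synthetic apo30/apo50/holo30 analog triple and
prints, among other things, the external fraction of the signalling pathways
rising from the inactive state (0.67) to the activated ones (0.75) and a
near-perfect DPCN rank correlation between the heating and effector-binding
analogs.

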