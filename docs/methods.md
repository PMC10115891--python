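# Methods

## The model of the data

Every analysis stage consumes an `Ensemble`: a fixed topology (two chains
tagged `f` and `h`, per-residue backbone N/CA/C/O, an amide H, and a few
sidechain heavy atoms) plus a `frames × atoms × 3` coordinate array in Å.
Real ensembles of this kind come from MD trajectories; the package reads
them as multi-model PDB (via biotite) or from its own `.npz` + JSON
container. For validation, the `synthetic` module draws ensembles from a
multivariate Gaussian over Cα displacements around a compact self-avoiding
reference fold — not dynamics, just a distribution — because a Gaussian
ensemble gives every downstream statistic an analytic oracle.

Displacements are applied at the residue level: all atoms of a residue move
rigidly with its Cα. This keeps a single planted truth driving both the
Cα-level correlation analyses and the heavy-atom contact analyses.

## Correlation networks

The coupling between residues *i* and *j* is the generalized correlation

r_MI = (1 − exp(−(2/3)·I))^{1/2},

with *I* the mutual information between the two 3-D displacement vectors,
in nats (natural logarithms throughout; the exponent 2/3 is fixed by the
dimensionality 3). Displacements are taken after a Kabsch superposition of
every frame onto the ensemble mean, iterated to self-consistency (the
network builder uses two iterations, which is converged for these
ensembles).

Two estimators:

* **Gaussian closed form** (default): I = ½ ln(det Σ_i · det Σ_j / det Σ_ij)
  from the 3×3 marginal and 6×6 joint covariances. The all-pairs build pools
  one 3N×3N covariance and evaluates O(N²) small determinants. A singular
  joint covariance (e.g. duplicated streams) returns the cap I_cap = 30 nats
  with a degeneracy flag; r_MI(30) = 1 to ~1e-9.
* **Kraskov k-NN** (`knn`, k = 6): the KSG-1 estimator with Chebyshev
  metric, for non-Gaussian ensembles. On Gaussian fixtures at 20,000 frames
  the two agree within 0.05 nats.

Estimates are clamped to [0, I_cap]; r_MI is monotone in I with r_MI(0) = 0.

**Finite-size bias worth knowing about.** Rigid-body removal projects out 6
of the 3N displacement degrees of freedom, which shifts pairwise
correlations by O(1/N). On a 10-residue toy fold this bias reaches ~0.05 in
r_MI; at 60–100 residues it is within the estimator tolerance (0.03). Tests
that assert tight recovery therefore use 60–100-residue chains, or evaluate
on raw displacements where the contract allows it.

Eigenvector centrality is the leading eigenpair of the r_MI adjacency
(diagonal set to 0; a constant diagonal would shift ε but not **c**). The
dense symmetric solver is the default; power iteration is kept as an
independent numerical route and agrees to 1e-6. Disconnected networks are
scored on the largest component with zeros (and a warning) elsewhere.
Cross-state ΔEC uses unit-L2 profiles; the normalization choice is recorded
in the profile metadata. ΔEC magnitudes depend on that choice, so signs and
rankings — not magnitudes — are the supported comparison surface.

## Pathways

Edge weights are w = −ln(clamp(r_MI, 1e-8, 1−1e-12)); the clamp mask is
recorded. Minimizing total w maximizes the product of correlations along
the path. Multiple sources are handled by a virtual zero-weight
super-source, so the ranking over paths is global rather than per-source.
Suboptimal paths are Yen's loopless k-shortest (k = 50 by default, the
conventional bundle size). An optional r_MI threshold floors all weaker
edges before the logarithm: on finite synthetic ensembles the MI estimator
noise floor (~r_MI 0.05–0.08 at 4,000 frames) would otherwise let spurious
one-hop edges compete with genuine multi-edge channels. The end-to-end
pipeline uses threshold 0.2 and k = 8, because the planted toy networks
support about that many meaningful channels; both knobs are recorded in the
outputs.

Exposure labels come from relative solvent accessibility on the
ensemble-mean structure: Shrake–Rupley areas (probe 1.4 Å, element-based
radii, hydrogens excluded) summed per residue and divided by the residue
type's theoretical maximum (Tien et al. 2013 values; unknown types fall
back to the Gly maximum with a warning). Residues at or above relative SASA
0.2 are "external", the rest "internal"; the threshold is a config knob.
The external fraction of a path set is weighted by path membership counts,
so residues that appear on many suboptimal paths dominate the statistic.

## Perturbation contact networks

w_ij is the mean atomic contact count per frame (atom pairs under the 5 Å
cutoff), chosen over a raw total so that the conventional threshold w_t = 6
is independent of frame count; `aggregate="sum"` provides the raw-total
alternative. Symmetric mode counts heavy–heavy pairs once per unordered
residue pair; asymmetric mode counts the backbone amide (N plus amide H)
of each residue against the heavy atoms of all others and is directional.
`min_seq_sep = 1` excludes only self-contacts: neighbour contacts carry
backbone-mediated perturbations, and their constant part cancels in the
difference. Distances are plain Euclidean — ensembles are not periodic by
contract.

The ground truth for planted contact shifts is computed by contact-counting
the two *reference* structures exactly: moving a residue necessarily changes
its geometry relative to chain neighbours as well as the addressed partner,
so every residue pair whose reference contact count changes is a
ground-truth record (with sign and magnitude), and the "no false edges"
check is made against that full affected set. A Cα-distance proxy is not
sufficient — contact counts react to atom-level geometry even when the
Cα–Cα distance barely moves.

Network similarity is Spearman rank correlation over the union of pairs
whose |Δw| reaches the floor (default 6) in either network, with the number
of compared pairs always reported; fewer than 3 comparable pairs is an
error, not a number.

## Structure metrics

Superposition is the standard least-squares rigid fit on Cα with a
reflection guard (det = +1). Fitting to "mean" iterates until the mean is
self-consistent (tolerance 1e-12, cap 20 iterations), which makes the
operation idempotent. Collinear Cα sets are rejected.

The secondary-structure assigner is a simplified Kabsch–Sander: backbone
H-bond energy E = q1·q2·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol
(q1·q2·332 = 27.888), bond when E < −0.5; amide H reconstructed 1 Å from N
anti-parallel to the preceding carbonyl; helix from pairs of consecutive
i→i+4 (or i+3 / i+5) turns, sheet from parallel/antiparallel bridge
patterns with |i−j| > 2, everything else coil. It is deliberately 3-class —
the persistency analyses compare helix/sheet/coil only — and per-frame
external assignment tables are accepted as an alternative input, so no test
or pipeline ever shells out to an external assigner. Persistency is the
fraction of frames matching a reference assignment; for synthetic systems
the reference is the generator's design assignment (or the per-residue
majority class in the CLI, which reports which reference it used).

Hydrogen bonds are distance-only N···O series with an occupancy cutoff of
3.5 Å; no angular term, matching the distance-based definition used in
ensemble comparisons. Hinge angles are evaluated at the middle residue of
an ordered Cα triple.

## Essential dynamics

PCA diagonalizes the population covariance (1/n denominator) of flattened,
aligned Cα or backbone coordinates with a dense symmetric solver — no
randomized or truncated routines, so results are bit-deterministic. The
population convention makes a joint basis fitted on duplicated data exactly
equal the single-state fit. Two spectra are reported side by side and
labelled: the standard λ_m/Σλ variance-explained, and the cumulative
Σλ_m²/Σλ² squared-eigenvalue metric that some ensemble-comparison
conventions call total kinetic variance; the second is non-standard, so it
is computed literally and never substituted for the first. Joint bases are
fitted on frame-concatenated coordinates of states aligned to a common
reference; state separability along each joint component is quantified by
the Bhattacharyya coefficient of the two 1-D projection histograms (50
shared bins over the pooled range).

## NMR thermometry

Temperature coefficients are reported in ppb/K with the sign convention
that a shift decreasing with temperature is negative. Window membership is
endpoint-inclusive; the default windows are 292.92–302.73 K and
307.62–322.41 K. With exactly two points in a window the slope is the
difference quotient (which equals the least-squares slope); with more it is
the least-squares slope. The curvature test compares a linear null against
a quadratic alternative on centered temperatures (centering only for
conditioning): F = (RSS_lin − RSS_quad)/(RSS_quad/(n−3)), p from F(1, n−3),
flag at p < α = 0.05. A perfect linear fit (both RSS ≈ 0) returns p = 1:
no evidence of curvature. Shift agreement matches computed and experimental
tables on residue labels, reports Pearson r, per-residue residuals and the
unmatched residues on both sides; ensemble-averaged computed shifts carry
the across-frame standard deviation and frame count.

The filter for which residues enter a thermometry analysis is a plain
completeness criterion (residue present at all temperatures); any
spectral-quality shortlisting beyond that is data-specific and out of scope
here.

## The synthetic study triple and what passing tests mean

`make_study_triple` builds an inactive state (apo30 analog) and two
activated states (holo30 and apo50 analogs) on one toy fold. The inactive
state routes source→destination couplings (per-axis ρ = 0.40, plus a 0.30
branch) through the two most buried residues; the activated states add
stronger couplings (Δρ = 0.45, plus a 0.35 branch) through the two most
exposed residues, one contact gain between a distant residue pair, and — for
the heating analog only — a covariance scale of 1.4. Coupling strengths are
capped by positive-semidefiniteness of the coupling graph (a chain of
correlations ρ needs 2ρ·cos(π/(k+1)) < 1; the combined internal/external
routes form a 6-cycle, safe below ρ ≈ 0.5). Default problem sizes are 48
residues and 4,000 frames, which resolve every planted effect while keeping
the full pipeline around a minute on one CPU.

What the generator emulates: planted pairwise coupling with known r_MI,
two-state contact rearrangements with exact reference-geometry truth,
heating as a uniform variance scale, and polynomial shift-vs-temperature
profiles. What it does not emulate: anharmonic and multi-basin dynamics,
time correlation (frames are i.i.d.), solvent, sidechain rotamer physics,
and any force field. Passing tests therefore demonstrate that the
*estimators and network statistics* recover planted truth at realistic
sample sizes — not that any particular real protein behaves this way.

## Numerical choices and degenerate inputs

* MI cap I_cap = 30 nats (r_MI indistinguishable from 1); degenerate joint
  covariances return the cap with a flag rather than raising.
* r_MI clamp for path weights: [1e-8, 1−1e-12], recorded per edge.
* Eigen residual ‖Ac − εc‖ < 1e-8 asserted on every computed profile.
* Contact counting is chunked (100 frames per block) over an explicit
  eligible-atom-pair list; memory stays below ~100 MB for the sizes used.
* Seeds: every generator takes one explicit seed; derived seeds (seed+1 for
  state B, seed+10/20 for the study states) keep the two states of a pair
  independent but reproducible. No global random state is touched.
* Tie-breaks: edge lists sort by |weight| descending then lexical node
  order; suboptimal paths are re-sorted stably by total weight after
  generation to guard against floating-point ties.

## Known limitations

* The Gaussian MI estimator is exact only for Gaussian ensembles; for real
  trajectories with multi-basin kinetics the knn estimator is the safer
  default, at ~100× the cost per pair.
* The simplified secondary-structure assigner reproduces clean helix and
  bridge patterns but is not a full 8-class implementation; borderline
  geometries (bent helices, bulged strands) may classify as coil.
* Relative SASA uses element-based radii on toy residues whose sidechains
  are schematic; absolute exposure values are meaningful only relative to
  the 0.2 threshold convention.
* Asymmetric (NH) contact mode requires an amide H or falls back to the N
  atom alone; protonation-state subtleties are out of scope.
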