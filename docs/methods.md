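# Methods

## Model

`aortavae` learns a generative shape model of fixed-topology triangulated
vessel surfaces.  Every mesh in a dataset shares one template connectivity
(vertex count N and faces identical), which makes three precomputations
valid for the whole cohort: the graph Laplacian of each resolution level,
the Chebyshev rescaling `L̄ = 2L/λ_max − I`, and the pooling matrices.

* **Graph layer.** Binary adjacency from face edges; symmetric normalized
  Laplacian with the Moore–Penrose degree inverse, so isolated vertices are
  handled by the formula itself (`L_ii = 1`).  `λ_max` is found by an
  iterative Lanczos solve (tolerance 1e-6) per level; if the solver fails
  the analytic bound 2.0 is used — only the polynomial rescaling changes,
  the filter stays well-defined.
* **Spectral convolution.** Chebyshev filters of order K = 6 (a
  conventional choice in convolutional mesh autoencoders; exposed in
  `ModelConfig.cheb_order`).  The three-term recursion is carried on the
  filtered signal (sparse matrix–vector products, O(K·E·F)); dense matrix
  polynomials are never formed.  A bias per output channel is included
  (toggleable).
* **Pooling.** Quadric-error pair contraction restricted to mesh edges.
  The retained endpoint of each contraction keeps its original coordinates,
  so every coarse vertex set is a strict subset of the fine one and the
  down-sampling matrix is a 0/1 selector.  Contractions that would break
  the local manifold structure (link condition) are skipped; at very coarse
  levels this can exhaust the candidate queue, in which case the hierarchy
  stops at the achievable count and records it (the default 640-vertex tube
  template yields 640→160→40→10→{4..6} depending on geometry).  Per-level
  targets are also clamped at 4 vertices, below which pair contraction on a
  tube is not meaningful.  Discarded vertices re-enter through clamped
  barycentric weights on their nearest coarse triangle (brute-force
  point-to-triangle search — a one-off template cost).
* **Network.** Encoder: 4 × (Chebyshev conv → ELU → pool), channels
  3→32→32→32→64, then a linear layer to a hidden width of 64 and two
  parallel heads for μ and log σ² (σ parameterized as exp(½ log σ²) for
  positivity; log σ² clipped to ±15 to keep exponentials finite).  Decoder:
  two linear layers back to coarsest-level features, 4 × (unpool →
  Chebyshev conv → ELU), and a final convolution to 3 channels with no
  activation.  Inputs are raw coordinates in cm, centered per mesh
  (centering only — norms and orientations are meaningful signal that
  ProcAug manipulates; flag `center_inputs`).
* **Objective.** β-weighted closed-form KL against N(0, I) plus four
  geometric terms: entrywise-L1 vertex loss, symmetric summed squared
  Chamfer distance on vertex sets, per-face-edge absolute edge-length
  difference (shared edges counted twice, as the face-wise sum implies),
  and per-face-edge |⟨unit edge, ground-truth face normal⟩|.  The normal
  term takes absolute values so that it is a nonnegative penalty minimized
  at perpendicularity; a raw signed sum could be driven arbitrarily
  negative and would reward anti-alignment.  Weights default to
  α_chamfer = α_vertex = 1, α_edge = α_normal = 0.1.  Losses are summed per
  mesh and averaged over the batch, so logged magnitudes are comparable
  across batch sizes.

The whole network, including all adjoints, is hand-written NumPy/SciPy: the
model is small enough (≈90 k parameters at d = 4) that sparse-matrix
products plus BLAS contractions train it on one CPU core in about a minute
per hundred epochs, and exact analytic gradients are unit-tested against
finite differences.  Optimizer: Adam, lr 1e-3, batch 16 (all in
`TrainConfig`; the reference training protocols here use 150 epochs).

## ProcAug

Each training shape is Procrustes-aligned (centered, unit Frobenius norm,
SVD rotation with the Kabsch sign correction so the solution stays in
SO(3) — mirror images are not anatomically valid) against a reference
geometry, by default the first training mesh (configurable, including the
vertex-wise mean).  Classical Procrustes also removes translation; since
only scale and rotation are re-sampled as augmentations, both meshes are
centered at their centroids before alignment (a `--no-center` escape hatch
exists).  The per-shape ZYX Euler angles (ψ, ξ, γ with
R = R_z(γ)R_y(ξ)R_x(ψ), ξ on the canonical branch [−π/2, π/2], gimbal lock
resolved by γ = 0) define elementwise min/max angle ranges; the centered,
pre-normalization Frobenius norms define the scale range.  During training
each batch sample independently receives identity, rescale-to-s, or
rotation with probability 1/K (K = 3), parameters drawn uniformly from the
fitted ranges, re-sampled every epoch.  The single-transform ablation arms
("only scaling" / "only rotation") keep the same 1/3 trigger probability
and replace the disallowed branch with identity, so arms differ only in
which transformation is active.

## Synthetic cohort

The generator emulates an infrarenal AAA cohort as swept-tube surfaces on a
fixed template (40 rings × 16 vertices = 640, ~1248 triangles — small
enough that four factor-4 pooling levels remain meaningful and CPU training
takes minutes).  Controlled factors, drawn uniformly per subject:

| factor | default range | unit |
|---|---|---|
| trunk length | 8 – 12 | cm |
| base (healthy lumen) radius | 0.8 – 1.2 | cm |
| sac amplitude (added radius) | 0.5 – 1.5 | cm |
| sac position | 0.4 – 0.6 | fraction of length |
| sac axial width | 1 – 2 | cm |
| proximal neck angulation | 0 – 30 | degrees |
| axial torsion | 0 – 20 | degrees |
| radial vertex noise sd | 0.02 | cm |
| global scale | 0.8 – 1.2 | — |
| global rotation (each ZYX angle) | ±15 | degrees |

Lengths and radii approximate the infrarenal aorta (sac radii up to
~2.7 cm, i.e. aneurysmal diameters past the 5 cm intervention threshold);
scale and orientation jitter exist specifically so the Procrustes policy
has real nuisance transformations to discover.  Noise is radial (along the
local ring direction) to preserve tubular topology.  Ends are open rings by
default (capping available); the network uses only connectivity, not
watertightness.  The generator does **not** emulate: vertex correspondence
error, segmentation artifacts, branching (iliac bifurcation), non-tubular
sac asymmetry, or calcification — so passing tests demonstrate that the
pipeline recovers planted, smoothly-parameterized factor structure, not
that it handles raw clinical meshes.

## Scaled-down study design

The reference experiments (test suite and `scripts/acceptance.py`) run on a
60-subject synthetic cohort with latent size d = 4, one fold of a 10-fold
split, 150 training epochs per model, 3 paired seeds for the
augmentation/β comparisons and 20 seeds for generation — sizes chosen so
the full study completes in minutes on a single core while still showing
the directional effects (trained model beats the mean-shape baseline,
ProcAug lowers test L2, larger β raises det(R), larger extrapolation S
raises RCD).  Disentanglement det(R)×100 for the directional β comparison
is computed from the latent means of the full cohort (60 observations):
a 4×4 correlation determinant estimated from a 6-mesh test fold alone is
dominated by sampling error.  Per-fold reporting still uses test-fold
latents, as in the evaluation CLI.

## Numerical choices and edge cases

* Chebyshev recursion is linear and exactly equals the dense
  eigendecomposition filter; the test suite checks 1e-8 relative agreement.
* Procrustes with degenerate (rank-deficient) cross-covariance warns and
  resolves by the SVD's deterministic ordering.
* Contraction priority ties break by (error, lower vertex index); the
  hierarchy is a pure function of the template and is cached/serialized.
* Barycentric weights are clamped to [0, 1] and renormalized when the
  closest-point projection falls on a triangle edge or vertex.
* Extrapolation uses rejection sampling (not clamping) against the
  training-set latent mean ± 3 sd box, so accepted samples keep an
  isotropic law inside the box; a >99% rejection rate raises with advice to
  lower S.
* Latent-mode ranking averages E over a designated evaluation set, making
  the ranking a property of the model rather than of a single sample; ties
  break by lower index.
* k-fold splitting, PCA and nearest-neighbour queries are delegated to
  scikit-learn / SciPy; covariance uses the unbiased 1/(n−1) estimator.

## Known limitations

* The decoder can emit self-intersecting surfaces; no repair is attempted
  (mesh repair and hole filling are out of scope).
* Only fixed-topology cohorts are supported; establishing vertex-wise
  correspondence across subjects is assumed done upstream.
* Disentanglement is partial: latent modes may mix correlated anatomical
  factors, and det(R) estimates are noisy at small n.
* β and the loss weights interact with mesh scale (losses are summed over
  vertices); cohorts at very different units may need re-tuned β.
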