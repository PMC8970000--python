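# Methods

## Model and procedure

`rhcg` builds ensembles of disordered polypeptides by hierarchical
assembly of fragment conformers and corrects any deliberate sampling bias
by Bayesian maximum-entropy reweighting.

**Tiling.** A construct of L residues is tiled into fragments of length
`fragment_length` (default 5) advancing by `fragment_length −
overlap_length` (default step 3), giving ceil((L−5)/3)+1 windows. The
final window is anchored to the C terminus so coverage is exact; for a
non-commensurate L it overlaps its predecessor by more than the nominal
two residues. This anchoring is our resolution of the tiling ambiguity
for the 130-residue tau construct (43 pentamers with step 3 nominally
span 131 residues); it is a convention, not the only possible one. The
growth construct may include N-terminal pad residues (one for tau K18)
that seed the first fragment and are removed after assembly.

**Fragment libraries and local bias.** Each position holds F conformers
with selection weights w_n^f on the simplex; uniform weights give plain
hierarchical chain growth (HCG). When per-residue data are available, the
weights are set by a local BioEn optimization of θ_f·S_KL(w|uniform) +
χ²/2 using only the fragment's *nonterminal* residues — the first and
last span residues are excluded because caps and junctions perturb them.
A residue therefore contributes data to every fragment in which it is
interior. θ_f defaults to 10; larger values mean a gentler bias.

**Hierarchical growth.** Chains are assembled along a left-packed binary
tree over positions (the unbalanced case simply passes odd nodes
through). At each internal node, `pool_size` clash-free merged subchains
(default 10000) are built: a member of each child is drawn — fragments
with probability w_n^f, pool members uniformly, since pool members are
themselves draws from the biased, clash-conditioned distribution — the
downstream part is superposed onto the upstream part by a least-squares
(Kabsch) fit of backbone N/Cα/C/O of the shared junction residues, and
the merge is discarded if any inter-part heavy-atom pair outside the
junction residues lies closer than `clash_cutoff` (default 2.0 Å, a
conservative heavy-atom contact floor; the criterion itself is a design
choice since only "steric clash" is physically prescribed). The merged
chain keeps upstream coordinates up to and including the first junction
residue and downstream coordinates beyond it. The root node draws
`n_chains` full constructs. Superpositions and clash tests are batched
(vectorized Kabsch via batched 3×3 SVD) with memory-bounded chunking.

**Bias bookkeeping and correction.** Every chain records log p[f^c] =
Σ_n log w_n^{f_n^c} (log space avoids underflow at 40+ fragments).
Reference weights are w_c⁰ ∝ exp(−βG_c)/p[f^c]; the default interfragment
energy G is the clash indicator already enforced during growth, so
w_c⁰ ∝ 1/p[f^c] and, for uniform libraries, w_c⁰ = 1/C. An arbitrary
`energy_model` callable can supply βG per chain.

**Global refinement.** BioEn minimizes θ·S_KL(w|w⁰) + χ²/2 with weights
parameterized as w_c = w_c⁰ e^{g_c}/Z (softmax; one gauge direction is
redundant and harmless). The objective is convex in w, so the solution is
initialization-independent; we use L-BFGS-B with the analytic gradient,
normalizing the objective by max(1, θ) so the stopping tolerances
(ftol 1e-15, gtol 1e-12, up to 2·10⁴ iterations) act at the same relative
accuracy for any confidence level. Non-convergence is flagged on the
result, never silent. σ_i combines the experimental and forward-model
errors in quadrature; forward-error defaults are 1 ppm for Cα shifts and
0.9 Hz for ³J couplings. θ defaults to 5 with an L-curve utility
(`reweight.l_curve`) for choosing it; the corner is reported, the choice
stays with the user. 0·log 0 is treated as exactly 0 throughout, and a
positive weight on a zero-reference member is an error, not an epsilon.

**Importance-sampling diagnostics.** S_KL^bias = Σ w_c log(C·w_c)
measures how far the refined weights are from uniform; ≲1 indicates good
overlap between grown and refined ensembles. θ_f can be selected by
minimizing S_KL^bias over a grid (`reweight.select_theta_f`), ties going
to the largest (gentlest) θ_f.

## Forward models

- **³J(HN,Hα)**: A·cos²(φ−60°)+B·cos(φ−60°)+C with (A,B,C) =
  (8.4, −1.36, 0.33) Hz (the Vögeli parameterization; configurable).
- **RDCs**: D_r = D_HN^max · v_rᵀ S v_r per chain, weight-averaged.
  D_HN^max folds μ₀, γ_H, γ_N and ħ into 21.65 kHz at the idealized
  1.04 Å amide bond and scales as 1/r³. Amide H is reconstructed
  geometrically (opposite the N-CA/N-C(prev) bisector at 1.04 Å) when
  absent. The alignment tensor S is a *shape approximation*: the
  traceless, scaled anisotropy of the gyration tensor,
  S = s₀·(3/2)(T − trT/3·I)/trT with a single configurable order
  magnitude s₀. This captures the shape dependence of steric alignment
  (sign changes at turns) but not the absolute scale or the fine
  orientational weighting of an obstruction-surface simulation; a
  `tensor_backend` hook accepts externally computed per-chain tensors.
- **SAXS**: Debye summation I(q)=ΣΣ f_i f_j sinc(q·d_ij) with reduced
  per-heavy-atom form factors (effective electron counts). Solvation-
  shell and excluded-volume corrections are not modeled — a known
  fidelity gap relative to solution data. The experimental comparison
  fits scale a and background b on q > q_split (default 0.012 Å⁻¹) by
  linear least squares, then, with (a,b) fixed, an aggregate term
  c·exp(−q²R_a²/3) below q_split by bounded nonlinear least squares.
- **R_G**: geometric (all heavy atoms weighted equally) or mass-weighted;
  ensemble value is the weighted root mean square.
- **R_h**: the sequence-length-corrected empirical map
  R_G/R_h = a₁(R_G − a₂N^{1/3})/(N^{0.6} − N^{1/3}) + a₃ with
  (a₁,a₂,a₃) = (0.216, 4.06, 0.821) (default) or the Kirkwood double
  sum 1/⟨1/r_ij⟩; ensembles combine per-chain radii harmonically, as a
  diffusion measurement averages 1/R_h.
- **FRET / SAW-ν**: end-to-end density p(r) ∝ r^{2+g} e^{−(r/b)^δ},
  g = (γ−1)/ν with γ = 1.1615, δ = 1/(1−ν); moments are evaluated
  analytically via Γ functions, so normalization and the mean-distance
  constraint are exact. E = ⟨1/(1+(r/R₀)⁶)⟩ by adaptive quadrature
  (tolerance 1e-10) or directly over ensemble Cα–Cα distances. ν is
  sanity-banded to (0.33, 0.7). The default R₀ and ν for any given dye
  pair are experiment-specific placeholders and must be set by the user.
- **Chemical shifts**: strictly a plug-in contract (callable per chain,
  residue and observable). The built-in `SyntheticShiftPredictor` (coil
  baseline plus Ramachandran-basin offset) exists to close the loop in
  tests and demos; it is not a physical shift model.

## Synthetic data generator

`rhcg.synthetic` emulates the fragment libraries that would come from
replica-exchange MD: ideal-geometry backbones (Engh–Huber-like bonds and
angles, N/Cα/C/O plus Cβ except glycine, acetyl and N-methyl caps) whose
φ/ψ are drawn from per-residue mixtures of the conventional basins
α(−63,−43), β(−120,130), PPII(−75,150) with 15° spread (1.5× for
glycine), proline φ clamped near −65°, and trans ω (180°±3°). These
values are conventional Ramachandran statistics chosen for realism, not
fits to any particular protein or force field. What passing tests on
synthetic libraries demonstrate is the correctness of the machinery —
tiling, bias, growth, correction, refinement, forward models — not the
physical accuracy of any real protein ensemble: side chains beyond Cβ,
solvent, sequence-specific basin statistics and library imperfections of
real MD are all absent.

Synthetic observations are Y = Σ_c w_c^true·y_i^c + N(0,σ_i), with the
truth recorded for scoring; σ = 0 reports unit σ so χ² stays defined.

## Numerical choices

- Superposition: batched Kabsch with SVD sign correction (proper
  rotations only); validated against an independent quaternion (Horn)
  implementation at 1e-8.
- Sampling: inverse-CDF draws from explicit cumulative weights; a `None`
  (uniform) weight vector consumes the random stream identically to an
  explicit uniform vector, so biased growth with uniform weights
  reproduces unbiased growth bitwise at the same seed.
- Seeding: one master seed; per-node streams derived via
  `numpy.random.SeedSequence.spawn`, making runs reproducible and
  node-parallelizable.
- A node that cannot produce a clash-free merge within `max_attempts`
  (default 10⁴) draws per requested member raises an error naming the
  node and the attempt count.
- Fragment-weight simplex asserted to 1e-12; refined weights to 1e-10.
- Degenerate inputs: empty local data leaves a library unchanged (with a
  warning); collinear geometry is rejected by the alignment tensor;
  prolines (no amide H) are rejected by the RDC profile with the residue
  list named.

## Problem sizes in tests and benchmark script

The validation suites run on an 11-residue, 3-fragment, 4-conformer toy
system whose 64 fragment combinations are exhaustively enumerable — this
is what makes the sampling distribution and the importance-sampling
correction checkable exactly. Growth checks use 10⁵ chains against the
enumeration (4 binomial SE), bias-corrected expectations 3 SE, and the
full biased-vs-unbiased round trip 2000 chains per route (3 combined SE).
These sizes were chosen so the whole suite completes on a laptop-class
single core; pool-ancestry correlations are kept negligible by using
pools at least 4× the chain count in those checks (the pool-resampling
correlation of the production default, pool 10⁴ at C = 5·10⁴, is exposed
but not corrected — see limitations).

## Known limitations

- Pool resampling correlates chains that share subchain ancestors; large
  pools mitigate but do not remove this, and no variance correction is
  attempted. Rejection statistics per node are logged.
- The steric-alignment tensor is a shape approximation with a free global
  scale; absolute RDC magnitudes are therefore only defined up to that
  scale unless a per-chain tensor backend is supplied.
- SAXS omits solvation-shell/excluded-volume corrections.
- The hierarchical clash criterion excludes junction-residue pairs at
  their own merge; re-validation of emitted chains is therefore done by
  replaying the assembly tree, not by a flat distance matrix.
- Chemical-shift prediction, PRE calculations with spin-label rotamers
  and explicit-dye growth are out of scope; the shift interface is the
  intended integration point for external predictors.
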