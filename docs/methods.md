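# Methods

## The heterogeneous drug–disease network

A dataset is the triple (M_rr, M_dd, M_rd) over n drugs and m diseases:
drug–drug similarity M_rr (n×n), disease–disease similarity M_dd (m×m), and
the binary association matrix M_rd (n×m, drugs in rows). Similarity
matrices must be symmetric with unit diagonal (tolerance 1e-8; asymmetry
below the tolerance is repaired by averaging with the transpose, anything
larger is rejected with the maximum deviation reported, since a silent
repair of a genuinely asymmetric input would hide a data error). M_rd must
be exactly 0/1. The identifier order of the association matrix is
canonical; similarity matrices are permuted to match it at load time.

Where disease similarity is not given, it can be derived from a binary
symptom–disease profile matrix with the Gaussian interaction profile (GIP)
kernel: K(d_i, d_j) = exp(−γ‖p_i − p_j‖²) with γ = γ′ · m / Σ_i‖p_i‖², i.e.
the bandwidth is the multiplier γ′ (default 1, the common convention)
divided by the mean squared profile norm. The kernel is symmetric with unit
diagonal and entries in (0, 1]; an all-zero profile matrix is rejected
because the bandwidth is undefined.

## Derived adjacency representations

* **Factorization input** M_MF = M_rd ⊙ (M_rr · M_rd · M_dd), normalized by
  its maximum entry. Unknown pairs stay exactly zero; known associations
  are weighted by how consistent they are with the similarity structure.
  An all-zero M_rd yields an all-zero adjacency and no division.
* **Completion input** M_MC = [[M_rr, M_rd], [M_rd′, M_dd]], the
  (n+m)×(n+m) block matrix. Block index ranges are recorded so the blocks
  can be extracted bit-exactly.
* **Overlap-completion inputs.** M_rd1 imputes every all-zero disease
  column from the k most similar diseases; M_rd2 imputes every all-zero
  drug row from the k most similar drugs (k = 10 by default; the weighting
  is similarity-proportional because the imputed values feed a real-valued
  completion, and each imputed profile is rescaled to maximum 1 so
  pseudo-associations never outrank true ones; neighbours with empty
  profiles are excluded and an input with no usable neighbour is rejected).
  The drug-side stack is [M_rr; M_rd1ᵀ] of shape (n+m)×n and the
  disease-side stack is [M_dd, M_rd2ᵀ] of shape m×(m+n). This orientation
  is the one in which both one-sided completions expose the unknown
  drug–disease block: it is read back from rows n: of the completed
  drug-side matrix and columns m: of the completed disease-side matrix.

## Prediction methods

**NMF.** Lee–Seung multiplicative updates minimizing ‖V − WH‖² with
V = M_MF. Denominators carry an ε = 1e-12 stabilizer; factors are
initialized uniform (0, 1] scaled by sqrt(mean(V)/r) so the initial
reconstruction matches the input scale, and a seed fixes the run. The
objective trace is recorded per full update and is non-increasing (a known
property of the updates; the test suite allows 1e-10 slack). Iteration
stops when the relative objective change falls below `tol` (1e-6) or at
`max_iter` (2000). The rank is either given or chosen as the smallest k
whose cumulative explained variance CEV_k = Σ_{i≤k}σ_i²/Σσ_i² reaches 0.90,
computed from the full SVD of the input.

**Permutation-based NMF (NMF-PDR).** Scores each pair by how consistently
its NMF prediction from the observed association structure exceeds
predictions from randomized structure. K observed copies (default K = 100)
shuffle the M_MF values sitting at positive positions among themselves;
three null families permute whole rows, whole columns, or both. Each of the
4K matrices is factorized at one common rank, selected once on the
unpermuted M_MF (per-permutation reselection would confound rank changes
with permutation effects and quadruple the SVD cost). Per pair, the
observed collection is compared against each null collection with a
one-sided Wilcoxon rank-sum test (normal approximation, average ranks,
tie-corrected variance, 0.5 continuity correction); degenerate all-tied
comparisons get z = 0. The three z-scores are summed and divided by their
exact null standard deviation. Because all three tests reuse the same
observed collection, each pair of z-scores has null correlation
K/(2K+1) ≈ 1/2, so the sum's null sd is sqrt(3 + 6K/(2K+1)) ≈ sqrt(6), not
sqrt(3); dividing by the former keeps the combined score standard normal
under the null (verified by Monte-Carlo in the test suite), and since the
divisor is a positive constant it does not affect any ranking-based metric.
A master seed spawns independent child seeds per replicate, making results
reproducible and independent of execution order.

**BNNR.** Bounded nuclear-norm completion
min ‖X‖_* + α/2‖P_Ω(X) − P_Ω(M)‖² s.t. 0 ≤ X ≤ 1, solved by ADMM on the
splitting X = W: W-step is singular-value soft-thresholding at 1/β, X-step
blends (αM + β(W − Y))/(α+β) on observed entries with W − Y elsewhere and
clips to [0, 1], then the scaled dual Y ascends on X − W. Defaults α = 1,
β = 10 (β is the ADMM penalty parameter). Input is M_MC with *every* entry
treated as observed — similarity blocks and both the 1s and 0s of the
association blocks — so the bounded low-rank fit denoises the zeros; the
alternative of treating zeros as missing is available via
`mask_zeros_unknown`. The completed matrix is not re-symmetrized;
predictions read only the top-right drug–disease block. Convergence is a
relative Frobenius change below 1e-6 or 500 iterations; a residual that
grows for 50 consecutive iterations raises a divergence error. The solver
is deterministic.

**OMC.** Runs the same bounded completion on the drug-side and disease-side
stacks separately and averages the two completed drug–disease blocks
elementwise.

## Evaluation protocol

Pairs are stratified into the "1" and "0" groups and each group is
partitioned independently into k = 10 folds (sizes within a group differ by
at most one). When a fold is the test set, its positives are zeroed in
M_rd *before* any adjacency is built, and every derived input is recomputed
from the masked network per fold — predictions for test pairs therefore
never see their own labels. Per repeat, the test-fold scores (both groups)
are assembled into one full score matrix covering every pair exactly once;
cross-validation is repeated N = 25 times by default and the median over
repeats is the headline statistic (mean and SD are also reported).

Metrics are disease-centric: per disease the scores are rank-transformed
(average ranks under ties, which keeps AUC equal to the Mann–Whitney
statistic; the displayed reordered matrix uses a stable sort by drug
index), all pairs are pooled on the negated rank, and AUC / AUPR are
computed over the pool, AUPR by the step-wise average-precision convention
(recorded here because trapezoidal PR integration would give slightly
different values). A matrix with no positives (or no negatives) makes the
metrics undefined and raises rather than returning 0.

`run_cv(..., recompute_adjacency=False)` is a deliberately broken
diagnostic that trains once per repeat on the unmasked network; it exists
only to measure how much that leakage inflates the metrics, and the test
suite asserts the honest pipeline scores lower.

The balanced-subsample evaluator implements the comparator protocol: per
fold, the test set is the fold's positives plus an equal-size random draw
of negatives (drawn from the fold's own negatives, so draws are disjoint
across folds; the source description leaves the draw population open), and
metrics are computed on the union of these balanced test sets. On sparse
matrices this discards most negatives and inflates AUPR severely — on the
default synthetic network the same BNNR predictions score ≈ 0.27 AUPR under
the full protocol and ≈ 0.90 under the balanced one.

## The synthetic generator

Real drug-repurposing datasets cannot be bundled, so all tests run on
planted-structure networks. Drugs and diseases share c latent clusters;
each entity's latent vector is its cluster centroid (centroids drawn with
separation scale `signal`) plus Gaussian noise `noise_sd`; similarities are
Gaussian kernels of latent distance (exactly 1 within a cluster when
`noise_sd` = 0); pair affinities get a small logistic perturbation (scale
0.05) and the top round(size·(1 − target_sparsity)) pairs become
associations, so realized sparsity matches the target up to rounding and
the "similar drugs target related diseases" principle holds by
construction. Defaults — 60 drugs × 40 diseases, 4 clusters, latent
dimension 8, signal 4.0, noise 0.5, sparsity 0.95 — give within-cluster
similarity ≈ 0.6, cross-cluster ≈ 0.02, and a sparsity in the range of the
published benchmark datasets (0.89–0.995) at a size where a full
cross-validation of every method runs in seconds.

What the generator does **not** emulate: degree heterogeneity (popular
drugs / well-studied diseases), multiple noisy similarity sources,
block-structured missingness, and unbalanced cluster sizes. Passing
recovery tests therefore show that the implementations are correct and the
protocol is leakage-safe — not that the methods' real-data ranking is
reproduced. One documented consequence: on these planted networks the
permutation-based scorer improves AUC over plain NMF on every seed tested
(means 0.861 vs 0.810) but its mean AUPR is slightly lower (0.197 vs
0.211), because the z-transform discards score magnitude and there is no
row/column popularity bias for the permutation nulls to remove; on real,
degree-biased data that bias removal is precisely the method's advantage.

## Numerical choices and limitations

* Sparsity is kept at full precision internally; 4-decimal rounding is for
  display only.
* Scores tied across pairs enter the metrics with average ranks, so results
  are deterministic without arbitrary tie-breaking.
* All stochastic components (generator, fold assignment, NMF
  initialization, permutations, balanced draws) consume independent
  children of a single seed.
* Full SVDs are used throughout (problem sizes here do not justify
  truncated solvers); BNNR on the block matrix scales as one (n+m) SVD per
  iteration, and the permutation scorer costs 4K NMF runs, which dominates
  its runtime.
* The test-suite and example problem sizes (desk scale: tens of drugs and
  diseases, K = 25, 1–3 repeats) are the package's chosen defaults for
  fast, reproducible verification; the module-level defaults (K = 100,
  N = 25 repeats) match the recommended analysis settings.
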