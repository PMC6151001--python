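# Methods

## Model

`pipalign` implements alignment under the Poisson indel process: a
string-valued evolutionary process on a rooted binary tree τ with branch
lengths b(v) in expected substitutions per site. Single characters are
inserted as a Poisson process with rate λ per unit branch length plus an
atomic mass λ/μ at the root (the root's virtual infinite stem makes the
process stationary: the expected sequence length is λ/μ everywhere).
Each character independently substitutes according to a rate matrix
**Q** and is deleted at rate μ; both are combined in the generator
**Q**_ε on Σ∪{ε}, where ε is absorbing — a deleted character never
returns and never substitutes. At insertion, characters are drawn from
the substitution model's stationary distribution π; the gap-augmented
insertion distribution π_ε places no mass on ε and is used unnormalised
over Σ (this convention is validated against a latent-path enumeration
oracle, see below).

Key per-node quantities (all computed in `likelihood.PIPContext`):

| quantity | value | meaning |
|---|---|---|
| ι(v) | b(v)/(‖τ‖+μ⁻¹), root μ⁻¹/(‖τ‖+μ⁻¹) | insertion-point prior; sums to 1 |
| β(v) | (1−e^{−μb(v)})/(μb(v)), root 1 | survival to the branch's lower end |
| ‖ν‖ | λ(‖τ‖+μ⁻¹) | normalising Poisson intensity |
| p(c_∅) | Σ_v ι(v)(1−β(v)+β(v)Σ_σ π(σ)f̃_v(σ)) | all-gap column likelihood |

A column's likelihood sums ι(v)·f_v over the *ancestral set* 𝒜: the most
recent common ancestor of the gap-free leaves and all its ancestors
(membership of the MRCA itself is confirmed by the enumeration oracle).
f_v weights a pruning recursion f̃ over Σ_ε by β(v); the ε row of every
transition matrix being the identity makes all-gap descent emerge without
special cases.

## The aligner

Each progressive merge maximises the marginal likelihood of the tree
rooted at the current node over all pairwise alignments of the two child
sub-alignments. The likelihood is not monotone in alignment length —
φ(p(c_∅),·) is unimodal — so the dynamic program indexes partial
alignments by length k (three cubic tensors; cell = ‖ν‖/k × column
likelihood × best predecessor at layer k−1). The terminal length k₀ is
the argmax over k ∈ [max(|X|,|Y|), |X|+|Y|] of the best terminal cell.

Numerical and algorithmic choices:

* **Log domain everywhere.** Scores, φ (via log-gamma), and column
  likelihoods are accumulated in logs; pruning partials are kept linear
  but rescaled per node with the scale tracked in log space (the standard
  Felsenstein scaling), so no underflow occurs at any realistic depth.
* **Constant-time column scores.** Every sub-alignment column carries the
  rescaled partials f̃ at its root and the quantity
  log Σ_{w∈𝒜} b(w)β(w)(π·f̃_w). The latter is normalisation-free: at any
  later step, dividing by the current ‖τ‖+μ⁻¹ turns each summand into
  ι(w)·f_w, which is what lets the caches survive the re-normalisation of
  subtree-local contexts. Ancestral sets extend per merge as {v} (match),
  𝒜_left∪{v} (gap in Y), 𝒜_right∪{v} (gap in X).
* **Tie handling.** Log-score ties are detected with relative tolerance
  1e-10 (exact float equality would make the randomised rule unreachable)
  and resolved by a seeded uniform choice, for both per-cell traceback
  entries and k₀. Fixed seed ⇒ byte-identical output.
* **Rolling storage.** Score tensors are kept as two k-layers (a layer
  reads only the previous one; cells within a layer are independent — a
  property the tests verify by recomputing layers in shuffled order); the
  traceback tensor is kept in full.
* **Boundary cells** (i=0 or j=0, k>0) are filled by the gap-only
  recurrences with out-of-range predecessors at log-zero, making all-gap
  prefixes reachable.
* **Normalisation scope.** By default every merge rebuilds ‖τ‖, ‖ν‖, ι, β
  for the clade at hand, with the clade root taking the root role
  (`normalization="subtree"`); a `"global"` mode keeps the full-tree
  normaliser throughout. The two coincide at the root, so either way the
  reported likelihood is the exact full-tree marginal likelihood of the
  output — verified per dataset by the cache-free rescorer.
* **No early stopping.** The terminal score is empirically unimodal in k,
  but correctness is not allowed to depend on that observation; all
  layers are always evaluated.

Degenerate inputs are rejected rather than repaired: non-binary or
unrooted trees, zero/missing branch lengths, duplicate taxa, empty or
gapped input sequences, and all-gap columns in scoring inputs all raise
with a description. The β limit at μb→0 is exercised in tests only.

## Substitution models

JC69, K80(κ) and GTR for nucleotides; WAG and LG with their published
frequencies (overridable) for amino acids. All generators are normalised
to one expected substitution per unit branch length at stationarity
before μ is added, so branch lengths keep their usual units. Transition
matrices use the eigendecomposition of **Q**_ε when it is diagonalizable
to working precision — **Q**_ε is non-reversible (absorbing state), so
no symmetric shortcut applies — with scipy's scaling-and-squaring as the
fallback; they are computed once per context and cached. IUPAC ambiguity
codes are spread as unit indicators over compatible states.

## Simulator

The simulator (`simulate.simulate`) draws the root length from
Poisson(λ/μ) with characters i.i.d. π, then recurses: existing
characters take one draw from exp(b·**Q**_ε) per branch (absorption =
deletion below that point); Poisson(λb) insertions are placed at uniform
times and uniform positions, each evolving for its residual time, with
on-branch deaths discarded as unobservable. Evolving survivors first and
adding insertions second is equivalent to event-ordered simulation by
the exchangeability of the Poisson process and samples the exact
marginal. Homology is tracked by immutable character identities threaded
through a global column order, so the emitted truth alignment is exact.

What the simulator emulates is exactly the estimator's model — that is
the point of the verification protocols, which test correctness of the
implementation, not robustness: passing them shows the aligner maximises
and reports the PIP likelihood faithfully, not that PIP describes any
particular real dataset (real data have multi-residue indels and
rate variation, which the model excludes).

The 120-dataset verification suite uses 30 datasets per leaf count in
{4,5,6,7} with the rate pairs (0.1,0.1), (0.1,1), (1,0.1), (1,1) cycling
within each leaf count; random topologies by successive splitting of a
uniformly chosen branch; branch lengths U(0.05, 0.5). Root lengths are
conditioned to [5,8] by direct truncated-Poisson sampling (identical to
resample-until-inside, without the unbounded loop at small λ/μ), and
datasets with an empty leaf sequence are redrawn so every dataset is
alignable.

## Verification oracles

Two independent routes guard the fast paths:

* the cache-free scorer `msa_likelihood` re-prunes every column from the
  leaves with no shared state with the aligner's incremental caches;
  exhaustive trace enumeration (counts checked against the Delannoy
  recurrence, capped at 10⁶) plus this scorer bounds the DP from above;
* `oracle.column_likelihood_enumerated` sums explicitly over insertion
  node × inserted character × all Σ_ε state assignments, against which
  the pruning scorer agrees to <1e-12 on 2- and 3-leaf trees over every
  gap pattern.

Protocol sizes used by the test suite: 1000 random trees (2–64 leaves)
for the analytic identities; the 120-dataset likelihood match; 200
random instances (sub-alignment lengths ≤ 5, so ≤ 1683 enumerated
alignments each) for optimality; 2000 replicates × 3 rate pairs for
simulator stationarity; sequence lengths {8,16,32} for the cubic-scaling
check (cell-count ratio 8±15% per doubling; the exact finite-size ratios
are 7.1 and 7.5 because of the +1 boundary planes).

## Limitations

Single-residue indels only (long indels must be explained as runs of
events); no rate variation across sites or branches for indels; no codon
models; λ and μ are user inputs, not estimated; the guide tree is fixed
and never re-estimated; the progressive procedure is greedy across
merges — each merge is exactly optimal, the composition is a heuristic,
as in all progressive aligners.
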