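"""Simulation-based correctness protocols.

Two end-to-end checks of the aligner:

1. *Likelihood match*: on a 120-dataset simulated suite (4–7 leaves,
   four (λ, μ) rate pairs, root lengths conditioned to 5–8) the final
   log-likelihood reported by the progressive aligner must equal the
   cache-free scorer evaluated on the aligner's own output.
2. *Optimality*: on random small instances, exhaustive enumeration of
   every pairwise alignment with independent scoring must confirm that
   the dynamic program attains the maximum and returns a member of the
   argmax set.
"""

from __future__ import annotations

import numpy as np

from .aligner import SubAlignment, align_subalignments, leaf_subalignment
from .likelihood import PIPContext, msa_likelihood
from .oracle import best_by_enumeration
from .progressive import progressive_align
from .simulate import VERIFICATION_RATE_PAIRS, make_verification_suite, random_tree
from .substitution import jc69
from .tree import Tree

__all__ = [
    "likelihood_match_suite",
    "random_pair_instance",
    "optimality_check",
    "run_verification",
]

REL_TOL = 1e-9


def likelihood_match_suite(seed: int = 0) -> dict:
    """Protocol 1: aligner log-likelihood vs. independent rescoring, 120 datasets."""
    suite = make_verification_suite(seed)
    deltas = []
    n_match = 0
    for i, (tree, lam, mu, sim) in enumerate(suite):
        model = jc69(mu)
        result = progressive_align(sim.leaf_seqs, tree, model, lam, seed=seed + i)
        ctx = PIPContext(tree, model, lam)
        independent = msa_likelihood(result.msa, ctx)
        rel = abs(result.loglik - independent) / max(1.0, abs(independent))
        deltas.append(rel)
        if rel <= REL_TOL:
            n_match += 1
    return {
        "n_datasets": len(suite),
        "n_match": n_match,
        "n_mismatch": len(suite) - n_match,
        "max_rel_delta": float(max(deltas)),
    }


def random_pair_instance(
    rng: np.random.Generator,
) -> tuple[Tree, float, float, SubAlignment, SubAlignment, PIPContext]:
    """A random small DP instance: two child sub-alignments at a root node.

    Half the instances are two single sequences on a cherry (lengths
    1–5); the rest put a short pairwise alignment (built by the aligner
    on a two-leaf clade, lengths 1–3 each) against a single sequence on
    a three-leaf tree.  Rates are drawn from the four verification
    pairs; sequences are i.i.d. draws from the stationary distribution.
    """
    lam, mu = VERIFICATION_RATE_PAIRS[rng.integers(4)]
    model = jc69(mu)

    def rand_seq(lo: int, hi: int) -> str:
        n = int(rng.integers(lo, hi + 1))
        return "".join(model.alphabet[i] for i in rng.choice(4, size=n, p=model.pi))

    if rng.random() < 0.5:
        tree = random_tree(2, rng)
        left, right = tree.children[tree.root]
        X = leaf_subalignment(tree.labels[left], rand_seq(1, 5), left, tree, model)
        Y = leaf_subalignment(tree.labels[right], rand_seq(1, 5), right, tree, model)
    else:
        tree = random_tree(3, rng)
        left, right = tree.children[tree.root]
        if tree.is_leaf(left):  # make X the cherry side
            left, right = right, left
        ctx_cherry = PIPContext(tree, model, lam, node=left)
        a, b = tree.children[left]
        Xa = leaf_subalignment(tree.labels[a], rand_seq(1, 3), a, tree, model)
        Xb = leaf_subalignment(tree.labels[b], rand_seq(1, 2), b, tree, model)
        X, _, _ = align_subalignments(Xa, Xb, ctx_cherry, rng)
        Y = leaf_subalignment(tree.labels[right], rand_seq(1, 5), right, tree, model)
    ctx = PIPContext(tree, model, lam)
    return tree, lam, mu, X, Y, ctx


def optimality_check(seed: int = 0, n_instances: int = 200) -> dict:
    """Protocol 2: DP score vs. exhaustive enumeration on random instances."""
    rng = np.random.default_rng(seed)
    n_optimal = 0
    n_member = 0
    worst = 0.0
    for _ in range(n_instances):
        _, _, _, X, Y, ctx = random_pair_instance(rng)
        merged, dp_score, _ = align_subalignments(X, Y, ctx, rng)
        best, argmax = best_by_enumeration(X, Y, ctx)
        gap = best - dp_score
        worst = max(worst, gap)
        if abs(gap) <= REL_TOL * max(1.0, abs(best)):
            n_optimal += 1
        from .msa import Alignment

        out = Alignment(merged.taxa, merged.rows())
        if any(out == a for a in argmax):
            n_member += 1
    return {
        "n_instances": n_instances,
        "n_optimal": n_optimal,
        "n_suboptimal": n_instances - n_optimal,
        "n_argmax_member": n_member,
        "max_score_gap": float(worst),
    }


def run_verification(seed: int = 0, n_optimality: int = 200) -> dict:
    """Both protocols; the CLI's ``verify`` subcommand is a thin wrapper."""
    return {
        "seed": seed,
        "likelihood_match": likelihood_match_suite(seed),
        "optimality": optimality_check(seed, n_optimality),
    }
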