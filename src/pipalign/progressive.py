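"""Progressive alignment along a guide tree.

The guide tree is traversed in postorder; at every internal node the two
child sub-alignments are aligned by the full-maximum-likelihood dynamic
program, carrying the per-column caches upward so each column score at
the next step costs constant time.  The procedure ends at the root with
the complete alignment, whose log-likelihood is, by construction, the
marginal indel-process likelihood of the full tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aligner import SubAlignment, align_subalignments, leaf_subalignment
from .likelihood import PIPContext
from .msa import Alignment
from .substitution import SubstModel
from .tree import Tree

__all__ = ["ProgressiveResult", "progressive_align", "make_leaf_subalignment"]


@dataclass
class ProgressiveResult:
    """Final alignment, its log-likelihood at the root, and step diagnostics."""

    msa: Alignment
    loglik: float
    per_node_lengths: dict[int, int] = field(default_factory=dict)
    seed: int | None = None


def make_leaf_subalignment(
    taxon: str, seq: str, node: int, tree: Tree, model: SubstModel
) -> SubAlignment:
    """A single input sequence as a sub-alignment (one row, cached partials)."""
    return leaf_subalignment(taxon, seq, node, tree, model)


def progressive_align(
    seqs: dict[str, str],
    tree: Tree,
    model: SubstModel,
    lam: float,
    seed: int = 0,
    normalization: str = "subtree",
) -> ProgressiveResult:
    """Align unaligned sequences progressively under the indel process.

    Parameters
    ----------
    seqs : dict
        Taxon → ungapped sequence over the model alphabet; taxa must
        match the guide-tree leaves exactly.
    tree : Tree
        Rooted binary guide tree with branch lengths.
    model : SubstModel
        Substitution model carrying the deletion rate μ.
    lam : float
        Insertion rate λ.
    seed : int
        Seeds the tie-breaking choices in the dynamic program.
    normalization : str
        ``"subtree"`` rebuilds the Poisson normaliser for the clade at
        each merge (each step maximises the likelihood of the tree
        rooted there); ``"global"`` keeps the full-tree normaliser
        throughout.  Both coincide at the root.
    """
    tree_taxa = set(tree.leaf_labels)
    if set(seqs) != tree_taxa:
        missing = tree_taxa - set(seqs)
        extra = set(seqs) - tree_taxa
        raise ValueError(
            f"sequence taxa do not match guide-tree leaves "
            f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
        )
    rng = np.random.default_rng(seed)
    sub: dict[int, SubAlignment] = {}
    per_node_lengths: dict[int, int] = {}
    loglik = float("nan")
    for v in tree.postorder():
        if tree.is_leaf(v):
            label = tree.labels[v]
            sub[v] = leaf_subalignment(label, seqs[label], v, tree, model)
        else:
            ctx = PIPContext(tree, model, lam, node=v, normalization=normalization)
            left, right = tree.children[v]
            merged, score, _ = align_subalignments(sub.pop(left), sub.pop(right), ctx, rng)
            sub[v] = merged
            per_node_lengths[v] = merged.n_cols
            loglik = score
    final = sub[tree.root]
    msa = Alignment(final.taxa, final.rows())
    return ProgressiveResult(msa, loglik, per_node_lengths, seed)
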