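"""Marginal MSA likelihood under the Poisson indel process.

The model places single-character insertions on a rooted tree as a
Poisson process with intensity ``λ`` per unit branch length plus an
atomic mass ``λ/μ`` at the root (the root's virtual infinite stem), and
deletes characters at rate ``μ`` through an absorbing gap state added to
the substitution process.  The marginal likelihood of an alignment ``m``
factorises over columns,

    p_τ(m) = φ(p(c_∅), |m|) · Π_c p(c),

where ``φ`` marginalises all histories of characters that were inserted
and deleted without reaching any leaf ("unobservable histories"), and
``c_∅`` is the all-gap column.  Each column likelihood sums over the
possible insertion nodes,

    p(c) = Σ_v ι(v) f_v,

with ι(v) the insertion-point prior, and f_v a survival-weighted
Felsenstein pruning over the gap-augmented alphabet.  Everything here is
computed from the leaves up with per-node rescaling, and accumulated in
log space.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .msa import Alignment
from .substitution import SubstModel
from .tree import Tree

__all__ = [
    "PIPContext",
    "insertion_probs",
    "survival_probs",
    "log_phi",
    "column_likelihood",
    "msa_likelihood",
]


def insertion_probs(tree: Tree, mu: float) -> np.ndarray:
    """Insertion-point prior ι(v) for every node of the tree.

    ι(v) = b(v) / (‖τ‖ + μ⁻¹) on branches and ι(Ω) = μ⁻¹ / (‖τ‖ + μ⁻¹)
    at the root, so the values sum to one.
    """
    if not mu > 0:
        raise ValueError("mu must be strictly positive")
    denom = tree.total_length + 1.0 / mu
    iota = np.array(tree.branch_length) / denom
    iota[tree.root] = (1.0 / mu) / denom
    return iota


def survival_probs(tree: Tree, mu: float) -> np.ndarray:
    """Survival probability β(v) of a character inserted on the branch into v.

    β(Ω) = 1; on a branch of length b, β = (1 − e^{−μb}) / (μb), the
    chance that a character inserted at a uniform time on the branch
    still exists at the branch's lower end.
    """
    if not mu > 0:
        raise ValueError("mu must be strictly positive")
    b = np.array(tree.branch_length)
    beta = np.empty_like(b)
    nz = np.arange(len(b)) != tree.root
    beta[nz] = -np.expm1(-mu * b[nz]) / (mu * b[nz])
    beta[tree.root] = 1.0
    return beta


def log_phi(p_empty: float, m_len: int, nu_norm: float) -> float:
    """Log marginal likelihood of all unobservable histories.

    φ(p(c_∅), |m|) = ‖ν‖^{|m|} · exp(‖ν‖ (p(c_∅) − 1)) / |m|!
    """
    if not 0.0 <= p_empty <= 1.0:
        raise ValueError("p(c_∅) must lie in [0, 1]")
    if m_len < 0:
        raise ValueError("alignment length must be non-negative")
    if not nu_norm > 0:
        raise ValueError("nu must be strictly positive")
    return m_len * np.log(nu_norm) + nu_norm * (p_empty - 1.0) - gammaln(m_len + 1)


class PIPContext:
    """Per-node likelihood constants for a (sub)tree evaluation.

    The context fixes the tree scope (the clade rooted at ``node``, by
    default the whole tree), the indel rates, and the normalisation mode:

    * ``"subtree"`` (default): ‖τ‖, ‖ν‖, ι and β are those of the clade,
      with the evaluation root playing the root role (β = 1, insertion
      mass point).  This is the tree "rooted at v" that each progressive
      step maximises.
    * ``"global"``: the denominators use the full guide tree's length, so
      intermediate steps share one Poisson intensity; the evaluation root
      still takes the root role structurally.

    Branch transition matrices and the all-gap column quantities are
    computed once here and reused by every column evaluation.
    """

    def __init__(
        self,
        tree: Tree,
        model: SubstModel,
        lam: float,
        node: int | None = None,
        normalization: str = "subtree",
    ) -> None:
        if not lam > 0:
            raise ValueError("lambda must be strictly positive")
        if normalization not in ("subtree", "global"):
            raise ValueError("normalization must be 'subtree' or 'global'")
        self.tree = tree
        self.model = model
        self.lam = lam
        self.mu = model.mu
        self.root = tree.root if node is None else node
        self.normalization = normalization

        self.nodes = tree.subtree_nodes(self.root)  # postorder, eval root last
        self._in_scope = np.zeros(tree.n_nodes, dtype=bool)
        self._in_scope[self.nodes] = True
        self.leaves = [v for v in self.nodes if tree.is_leaf(v)]
        self.leaf_labels = [tree.labels[v] for v in self.leaves]

        tau_local = tree.subtree_length(self.root)
        tau_used = tree.total_length if normalization == "global" else tau_local
        self.tau = tau_used
        self.denom = tau_used + 1.0 / self.mu
        self.nu = lam * self.denom

        n = tree.n_nodes
        self.iota = np.zeros(n)
        self.beta = np.zeros(n)
        self.trans: dict[int, np.ndarray] = {}
        for v in self.nodes:
            if v == self.root:
                self.iota[v] = (1.0 / self.mu) / self.denom
                self.beta[v] = 1.0
            else:
                b = tree.branch_length[v]
                self.iota[v] = b / self.denom
                self.beta[v] = -np.expm1(-self.mu * b) / (self.mu * b)
                self.trans[v] = model.transition_probs(b)

        self._init_empty_column()

    # -- all-gap column -----------------------------------------------

    def _init_empty_column(self) -> None:
        """f̃ and f of the all-gap column at every node, and log p(c_∅)."""
        model, tree = self.model, self.tree
        s1 = model.n_states + 1
        self.ftilde_empty = np.zeros((tree.n_nodes, s1))
        self.f_empty = np.zeros(tree.n_nodes)
        for v in self.nodes:
            if tree.is_leaf(v):
                ft = np.zeros(s1)
                ft[-1] = 1.0
            else:
                ft = np.ones(s1)
                for w in tree.children[v]:
                    ft = ft * (self.trans[w] @ self.ftilde_empty[w])
            self.ftilde_empty[v] = ft
            m = float(ft[:-1] @ model.pi)
            self.f_empty[v] = 1.0 - self.beta[v] + self.beta[v] * m
        self.p_empty = float(
            np.sum(self.iota[self.nodes] * self.f_empty[self.nodes])
        )
        self.log_p_empty = float(np.log(self.p_empty))

    # -- pruning ------------------------------------------------------

    def prune(self, leaf_ind: np.ndarray):
        """Rescaled pruning over all columns at once.

        Parameters
        ----------
        leaf_ind : ndarray, shape (n_leaves, n_cols, |Σ|+1)
            Per-leaf partial-likelihood vectors, ordered as ``self.leaves``.

        Returns
        -------
        F : ndarray (n_nodes, n_cols, |Σ|+1)
            Rescaled partials f̃; rows outside the scope stay zero.
        logscale : ndarray (n_nodes, n_cols)
            Per-node, per-column log of the factored-out scale.
        """
        tree = self.tree
        n_cols = leaf_ind.shape[1]
        s1 = self.model.n_states + 1
        F = np.zeros((tree.n_nodes, n_cols, s1))
        logscale = np.zeros((tree.n_nodes, n_cols))
        leaf_pos = {v: i for i, v in enumerate(self.leaves)}
        for v in self.nodes:
            if tree.is_leaf(v):
                F[v] = leaf_ind[leaf_pos[v]]
            else:
                acc = np.ones((n_cols, s1))
                ls = np.zeros(n_cols)
                for w in tree.children[v]:
                    acc = acc * (F[w] @ self.trans[w].T)
                    ls = ls + logscale[w]
                scale = acc.max(axis=1)
                safe = np.where(scale > 0, scale, 1.0)
                F[v] = acc / safe[:, None]
                with np.errstate(divide="ignore"):
                    logscale[v] = ls + np.log(scale)
        return F, logscale

    def ancestral_mask(self, leaf_ind: np.ndarray) -> np.ndarray:
        """Membership of each node in the ancestral set 𝒜 per column.

        𝒜 is the most recent common ancestor of the gap-free leaves and
        all its ancestors up to the evaluation root — exactly the nodes
        whose clade contains every gap-free leaf.  All-gap columns get an
        all-false row.
        """
        tree = self.tree
        n_cols = leaf_ind.shape[1]
        # a leaf is gap-free in a column if its indicator has mass on Σ
        nongap = leaf_ind[:, :, :-1].sum(axis=2) > 0  # (n_leaves, n_cols)
        below = np.zeros((tree.n_nodes, n_cols))
        leaf_pos = {v: i for i, v in enumerate(self.leaves)}
        for v in self.nodes:
            if tree.is_leaf(v):
                below[v] = nongap[leaf_pos[v]]
            else:
                below[v] = sum(below[w] for w in tree.children[v])
        n_s = below[self.root]  # |𝒮| per column
        mask = (below == n_s[None, :]) & (n_s[None, :] > 0)
        mask &= self._in_scope[:, None]
        return mask

    def log_column_likelihoods(self, leaf_ind: np.ndarray) -> np.ndarray:
        """log p(c) for every column; all-gap columns get log p(c_∅)."""
        F, logscale = self.prune(leaf_ind)
        mask = self.ancestral_mask(leaf_ind)
        m = F[:, :, :-1] @ self.model.pi  # (n_nodes, n_cols)
        with np.errstate(divide="ignore"):
            terms = (
                np.log(self.iota)[:, None]
                + np.log(self.beta)[:, None]
                + np.log(m)
                + logscale
            )
        terms = np.where(mask, terms, -np.inf)
        logp = logsumexp(terms, axis=0)
        empty = ~mask.any(axis=0)
        logp[empty] = self.log_p_empty
        return logp


def _leaf_indicators(aln: Alignment, ctx: PIPContext) -> np.ndarray:
    aln = aln.reorder(ctx.leaf_labels)
    return aln.leaf_indicators(ctx.model)


def column_likelihood(column: dict[str, str], ctx: PIPContext) -> float:
    """Likelihood p(c) of one column given as a taxon→symbol map."""
    aln = Alignment(tuple(column.keys()), tuple(column.values()))
    ind = _leaf_indicators(aln, ctx)
    return float(np.exp(ctx.log_column_likelihoods(ind)[0]))


def msa_likelihood(aln: Alignment, ctx: PIPContext) -> float:
    """Log marginal likelihood of a full alignment (cache-free scorer).

    Every column is re-pruned from the leaves; nothing is shared with the
    incremental caches used inside the aligner, which makes this the
    independent cross-check for the dynamic program.
    """
    if set(aln.taxa) != set(ctx.leaf_labels):
        raise ValueError("alignment taxa do not match the tree scope")
    if aln.has_all_gap_column():
        raise ValueError("input alignments must not contain all-gap columns")
    if aln.n_cols == 0:
        return log_phi(ctx.p_empty, 0, ctx.nu)
    ind = _leaf_indicators(aln, ctx)
    logp = ctx.log_column_likelihoods(ind)
    return float(logp.sum() + log_phi(ctx.p_empty, aln.n_cols, ctx.nu))
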