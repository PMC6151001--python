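"""Brute-force verification oracles for the aligner.

Two independent cross-checks of the dynamic program:

* exhaustive enumeration of every monotone pairwise alignment of two
  sub-alignments (their count is a Delannoy number), each scored with
  the cache-free marginal-likelihood scorer — the DP must attain the
  maximum and its output must be in the argmax set;
* a latent-variable column scorer that enumerates insertion node ×
  inserted character × full state assignments explicitly, against which
  the pruning-based column likelihood is validated on tiny trees.

The scorers here share no code path with the aligner's incremental
caches, which is what makes agreement meaningful.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

from .aligner import SubAlignment
from .likelihood import PIPContext, msa_likelihood
from .msa import Alignment
from .substitution import GAP

__all__ = [
    "delannoy",
    "enumerate_traces",
    "merge_by_trace",
    "enumerate_pairwise",
    "best_by_enumeration",
    "column_likelihood_enumerated",
]


@lru_cache(maxsize=None)
def delannoy(m: int, n: int) -> int:
    """Number of monotone {M,X,Y} traces consuming m and n columns."""
    if m == 0 or n == 0:
        return 1
    return delannoy(m - 1, n) + delannoy(m, n - 1) + delannoy(m - 1, n - 1)


def enumerate_traces(m: int, n: int, cap: int = 10**6) -> list[str]:
    """All monotone traces over {M, X, Y} consuming m X-columns and n Y-columns."""
    if delannoy(m, n) > cap:
        raise ValueError(
            f"enumeration of {delannoy(m, n)} alignments exceeds the cap {cap}; "
            "shrink the instance"
        )
    out: list[str] = []

    def rec(i: int, j: int, prefix: list[str]) -> None:
        if i == m and j == n:
            out.append("".join(prefix))
            return
        if i < m and j < n:
            prefix.append("M")
            rec(i + 1, j + 1, prefix)
            prefix.pop()
        if i < m:
            prefix.append("X")
            rec(i + 1, j, prefix)
            prefix.pop()
        if j < n:
            prefix.append("Y")
            rec(i, j + 1, prefix)
            prefix.pop()

    rec(0, 0, [])
    return out


def merge_by_trace(X: SubAlignment, Y: SubAlignment, trace: str) -> Alignment:
    """Stack the two sub-alignments into one MSA along a trace."""
    rows_x = ["" for _ in range(X.n_taxa)]
    rows_y = ["" for _ in range(Y.n_taxa)]
    i = j = 0
    for t in trace:
        if t in "MX":
            for r in range(X.n_taxa):
                rows_x[r] += X.cols[r, i]
            i += 1
        else:
            for r in range(X.n_taxa):
                rows_x[r] += GAP
        if t in "MY":
            for r in range(Y.n_taxa):
                rows_y[r] += Y.cols[r, j]
            j += 1
        else:
            for r in range(Y.n_taxa):
                rows_y[r] += GAP
    if i != X.n_cols or j != Y.n_cols:
        raise ValueError("trace does not consume both sub-alignments")
    return Alignment(X.taxa + Y.taxa, tuple(rows_x + rows_y))


def enumerate_pairwise(
    X: SubAlignment, Y: SubAlignment, ctx: PIPContext, cap: int = 10**6
) -> list[tuple[str, Alignment, float]]:
    """Every pairwise alignment of X and Y with its independent score."""
    results = []
    for trace in enumerate_traces(X.n_cols, Y.n_cols, cap):
        merged = merge_by_trace(X, Y, trace)
        score = msa_likelihood(merged, ctx)
        results.append((trace, merged, score))
    return results


def best_by_enumeration(
    X: SubAlignment,
    Y: SubAlignment,
    ctx: PIPContext,
    cap: int = 10**6,
    tol: float = 1e-9,
) -> tuple[float, list[Alignment]]:
    """Maximum independent score over all pairwise alignments, and the argmax set.

    The argmax set contains every enumerated alignment within ``tol`` of
    the maximum (log scale).
    """
    scored = enumerate_pairwise(X, Y, ctx, cap)
    best = max(s for _, _, s in scored)
    arg = [aln for _, aln, s in scored if s >= best - tol]
    return best, arg


def column_likelihood_enumerated(column: dict[str, str], ctx: PIPContext) -> float:
    """p(c) by explicit enumeration of the latent homology path.

    Sums over the insertion node v, the survival outcome on the branch
    into v, and every assignment of gap-augmented states to the nodes of
    the clade below v, multiplying insertion prior, survival weight,
    starting frequency and branch transition probabilities, with an
    indicator that the leaves show exactly the observed column.  Only
    feasible on toy trees; it is the ground truth for the pruning-based
    scorer.
    """
    tree, model = ctx.tree, ctx.model
    s = model.n_states
    eps = s
    obs = {}
    for v in ctx.leaves:
        sym = column[tree.labels[v]]
        obs[v] = eps if sym == GAP else model.alphabet.index(sym)
    total = 0.0
    for v in ctx.nodes:
        clade = tree.subtree_nodes(v)
        outside = [u for u in ctx.leaves if u not in clade]
        outside_all_gap = all(obs[u] == eps for u in outside)
        leaves_in = [u for u in clade if tree.is_leaf(u)]
        all_gap_inside = all(obs[u] == eps for u in leaves_in)
        # non-survival: the character dies before v, nothing below observes it
        f_v = 0.0
        if all_gap_inside:
            f_v += 1.0 - ctx.beta[v]
        # survival: state at v drawn from pi, propagate over all assignments
        surv = 0.0
        internal = [u for u in clade if u != v and not tree.is_leaf(u)]
        for sigma_v in range(s):
            p_start = model.pi[sigma_v]
            if v in leaves_in and obs[v] != sigma_v:
                continue  # a surviving character at a leaf must be the observed one
            for assign in product(range(s + 1), repeat=len(internal)):
                state = {v: sigma_v}
                state.update(dict(zip(internal, assign)))
                for u in leaves_in:
                    if u != v:
                        state[u] = obs[u]
                p = p_start
                for u in clade:
                    if u == v:
                        continue
                    P = ctx.trans[u] if u in ctx.trans else model.transition_probs(
                        tree.branch_length[u]
                    )
                    p *= P[state[tree.parent[u]], state[u]]
                surv += p
        f_v += ctx.beta[v] * surv
        if outside_all_gap:
            total += ctx.iota[v] * f_v
    return total
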