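"""Pairwise alignment of two sub-alignments by full maximum likelihood.

At an internal guide-tree node ``v`` the two child sub-alignments X and
Y are aligned so as to maximise the marginal indel-process likelihood of
the tree rooted at ``v``.  Because that likelihood is not monotone in
the alignment length (the unobservable-history factor φ first grows,
then shrinks), the dynamic program carries the partial alignment length
as a third index: three score tensors S^M, S^X, S^Y of logical size
(|X|+1)×(|Y|+1)×(|X|+|Y|+1) hold the likelihood of the best partial
alignment of the first i columns of X and j of Y at total length k,
ending respectively in a match column, an X-against-gaps column, or a
Y-against-gaps column.  Each cell multiplies ‖ν‖/k — which telescopes
into φ along the k axis — by the stacked-column likelihood and the best
predecessor at layer k−1.

Column likelihoods are evaluated in constant time by reusing per-column
caches carried with each sub-alignment: the rescaled pruning partials f̃
at the sub-alignment root and the accumulated ancestral-set partial sum
Σ_{w∈𝒜} ι(w)·f_w, extended at each merge according to

    𝒜 = {v}            for a match column,
    𝒜_left  ∪ {v}      for an X-against-gaps column,
    𝒜_right ∪ {v}      for a Y-against-gaps column.

Scores live in log space throughout; the score tensors are stored as two
rolling k-layers (a layer depends only on the one below), while the
traceback tensor TR is kept in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import PIPContext, log_phi
from .substitution import GAP
from .tree import Tree

__all__ = [
    "SubAlignment",
    "DPState",
    "leaf_subalignment",
    "match_scores",
    "gap_scores",
    "column_score_match",
    "column_score_gap",
    "forward",
    "backtrack",
    "align_subalignments",
]

# traceback codes
_M, _X, _Y, _UNSET = 0, 1, 2, 3
TIE_RTOL = 1e-10


@dataclass
class SubAlignment:
    """An alignment over one clade with per-column likelihood caches.

    Attributes
    ----------
    node : int
        Guide-tree node this sub-alignment is rooted at.
    taxa : tuple[str, ...]
        Leaf labels of the clade (postorder).
    cols : ndarray of single characters, shape (n_taxa, n_cols)
        The alignment; gaps are ``'-'``.  No column is all-gap.
    F : ndarray (n_cols, |Σ|+1)
        Rescaled pruning partials f̃ at ``node``.
    logscale : ndarray (n_cols,)
        Log of the scale factored out of each f̃ column.
    logA : ndarray (n_cols,)
        Log of Σ_{w∈𝒜} b(w)·β(w)·(π·f̃_w) with the ancestral set taken
        inside this clade; dividing by the step's normaliser turns each
        summand into ι(w)·f_w.  NaN at the global root, where it can
        never be consumed.
    """

    node: int
    taxa: tuple[str, ...]
    cols: np.ndarray
    F: np.ndarray
    logscale: np.ndarray
    logA: np.ndarray

    @property
    def n_cols(self) -> int:
        return self.cols.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.cols.shape[0]

    def rows(self) -> tuple[str, ...]:
        return tuple("".join(r) for r in self.cols)


@dataclass
class DPState:
    """Forward-phase result: traceback tensor and terminal diagnostics."""

    tr: np.ndarray  # (|X|+1, |Y|+1, |X|+|Y|+1) uint8 codes
    k0: int
    score: float  # log-likelihood at the selected terminal cell
    terminal: np.ndarray  # best score at (|X|,|Y|,k) for every k
    n_cells: int  # number of (i,j,k,state) cell evaluations


def _branch_beta(mu: float, b: float) -> float:
    return -np.expm1(-mu * b) / (mu * b)


def leaf_subalignment(taxon: str, seq: str, node: int, tree: Tree, model) -> SubAlignment:
    """Wrap an input sequence as a single-row sub-alignment with caches."""
    if len(seq) == 0:
        raise ValueError(f"empty sequence for taxon {taxon!r}")
    if GAP in seq:
        raise ValueError(
            f"sequence for {taxon!r} contains '-': gaps are alignment output, not input"
        )
    cols = np.array([list(seq)], dtype="<U1")
    F = np.stack([model.indicator(ch) for ch in seq])
    m = F[:, :-1] @ model.pi
    b = tree.branch_length[node]
    beta = _branch_beta(model.mu, b)
    logA = np.log(b * beta * m)
    return SubAlignment(node, (taxon,), cols, F, np.zeros(len(seq)), logA)


# -- constant-time column scores ---------------------------------------


def _child_setup(X: SubAlignment, Y: SubAlignment, ctx: PIPContext):
    """Transition-propagated partials of both children and the all-gap column."""
    PL = ctx.trans[X.node]
    PR = ctx.trans[Y.node]
    gX = X.F @ PL.T  # (|X|, s+1)
    gY = Y.F @ PR.T
    geX = PL @ ctx.ftilde_empty[X.node]  # (s+1,)
    geY = PR @ ctx.ftilde_empty[Y.node]
    return gX, gY, geX, geY


def match_scores(X: SubAlignment, Y: SubAlignment, ctx: PIPContext) -> np.ndarray:
    """log p of every matched column [X_i; Y_j], shape (|X|, |Y|).

    A match makes the two columns homologous, so the ancestral set is
    {v} alone: p = ι(v)·β(v)·Σ_σ π(σ)·f̃_v(σ) with f̃_v the product of
    the two transition-propagated child partials.
    """
    gX, gY, _, _ = _child_setup(X, Y, ctx)
    pi = ctx.model.pi
    m = (gX[:, :-1] * pi[None, :]) @ gY[:, :-1].T
    v = ctx.root
    with np.errstate(divide="ignore"):
        return (
            np.log(ctx.iota[v] * ctx.beta[v])
            + np.log(m)
            + X.logscale[:, None]
            + Y.logscale[None, :]
        )


def gap_scores(X: SubAlignment, Y: SubAlignment, ctx: PIPContext, which: str) -> np.ndarray:
    """log p of columns of one child stacked against all-gaps on the other.

    For an X-against-gaps column the ancestral set is 𝒜_left ∪ {v}: the
    cached partial sum over 𝒜_left is reused unchanged and only the root
    term is new (symmetrically for Y).
    """
    gX, gY, geX, geY = _child_setup(X, Y, ctx)
    pi = ctx.model.pi
    v = ctx.root
    if which == "X":
        g, ge, sub = gX, geY, X
    elif which == "Y":
        g, ge, sub = gY, geX, Y
    else:
        raise ValueError("which must be 'X' or 'Y'")
    m = (g[:, :-1] * ge[None, :-1]) @ pi
    with np.errstate(divide="ignore"):
        root_term = np.log(ctx.iota[v] * ctx.beta[v] * m) + sub.logscale
        anc_term = sub.logA - np.log(ctx.denom)
    return np.logaddexp(anc_term, root_term)


def column_score_match(X: SubAlignment, i: int, Y: SubAlignment, j: int, ctx: PIPContext) -> float:
    """log p of the single matched column [X_i; Y_j]."""
    return float(match_scores(X, Y, ctx)[i, j])


def column_score_gap(X: SubAlignment, Y: SubAlignment, i: int, ctx: PIPContext, which: str) -> float:
    """log p of column i of one child against an all-gap column on the other."""
    return float(gap_scores(X, Y, ctx, which)[i])


# -- forward phase -----------------------------------------------------


def _tie_argmax(cands: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Argmax along axis 0 with seeded uniform choice among near-ties."""
    best = cands.max(axis=0)
    tol = TIE_RTOL * np.maximum(1.0, np.abs(best))
    tied = cands >= best - tol
    tied &= np.isfinite(best)[None]
    r = rng.random(cands.shape)
    return np.where(tied, r, -1.0).argmax(axis=0)


def forward(
    X: SubAlignment,
    Y: SubAlignment,
    ctx: PIPContext,
    rng: np.random.Generator,
) -> DPState:
    """Fill the three score tensors layer by layer and select k₀.

    Layer k is computed from layer k−1 alone (all its cells are mutually
    independent, which is what makes the layer loop parallelisable); the
    scores are kept as two rolling layers, the traceback tensor in full.
    """
    if set(X.taxa) & set(Y.taxa):
        raise ValueError("sub-alignments share taxa")
    I, J = X.n_cols, Y.n_cols
    K = I + J
    pM = match_scores(X, Y, ctx)
    pX = gap_scores(X, Y, ctx, "X")
    pY = gap_scores(X, Y, ctx, "Y")
    lognu = np.log(ctx.nu)

    NEG = -np.inf
    V_prev = np.full((I + 1, J + 1), NEG)
    V_prev[0, 0] = log_phi(ctx.p_empty, 0, ctx.nu)
    tr = np.full((I + 1, J + 1, K + 1), _UNSET, dtype=np.uint8)
    terminal = np.full(K + 1, NEG)
    if I == 0 and J == 0:
        terminal[0] = V_prev[0, 0]
    n_cells = 0

    cand = np.full((3, I + 1, J + 1), NEG)
    for k in range(1, K + 1):
        w = lognu - np.log(k)
        cand.fill(NEG)
        cand[_M, 1:, 1:] = w + pM + V_prev[:-1, :-1]
        cand[_X, 1:, :] = w + pX[:, None] + V_prev[:-1, :]
        cand[_Y, :, 1:] = w + pY[None, :] + V_prev[:, :-1]
        n_cells += 3 * (I + 1) * (J + 1)
        V_k = cand.max(axis=0)
        V_k[0, 0] = NEG  # (0,0,k>0) is unreachable
        choice = _tie_argmax(cand, rng)
        tr[:, :, k] = np.where(np.isfinite(V_k), choice, _UNSET)
        terminal[k] = V_k[I, J]
        V_prev = V_k

    lo = max(I, J)
    window = terminal[lo : K + 1]
    best = window.max()
    if not np.isfinite(best):
        raise AssertionError("no finite terminal cell; inputs were invalid")
    tol = TIE_RTOL * max(1.0, abs(best))
    tied = np.flatnonzero(window >= best - tol)
    k0 = int(lo + tied[rng.integers(len(tied))])
    return DPState(tr, k0, float(terminal[k0]), terminal, n_cells)


def backtrack(state: DPState, I: int, J: int) -> list[str]:
    """Recover the column trace from (|X|,|Y|,k₀) down to (0,0,0).

    Returns a list over {'M','X','Y'} of length k₀ in left-to-right
    column order; 'M' consumes a column of both children, 'X'/'Y' one
    column of the named child against gaps.
    """
    i, j, k = I, J, state.k0
    trace: list[str] = []
    codes = "MXY"
    while k > 0:
        t = state.tr[i, j, k]
        if t == _UNSET:
            raise AssertionError("traceback reached an unset cell")
        trace.append(codes[t])
        if t == _M:
            i, j, k = i - 1, j - 1, k - 1
        elif t == _X:
            i, k = i - 1, k - 1
        else:
            j, k = j - 1, k - 1
    if i != 0 or j != 0:
        raise AssertionError("traceback did not consume both sub-alignments")
    return trace[::-1]


# -- merge -------------------------------------------------------------


def _merge(
    X: SubAlignment,
    Y: SubAlignment,
    trace: list[str],
    ctx: PIPContext,
    tree: Tree,
) -> SubAlignment:
    """Build the merged sub-alignment and extend its caches along Eq. 𝒜 rules."""
    v = ctx.root
    model = ctx.model
    pi = model.pi
    s1 = model.n_states + 1
    gX, gY, geX, geY = _child_setup(X, Y, ctx)
    k0 = len(trace)
    nT = X.n_taxa + Y.n_taxa
    cols = np.full((nT, k0), GAP, dtype="<U1")
    Fraw = np.empty((k0, s1))
    ls = np.empty(k0)
    logA_prev = np.full(k0, -np.inf)  # carried 𝒜 sum from the gap-free child
    i = j = 0
    for c, t in enumerate(trace):
        if t == "M":
            cols[: X.n_taxa, c] = X.cols[:, i]
            cols[X.n_taxa :, c] = Y.cols[:, j]
            Fraw[c] = gX[i] * gY[j]
            ls[c] = X.logscale[i] + Y.logscale[j]
            i += 1
            j += 1
        elif t == "X":
            cols[: X.n_taxa, c] = X.cols[:, i]
            Fraw[c] = gX[i] * geY
            ls[c] = X.logscale[i]
            logA_prev[c] = X.logA[i]
            i += 1
        else:
            cols[X.n_taxa :, c] = Y.cols[:, j]
            Fraw[c] = geX * gY[j]
            ls[c] = Y.logscale[j]
            logA_prev[c] = Y.logA[j]
            j += 1
    scale = Fraw.max(axis=1)
    F = Fraw / scale[:, None]
    ls = ls + np.log(scale)
    if v == tree.root:
        logA = np.full(k0, np.nan)  # the global root is never a child
    else:
        b = tree.branch_length[v]
        beta = _branch_beta(model.mu, b)
        m = F[:, :-1] @ pi
        logA = np.logaddexp(logA_prev, np.log(b * beta * m) + ls)
    return SubAlignment(v, X.taxa + Y.taxa, cols, F, ls, logA)


def align_subalignments(
    X: SubAlignment,
    Y: SubAlignment,
    ctx: PIPContext,
    rng: np.random.Generator,
) -> tuple[SubAlignment, float, DPState]:
    """Align two child sub-alignments at ctx's root node.

    Returns the merged sub-alignment (with caches ready for the next
    progressive step), the log-likelihood of the selected alignment on
    the tree rooted here, and the DP state for diagnostics.
    """
    state = forward(X, Y, ctx, rng)
    trace = backtrack(state, X.n_cols, Y.n_cols)
    merged = _merge(X, Y, trace, ctx, ctx.tree)
    return merged, state.score, state
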