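"""Sequence evolution simulator under the Poisson indel process.

Characters evolve independently down the tree: the root sequence is
drawn at the stationary length (Poisson with mean λ/μ, characters i.i.d.
from π), each existing character transitions along a branch of length b
according to exp(b·Q_ε) (absorption into ε deletes it everywhere below),
and new characters are inserted on the branch as a Poisson process with
rate λ per unit length, each entering at a uniform position and evolving
for its residual time.  Homology is tracked by immutable character
identities, so the emitted true alignment is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .msa import Alignment
from .substitution import GAP, SubstModel
from .tree import Tree

__all__ = ["SimResult", "simulate", "random_tree", "make_verification_suite"]

VERIFICATION_RATE_PAIRS = ((0.1, 0.1), (0.1, 1.0), (1.0, 0.1), (1.0, 1.0))


@dataclass
class SimResult:
    """True alignment, ungapped leaf sequences, and per-branch event counts."""

    true_msa: Alignment
    leaf_seqs: dict[str, str]
    events: dict[int, dict[str, int]]
    seed: int | None = None


@dataclass
class _Char:
    uid: int
    state: int


def simulate(
    tree: Tree,
    model: SubstModel,
    lam: float,
    seed: int | np.random.Generator = 0,
    root_length: int | None = None,
) -> SimResult:
    """Run the generative process once and return sequences plus truth.

    ``root_length`` overrides the Poisson(λ/μ) draw at the root, which is
    how length-conditioned datasets are produced.  Characters inserted
    and deleted before reaching any leaf are dropped from the emitted
    alignment — they are exactly the unobservable histories the scorer
    marginalises analytically.
    """
    if not lam > 0:
        raise ValueError("lambda must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = model.mu
    s = model.n_states
    pi = model.pi

    next_uid = 0
    master: list[int] = []  # global homology column order

    def fresh_uid() -> int:
        nonlocal next_uid
        next_uid += 1
        return next_uid - 1

    k0 = int(rng.poisson(lam / mu)) if root_length is None else int(root_length)
    root_seq = [_Char(fresh_uid(), int(rng.choice(s, p=pi))) for _ in range(k0)]
    master.extend(ch.uid for ch in root_seq)

    events: dict[int, dict[str, int]] = {}
    leaf_states: dict[str, list[_Char]] = {}

    def master_insert(uid: int, seq: list[_Char], slot: int) -> None:
        if slot > 0:
            master.insert(master.index(seq[slot - 1].uid) + 1, uid)
        elif seq:
            master.insert(master.index(seq[0].uid), uid)
        else:
            master.append(uid)

    def evolve_branch(parent_seq: list[_Char], v: int) -> list[_Char]:
        b = tree.branch_length[v]
        P = model.transition_probs(b)
        ev = {"insertions": 0, "deletions": 0, "substitutions": 0}
        out: list[_Char] = []
        for ch in parent_seq:
            new_state = int(rng.choice(s + 1, p=P[ch.state]))
            if new_state == s:
                ev["deletions"] += 1
            else:
                if new_state != ch.state:
                    ev["substitutions"] += 1
                out.append(_Char(ch.uid, new_state))
        n_ins = int(rng.poisson(lam * b))
        for _ in range(n_ins):
            u = rng.uniform(0.0, b)
            state = int(rng.choice(s, p=pi))
            Pres = model.transition_probs(b - u)
            end_state = int(rng.choice(s + 1, p=Pres[state]))
            if end_state == s:
                continue  # died on the branch: unobservable below
            ev["insertions"] += 1
            slot = int(rng.integers(len(out) + 1))
            uid = fresh_uid()
            master_insert(uid, out, slot)
            out.insert(slot, _Char(uid, end_state))
        events[v] = ev
        return out

    def descend(v: int, seq: list[_Char]) -> None:
        if tree.is_leaf(v):
            leaf_states[tree.labels[v]] = seq
            return
        for w in tree.children[v]:
            descend(w, evolve_branch(seq, w))

    descend(tree.root, root_seq)

    observed = [uid for uid in master if any(
        any(ch.uid == uid for ch in seq) for seq in leaf_states.values()
    )]
    col_of = {uid: j for j, uid in enumerate(observed)}
    labels = tree.leaf_labels
    rows = []
    for lab in labels:
        row = [GAP] * len(observed)
        for ch in leaf_states[lab]:
            row[col_of[ch.uid]] = model.alphabet[ch.state]
        rows.append("".join(row))
    true_msa = Alignment(tuple(labels), tuple(rows))
    leaf_seqs = {lab: r.replace(GAP, "") for lab, r in zip(labels, rows)}
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return SimResult(true_msa, leaf_seqs, events, seed_val)


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    blen_range: tuple[float, float] = (0.05, 0.5),
) -> Tree:
    """Random rooted binary topology by successive leaf attachment.

    Starts from a two-leaf tree and repeatedly splits a uniformly chosen
    branch to attach the next leaf; branch lengths are drawn uniformly
    from ``blen_range``.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    lo, hi = blen_range
    # children structure built top-down with string placeholders
    children: dict[int, list[int]] = {0: []}
    parent = {0: -1}
    counter = 1

    def new_node(par: int) -> int:
        nonlocal counter
        children[counter] = []
        parent[counter] = par
        children[par].append(counter)
        counter += 1
        return counter - 1

    new_node(0)
    new_node(0)
    for _ in range(n_leaves - 2):
        # split the branch above a uniformly chosen non-root node
        target = int(rng.integers(1, counter))
        par = parent[target]
        mid = new_node(par)
        children[par].remove(target)
        children[mid].append(target)
        parent[target] = mid
        new_node(mid)
    # emit newick with uniform branch lengths and leaf labels
    leaf_names = {}
    for i, v in enumerate(v for v in children if not children[v]):
        leaf_names[v] = f"T{i + 1}"

    def nwk(v: int) -> str:
        if not children[v]:
            core = leaf_names[v]
        else:
            core = "(" + ",".join(nwk(w) for w in children[v]) + ")"
        if parent[v] == -1:
            return core
        return f"{core}:{rng.uniform(lo, hi):.6f}"

    from .tree import parse_newick

    return parse_newick(nwk(0) + ";")


def _truncated_poisson(rng: np.random.Generator, mean: float, lo: int, hi: int) -> int:
    """Poisson(mean) conditioned on the closed range [lo, hi].

    Sampled directly from the renormalised pmf, which is exactly the
    resample-until-inside distribution without the rejection loop.
    """
    ks = np.arange(lo, hi + 1)
    logw = ks * np.log(mean) - gammaln(ks + 1)  # the e^-mean factor cancels
    w = np.exp(logw - logw.max())
    return int(rng.choice(ks, p=w / w.sum()))


def make_verification_suite(
    seed: int = 0,
    model_factory=None,
    paper_replica: bool = True,
) -> list[tuple[Tree, float, float, SimResult]]:
    """The 120-dataset correctness suite.

    Thirty datasets per leaf count in {4, 5, 6, 7}; within each leaf
    count the four (λ, μ) rate pairs (0.1, 0.1), (0.1, 1), (1, 0.1) and
    (1, 1) cycle.  In replica mode the root sequence length is
    conditioned to lie in [5, 8] and datasets with an empty leaf
    sequence are redrawn, so every dataset is alignable.
    """
    from .substitution import jc69

    if model_factory is None:
        model_factory = jc69
    rng = np.random.default_rng(seed)
    suite = []
    for n_leaves in (4, 5, 6, 7):
        for rep in range(30):
            lam, mu = VERIFICATION_RATE_PAIRS[rep % 4]
            model = model_factory(mu)
            while True:
                tree = random_tree(n_leaves, rng)
                rl = _truncated_poisson(rng, lam / mu, 5, 8) if paper_replica else None
                sim = simulate(tree, model, lam, rng, root_length=rl)
                if paper_replica and any(len(s) == 0 for s in sim.leaf_seqs.values()):
                    continue
                break
            suite.append((tree, lam, mu, sim))
    return suite
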