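import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from pipalign import (
    Alignment,
    PIPContext,
    column_likelihood,
    insertion_probs,
    jc69,
    log_phi,
    msa_likelihood,
    parse_newick,
    survival_probs,
)
from pipalign.oracle import column_likelihood_enumerated

from conftest import random_trees


# -- insertion prior and survival probability --------------------------


def test_insertion_prior_printed_values():
    # total length 1, mu=1: root mass = (1/1)/(1+1) = 0.5
    t = parse_newick("(A:0.5,B:0.5);")
    iota = insertion_probs(t, mu=1.0)
    assert iota[t.root] == pytest.approx(0.5, abs=1e-12)
    # branches 0.3 each, mu=1: leaf share 0.3/1.6
    t2 = parse_newick("(A:0.3,B:0.3);")
    iota2 = insertion_probs(t2, mu=1.0)
    for v in t2.leaves:
        assert iota2[v] == pytest.approx(0.1875, abs=1e-12)


def test_insertion_prior_sums_to_one(rng):
    for t in random_trees(60, rng):
        mu = float(rng.uniform(0.1, 3.0))
        assert insertion_probs(t, mu).sum() == pytest.approx(1.0, abs=1e-10)


def test_survival_probability_values():
    t = parse_newick("(A:1.0,B:1.0);")
    beta = survival_probs(t, mu=1.0)
    assert beta[t.root] == 1.0
    for v in t.leaves:
        assert beta[v] == pytest.approx((1 - np.exp(-1)) / 1, abs=1e-12)
    # short-branch limit: beta -> 1
    t2 = parse_newick("(A:1e-8,B:1e-8);")
    assert survival_probs(t2, mu=1.0)[0] == pytest.approx(1.0, abs=1e-7)
    t3 = parse_newick("(A:0.5,B:2.0);")
    b3 = survival_probs(t3, mu=0.8)
    assert np.all((b3[: t3.root] > 0) & (b3[: t3.root] < 1))


# -- unobservable-history factor ---------------------------------------


def test_log_phi_closed_form_edges():
    nu = 3.7
    assert log_phi(0.4, 0, nu) == pytest.approx(nu * (0.4 - 1.0), abs=1e-12)
    # p(c_empty)=1: phi = nu^m / m!
    from scipy.special import gammaln

    for m in (0, 1, 5, 20):
        assert log_phi(1.0, m, nu) == pytest.approx(
            m * np.log(nu) - gammaln(m + 1), abs=1e-12
        )
    with pytest.raises(ValueError):
        log_phi(1.5, 3, nu)
    with pytest.raises(ValueError):
        log_phi(0.5, -1, nu)


# -- pruning partials --------------------------------------------------


def test_leaf_partials_are_indicators(cherry, jc):
    ctx = PIPContext(cherry, jc, lam=1.0)
    aln = Alignment(("A", "B"), ("A", "-"))
    ind = aln.reorder(ctx.leaf_labels).leaf_indicators(jc)
    F, ls = ctx.prune(ind)
    la, lb = ctx.leaves
    assert list(F[la, 0]) == [1, 0, 0, 0, 0]
    assert list(F[lb, 0]) == [0, 0, 0, 0, 1]
    assert np.all(ls[[la, lb]] == 0)


def test_internal_partial_matches_brute_double_sum(jc):
    """Cherry with both leaves 'A', b=0.1: root f-tilde vs explicit sums."""
    t = parse_newick("(A:0.1,B:0.1);")
    ctx = PIPContext(t, jc, lam=1.0)
    aln = Alignment(("A", "B"), ("A", "A"))
    ind = aln.reorder(ctx.leaf_labels).leaf_indicators(jc)
    F, ls = ctx.prune(ind)
    P = expm(0.1 * jc.Q_eps)
    e_a = np.array([1.0, 0, 0, 0, 0])
    expected = np.empty(5)
    for s in range(5):
        left = sum(P[s, sp] * e_a[sp] for sp in range(5))
        right = sum(P[s, sp] * e_a[sp] for sp in range(5))
        expected[s] = left * right
    got = F[t.root, 0] * np.exp(ls[t.root, 0])
    assert np.allclose(got, expected, atol=1e-12)


def test_empty_column_partials(cherry, jc):
    """All-gap column: leaf f = 1 - beta; root f = sum_sigma pi f-tilde."""
    ctx = PIPContext(cherry, jc, lam=1.0)
    beta = survival_probs(cherry, jc.mu)
    for v in cherry.leaves:
        assert ctx.f_empty[v] == pytest.approx(1 - beta[v], abs=1e-12)
    m_root = ctx.ftilde_empty[cherry.root][:4] @ jc.pi
    assert ctx.f_empty[cherry.root] == pytest.approx(m_root, abs=1e-12)


# -- column likelihood -------------------------------------------------


def test_column_likelihood_hand_expanded_two_term_sum(jc):
    """Column (A, -) on a 2-leaf tree: iota(root) f_root + iota(leaf) f_leaf."""
    t = parse_newick("(A:0.2,B:0.2);")
    ctx = PIPContext(t, jc, lam=1.0)
    P = expm(0.2 * jc.Q_eps)
    denom = 0.4 + 1.0
    beta_leaf = (1 - np.exp(-0.2)) / 0.2
    f_leaf = beta_leaf * 0.25
    # root: f-tilde(sigma) = P[sigma, A] * P[sigma, eps]
    f_root = sum(0.25 * P[s, 0] * P[s, 4] for s in range(4))
    expected = (0.2 / denom) * f_leaf + (1.0 / denom) * f_root
    got = column_likelihood({"A": "A", "B": "-"}, ctx)
    assert got == pytest.approx(expected, abs=1e-12)


def test_empty_column_probability_saturates_with_deletion(jc):
    """p(c_empty) lies in (0,1) and -> 1 as mu*b grows (all insertions die)."""
    vals = []
    for b in (0.1, 1.0, 5.0, 20.0):
        t = parse_newick(f"(A:{b},B:{b});")
        ctx = PIPContext(t, jc, lam=1.0)
        assert 0 < ctx.p_empty < 1
        vals.append(ctx.p_empty)
    assert vals == sorted(vals)
    assert vals[-1] > 0.95


def test_column_likelihood_matches_latent_enumeration(jc, three_leaf):
    """Pruning vs explicit insertion-node x character x state enumeration."""
    for lam in (0.3, 1.0):
        ctx = PIPContext(three_leaf, jc, lam=lam)
        for pattern in itertools.product([0, 1], repeat=3):
            col = {
                x: (c if on else "-")
                for (x, c), on in zip(zip("ABC", "AGT"), pattern)
            }
            fast = column_likelihood(col, ctx)
            slow = column_likelihood_enumerated(col, ctx)
            assert fast == pytest.approx(slow, abs=1e-12)


# -- alignment likelihood ----------------------------------------------


def test_msa_likelihood_column_order_invariant(three_leaf, jc):
    ctx = PIPContext(three_leaf, jc, lam=0.8)
    a = Alignment(("A", "B", "C"), ("AC-G", "A--G", "-CTG"))
    b = Alignment(("A", "B", "C"), ("G-CA", "G--A", "GTC-"))  # columns permuted
    assert msa_likelihood(a, ctx) == pytest.approx(msa_likelihood(b, ctx), abs=1e-12)


def test_msa_likelihood_empty_alignment(cherry_ctx):
    aln = Alignment(("A", "B"), ("", ""))
    expected = cherry_ctx.nu * (cherry_ctx.p_empty - 1.0)
    assert msa_likelihood(aln, cherry_ctx) == pytest.approx(expected, abs=1e-12)


def test_msa_likelihood_decomposes_into_columns(rng, jc):
    """Eq-by-eq self-consistency on simulated data: total = sum log p(c) + log phi."""
    from pipalign.simulate import random_tree, simulate

    for _ in range(20):
        t = random_tree(int(rng.integers(3, 6)), rng)
        sim = simulate(t, jc, lam=2.0, seed=rng)
        if sim.true_msa.n_cols == 0:
            continue
        ctx = PIPContext(t, jc, lam=2.0)
        total = msa_likelihood(sim.true_msa, ctx)
        per_col = sum(
            np.log(column_likelihood(sim.true_msa.column(j), ctx))
            for j in range(sim.true_msa.n_cols)
        )
        expected = per_col + log_phi(ctx.p_empty, sim.true_msa.n_cols, ctx.nu)
        assert total == pytest.approx(expected, abs=1e-9)


def test_msa_likelihood_input_validation(cherry_ctx):
    with pytest.raises(ValueError):
        msa_likelihood(Alignment(("A", "Z"), ("AC", "AC")), cherry_ctx)
    with pytest.raises(ValueError):
        msa_likelihood(Alignment(("A", "B"), ("A-C", "A-C")), cherry_ctx)


def test_subtree_context_scopes_to_clade(three_leaf, jc):
    inner = [v for v in three_leaf.internal_postorder() if v != three_leaf.root][0]
    ctx = PIPContext(three_leaf, jc, lam=1.0, node=inner)
    assert set(ctx.leaf_labels) == {"A", "B"}
    assert ctx.tau == pytest.approx(0.6)
    assert ctx.iota[[v for v in ctx.nodes]].sum() == pytest.approx(1.0, abs=1e-12)
    assert ctx.beta[inner] == 1.0
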