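"""Score an existing alignment: total and per-column log-likelihood.

The marginal likelihood factorises over columns, times a closed-form
factor for all unobservable insertion-deletion histories, so the scorer
reports one log p(c) per column plus the total.
"""

import numpy as np

from pipalign import Alignment, PIPContext, jc69, msa_likelihood, parse_newick

tree = parse_newick("((A:0.2,B:0.3):0.2,C:0.4);")
aln = Alignment(("A", "B", "C"), ("ACG-T", "AC--T", "A-GGT"))

model = jc69(mu=0.8)
ctx = PIPContext(tree, model, lam=1.2)

total = msa_likelihood(aln, ctx)
ind = aln.reorder(ctx.leaf_labels).leaf_indicators(model)
per_col = ctx.log_column_likelihoods(ind)

for j, lp in enumerate(per_col):
    print(f"column {j + 1}: log p(c) = {lp: .6f}")
print(f"log p(c_empty) = {ctx.log_p_empty:.6f}  (all-gap column)")
print(f"total logL = {total:.6f}")

# Columns where few taxa share a residue score lower: the model must either
# posit an old insertion with many deletions, or a recent insertion placed
# below most of the tree.  The all-gap value p(c_empty) feeds the
# unobservable-history factor that links the per-column terms to the total.
assert np.isclose(total, per_col.sum() + (ctx.nu * (ctx.p_empty - 1.0)
                  + len(per_col) * np.log(ctx.nu)
                  - sum(np.log(k) for k in range(1, len(per_col) + 1))))
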