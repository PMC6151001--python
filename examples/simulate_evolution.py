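"""Simulate sequence evolution with indels and recover the true alignment.

The generative process is the same one the aligner assumes: a stationary
root sequence of mean length λ/μ, per-character deletion at rate μ, and
Poisson insertions along every branch.  Homology is tracked by character
identity, so the emitted alignment is exact truth, not an inference.
"""

from pipalign import jc69, parse_newick, simulate

tree = parse_newick("((A:0.3,B:0.4):0.2,(C:0.3,D:0.2):0.3);")
model = jc69(mu=1.0)

sim = simulate(tree, model, lam=6.0, seed=11)

print("true alignment (gaps mark deletions / missing insertions):")
for taxon in sim.true_msa.taxa:
    print(f"  {taxon}  {sim.true_msa.row(taxon)}")
print("ungapped sequences an aligner would see:")
for taxon, seq in sim.leaf_seqs.items():
    print(f"  {taxon}  {seq}")
ins = sum(e["insertions"] for e in sim.events.values())
dels = sum(e["deletions"] for e in sim.events.values())
print(f"events on branches: {ins} insertions, {dels} deletions")

# Every non-gap column entry descends from one inserted character; characters
# inserted and deleted before reaching any leaf are dropped — they are the
# 'unobservable histories' the likelihood marginalises analytically.
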