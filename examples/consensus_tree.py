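"""Majority-rule consensus of a sample of rooted trees.

A rooted clade is kept when it appears in more than the threshold
fraction of trees; retained edges get the mean length over the trees
containing the clade, and clade support is recorded on internal nodes.
"""

from commassembly import majority_rule_consensus, read_newick, write_newick

sample = [
    read_newick("(((A:1,B:1):1,C:2):1,D:3);"),
    read_newick("(((A:1,B:1):1,C:2):1,D:3);"),
    read_newick("(((A:1,C:1):1,B:2):1,D:3);"),
]
cons = majority_rule_consensus(sample, threshold=0.5)
print("consensus:", write_newick(cons))
for clade, support in sorted(cons.clade_support.items(), key=lambda kv: -kv[1]):
    print(f"  clade {{{', '.join(sorted(clade))}}}: support {support:.2f}")

strict = majority_rule_consensus(sample, threshold=0.99)
print("near-strict consensus:", write_newick(strict))
print("\n{A,B} appears in 2 of 3 trees: it survives the majority rule "
      "(support 0.67) but collapses into a polytomy at threshold 0.99.")
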