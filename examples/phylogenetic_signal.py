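"""Phylogenetic conservatism of every trait in the pool.

Blomberg's K (continuous traits; K ~ 1 under Brownian motion, with a
tip-permutation p) and the Fritz-Purvis D statistic (binary traits;
D ~ 1 for phylogenetically random traits, ~ 0 under threshold-Brownian
evolution, < 0 when hyper-conserved), each with its randomization or
simulation null.
"""

from commassembly import SimConfig, signal_table, simulate_dataset

study = simulate_dataset(SimConfig(seed=42))
table = signal_table(study.tree, study.traits, n_perm=999, n_sim=1000, seed=3)

cols = [c for c in ("type", "statistic", "value", "p", "p_random", "p_brownian")
        if c in table.columns]
print(table[cols].round(3).to_string())
print("\nAll traits were simulated with full phylogenetic signal "
      "(lambda = 1), so K clusters near 1 and D near 0; p_random < 0.05 "
      "rejects a random distribution of the trait along the phylogeny.")
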