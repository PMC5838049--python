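"""Functional and phylogenetic structure via null-model effect sizes.

For each assemblage, computes the standardized effect size of the
abundance-weighted mean pairwise distance under the taxa-labels null
(999 shuffles of species names across the pool distance matrix):
S.E.S. PW on Gower functional distances and NRI on patristic
distances.  Positive values = clustering, negative = overdispersion;
the rank-based p is the proportion of null values at or below the
observed distance.
"""

from commassembly import SimConfig, gower, nri, ses_pw, simulate_dataset

study = simulate_dataset(SimConfig(seed=42))
gower_dm = gower(study.traits)
rel = study.observed.div(study.observed.sum(axis=1), axis=0)

print(f"{'assemblage':<15} {'S.E.S. PW':>10} {'p':>7} {'NRI':>8} {'p':>7}")
for name in study.observed.index:
    f = rel.loc[name]
    pw = ses_pw(gower_dm, f, n_null=999, seed=1)
    phylo = nri(study.tree, f, n_null=999, seed=2)
    print(f"{name:<15} {pw.ses:>10.2f} {pw.p_quantile:>7.3f} "
          f"{phylo.ses:>8.2f} {phylo.p_quantile:>7.3f}")
print("\nThe 'high' plot was assembled under strong environmental "
      "filtering: its S.E.S. PW is strongly positive (functional "
      "clustering, small p). Neutral assemblages scatter around zero.")
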