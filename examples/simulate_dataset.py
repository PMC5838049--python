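"""Simulate a complete elevational survey dataset.

Generates a 125-species pool (ultrametric Yule phylogeny + 2 continuous
and 15 binary traits with full phylogenetic signal), assembles six
communities (three elevation plots x two seasons) under
filtering/neutral/limiting-similarity regimes, and runs the 3-transect
x 8-repeat detection process whose per-transect maximum over repeats
estimates abundance.
"""

from commassembly import SimConfig, simulate_dataset

study = simulate_dataset(SimConfig(seed=42))

print(f"pool: {study.tree.n_tips} species, "
      f"tree depth {study.tree.depths.max():.2f}")
print(f"traits: {study.traits.data.shape[1]} columns "
      f"({len(study.traits.continuous_columns)} continuous, "
      f"{len(study.traits.binary_columns)} binary)")
print("\nassemblages (true vs survey-estimated richness):")
for name in study.truth.index:
    true_sr = int((study.truth.loc[name] > 0).sum())
    obs_sr = int((study.observed.loc[name] > 0).sum())
    meta = study.metadata.loc[name]
    print(f"  {name:<15} {meta['elevation']:>6.0f} m  "
          f"true SR {true_sr:>3}  observed SR {obs_sr:>3}")
print("\nObserved richness is at most the true richness because repeat "
      "surveys miss individuals; the max-over-repeats estimator recovers "
      "most of the community at detection probability 0.8.")
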