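"""Cross-donor differential abundance with the rank-transformed mixed model.

Simulates ten donors with planted genus-level log2 effects for two synthetic
glycans and a reference glycan, fits the rank LMM (treatment fixed effect,
donor random intercept) per feature, adjusts p-values by Benjamini-Hochberg,
and prints the significant features next to the planted truth.
"""

import glycoferm as gf

cfg = gf.simulate.SimConfig(seed=2, n_donors=10, n_taxa=20)
taxa, meta, effects = gf.simulate.generate_taxa_tables(cfg)
print("planted effects (log2 fold change):")
for cls, eff in effects.items():
    print(f"  {cls}: {eff}")

res = gf.diffabund.differential_abundance(taxa, meta)
sig = res[res["q_value"] < 0.05].sort_values(["glycan", "q_value"])
print(f"\n{len(sig)} significant feature x glycan results (q < 0.05):")
print(sig[["feature", "glycan", "median_log2fc", "p_value", "q_value"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4g}"))

profiles, tree = gf.diffabund.significant_features(res, alpha=0.05, fc_filter=1.0)
print(f"\nfeatures passing the display filter (q < 0.05 and |median log2FC| "
      f"> 1 on >= 1 glycan): {list(profiles.index)}")
print("\nmedian_log2fc is the cross-donor median fold change vs the"
      "\nno-glycan control.  Planted responders appear with the planted"
      "\nsign; because abundances are compositional, boosting one genus"
      "\nnecessarily depresses the rest, so unplanted taxa can show small"
      "\nbut significant negative shifts -- the |log2FC| > 1 display filter"
      "\nis what separates the strong planted responders from this closure"
      "\nspillover.")
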