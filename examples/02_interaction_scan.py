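"""Run both gene-medication interaction approaches at a causal SNP.

Across a handful of phenotype replicates, fits the single-model interaction
test (SNP + med + SNP x med, pedigree mixed model) and the
medication-stratified med-diff test, then prints the estimated interaction
effect next to the simulated truth of +6.2 mm Hg.
"""
import numpy as np
import pandas as pd

import famgxe as f

cfg = f.cyp3a43_scenario(mafs=(0.054,), n_replicates=5, seed=2)
snp = cfg.causal_snps[0].snp

rows = []
for ds in f.generate_replicates(cfg):
    res = f.run_scan(ds, approach="both", snp_set=[snp])
    rows.append(res)
res = pd.concat(rows, ignore_index=True)
conv = res[res["converged"]]

print(f"causal SNP {snp}, simulated interaction +6.2 mm Hg, "
      f"{res['replicate'].nunique()} replicates\n")
for app, adf in conv.groupby("approach"):
    print(f"{app}: mean effect {adf['beta_effect'].mean():+.2f} mm Hg "
          f"(mean SE {adf['se_effect'].mean():.2f}), "
          f"median 1DF p {adf['p_1df'].median():.3f}, "
          f"median 2DF p {adf['p_2df'].median():.3f}")
print("\nThe interaction-model effect is beta_Int; the med-diff effect is the")
print("difference of stratum-specific SNP slopes - both target the same +6.2.")
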