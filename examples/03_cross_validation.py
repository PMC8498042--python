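"""Genomic repeatability by k-fold and chessboard cross-validation.

The k-fold scheme estimates repeatability of a line trial; the chessboard
scheme partitions female and male parents separately so that test hybrids
share both (T2), one (T1) or no (T0) parents with the training set —
abilities are expected to order T2 >= T1 >= T0.
"""

import numpy as np
import pandas as pd

from rrgskit import popgen, validation
from rrgskit.prediction import candidate_design_rows

geno = popgen.make_founders(200, 150, 5, 100.0, 0.1, 0.5, seed=20)
arch = popgen.make_architecture(150, 80, var_additive=1.0, dominance_ratio=0.0,
                                seed=21)
g = popgen.genetic_value(geno.dosage, arch)
rng = np.random.default_rng(22)
y = pd.Series(g + rng.normal(scale=g.std(), size=len(g)),  # h2 = 0.5
              index=geno.individual_ids)
res = validation.kfold_cv(y, geno, model="gblup", k=5, repeats=5, seed=23,
                          varcomp=(1.0, 1.0))
print(f"5-fold genomic repeatability of the line trial (h2=0.5): "
      f"{res.mean_ability:.2f}")

# hybrids for the chessboard: 15 females x 6 males
hyb_geno = popgen.make_founders(21, 120, 4, 100.0, 0.1, 0.5, seed=24, prefix="P")
hyb_arch = popgen.make_architecture(120, 60, var_additive=1.0,
                                    dominance_ratio=0.3, seed=25)
females, males = hyb_geno.individual_ids[:15], hyb_geno.individual_ids[15:]
rows = []
for f in females:
    for m in males:
        za, zd = candidate_design_rows(hyb_geno.row(f), hyb_geno.row(m))
        gv = hyb_arch.intercept + za @ hyb_arch.additive + zd @ hyb_arch.dominance
        rows.append({"female_parent": f, "male_parent": m,
                     "value": gv + rng.normal(scale=0.5)})
res_cb = validation.chessboard_cv(pd.DataFrame(rows), hyb_geno,
                                  n_female_folds=3, n_male_folds=2, seed=26,
                                  varcomp=(0.02, 0.01, 0.3))
print("chessboard abilities (mean over held-out cells):")
for cls in ("T2", "T1", "T0"):
    print(f"  {cls}: {res_cb[cls].mean_ability:.2f}")
print("sharing parents with the training set makes hybrids easier to predict.")
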