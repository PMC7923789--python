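#!/usr/bin/env python
"""Multivariate view of the seed-averaged experiment (seeds 1-10).

PCA biplots of the Block A descriptor matrix and of the postural spectra, and
PLS1 calibrations of the spectra against each locomotion descriptor and
mortality, with the LV1 loading spectrum figure. Writes under results/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from wormspectra import RunConfig, pca_fit, pls1_fit, run_experiment
from wormspectra.multivariate import AUTOSCALE, MEAN_CENTER, save_biplot, save_loading_spectrum
from wormspectra.pipeline import BLOCK_A_DESCRIPTORS

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
FIG = OUT / "figures"
FIG.mkdir(parents=True, exist_ok=True)

N_SEEDS = 10
spectra, blocks, morts = [], [], []
for seed in range(1, 1 + N_SEEDS):
    res = run_experiment(RunConfig(seed=seed))
    spectra.append(res.spectra.set_index("treatment_id"))
    blocks.append(res.block_a.set_index("treatment_id")[BLOCK_A_DESCRIPTORS])
    morts.append(res.mortality.set_index("treatment_id")["mortality_pct"])
X_spec = sum(spectra) / N_SEEDS
X_block = sum(blocks) / N_SEEDS
mort = sum(morts) / N_SEEDS

pca_a = pca_fit(X_block, 2, AUTOSCALE)
pca_b = pca_fit(X_spec, 2, MEAN_CENTER)
print(f"Block A PCA: PC1 {pca_a.explained_variance_pct[0]:.1f}%, "
      f"PC2 {pca_a.explained_variance_pct[1]:.1f}%")
print(f"Block B PCA: PC1 {pca_b.explained_variance_pct[0]:.1f}%, "
      f"PC2 {pca_b.explained_variance_pct[1]:.1f}%")
save_biplot(pca_a, FIG / "pca_block_a_biplot.png", "Locomotion metrics (Block A)")
save_biplot(pca_b, FIG / "pca_block_b_biplot.png", "Postural spectra (Block B)")

rows, models = [], {}
for name in BLOCK_A_DESCRIPTORS + ["mortality"]:
    y = mort.loc[X_spec.index].to_numpy() if name == "mortality" else X_block.loc[X_spec.index, name].to_numpy()
    model = pls1_fit(X_spec, y, n_lv=2, preprocessing=MEAN_CENTER)
    models[name] = model
    rows.append({"response": name, "r2_calibration": model.r2_calibration})
table = pd.DataFrame(rows)
table.to_csv(OUT / "pls_r2_seed_averaged.csv", index=False, float_format="%.4f")
print("\nPLS1 calibration of postural spectra against each response:")
print(table.round(3).to_string(index=False))

save_loading_spectrum(
    {k: models[k] for k in ("M", "A_m", "mortality")},
    FIG / "pls_lv1_loadings.png",
    "LV1 loadings over the postural spectrum",
)
lv1 = pd.DataFrame({"bin": np.arange(100)})
for k in ("M", "A_m", "mortality"):
    lv1[f"lv1_{k}"] = models[k].x_loadings[:, 0]
lv1.to_csv(OUT / "pls_lv1_loadings_seed_averaged.csv", index=False, float_format="%.6g")
print("\nLV1 loadings and figures under", FIG)
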