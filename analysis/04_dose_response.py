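#!/usr/bin/env python
"""LC50 estimation from the simulated lethality assays, plus unit conversions.

Fits the log-logistic dose-response per (ascorbic acid, food) series from
results/assay_counts.csv (run 01_simulate.py first), writes results/lc50.csv
and a dose-response figure, and prints the worked toxicological conversions.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from wormspectra import (
    MortalityCurve,
    adi_from_noael,
    dose_for_body,
    fit_lc50,
    loglogistic,
    mass_in_well,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
counts = pd.read_csv(OUT / "assay_counts.csv")

rows = []
curves = {}
for (asa, food), grp in counts.groupby(["asa_mM", "food"]):
    grp = grp.sort_values("nitrite_mg_L")
    curve = MortalityCurve(
        doses=grp["nitrite_mg_L"].to_numpy(),
        dead=grp["dead"].to_numpy(),
        total=grp["total"].to_numpy(),
    )
    est = fit_lc50(curve)
    curves[(asa, food)] = (curve, est)
    rows.append(
        {
            "asa_mM": asa, "food": food, "lc50_mg_L": est.lc50,
            "hill_slope": est.hill_slope, "method": est.method, "status": est.status,
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "lc50.csv", index=False, float_format="%.4g")
print(table.to_string(index=False))

fig_dir = OUT / "figures"
fig_dir.mkdir(exist_ok=True)
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
for ax, asa in zip(axes, sorted(counts["asa_mM"].unique())):
    for food, color in [("AA", "gold"), ("PA", "black"), ("PP", "red")]:
        curve, est = curves[(asa, food)]
        pct = 100.0 * curve.dead / curve.total
        ax.plot(curve.doses, pct, "o", color=color, label=food)
        if est.status == "ok" and est.method == "loglogistic_fit":
            grid = np.linspace(1, 10000, 300)
            ax.plot(grid, 100 * loglogistic(grid, est.lc50, est.hill_slope), "-", color=color, lw=1)
            ax.axvline(est.lc50, color=color, ls=":", lw=0.8)
    ax.set_title(f"ascorbic acid {asa:g} mM")
    ax.set_xlabel("nitrite (mg/L)")
axes[0].set_ylabel("% mortality")
axes[0].legend()
fig.tight_layout()
fig.savefig(fig_dir / "dose_response.png", dpi=150)

aa = table[(table.asa_mM == 0.0) & (table.food == "AA")]["lc50_mg_L"].iloc[0]
print(f"\nNitrite mass in a 300 uL well at the AA LC50 ({aa:.0f} mg/L): "
      f"{mass_in_well(aa, 300e-6):.3f} mg")
print(f"Rat-equivalent acute dose (121 mg/kg bw, 230 g rat): {dose_for_body(121, 0.230):.2f} mg")
adi = adi_from_noael(6.7, 100)
print(f"ADI from rat NOAEL 6.7 mg/kg bw/day / UF 100: {adi.raw:.3f} -> {adi.rounded} mg/kg bw/day")
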