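"""Group comparison of the morphometric indices and curvature spectra.

Compares monoculture vs co-culture samples from step 04: Mann–Whitney U
tests (Bonferroni m = 3 over the three endpoints: sprout range, sprout
roughness, sprout area), a Kolmogorov–Smirnov test of the pooled
sprout-curvature distributions, and the linear regression of MSC
coverage ratio against sprout volume over the co-culture samples.
Writes stats tables and a curvature histogram figure.

Note: the phantom generator plants no coverage–volume dependence (wrap
MSC size is fixed while sprout lengths jitter), so the regression acts
as a negative control of the procedure: expect a weak, unstable fit.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from angiocross.stats import ks_two_sample, linear_fit, mann_whitney

IN = Path("results/meshes")
OUT = Path("results/stats")
ENDPOINTS = ["sprout_range_um", "sprout_roughness", "surface_area_sprout"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(IN / "morphometry.csv")
    mono = table[table.group == "mono"]
    co = table[table.group == "co"]

    rows = []
    for col in ENDPOINTS:
        res = mann_whitney(mono[col], co[col], m_comparisons=len(ENDPOINTS))
        rows.append(
            {
                "endpoint": col,
                "median_mono": mono[col].median(),
                "median_co": co[col].median(),
                "U": res.statistic,
                "p": res.p,
                "p_bonferroni": res.p_adjusted,
                "significant": res.significant,
            }
        )
        print(
            f"{col}: mono median {mono[col].median():.3g} vs co "
            f"{co[col].median():.3g}, adj. p = {res.p_adjusted:.3g}"
        )
    pd.DataFrame(rows).to_csv(OUT / "mann_whitney.csv", index=False)

    h_mono = np.concatenate(
        [np.load(f) for f in sorted(IN.glob("mono_*_sprout_H.npy"))]
    )
    h_co = np.concatenate([np.load(f) for f in sorted(IN.glob("co_*_sprout_H.npy"))])
    ks = ks_two_sample(h_mono, h_co)
    print(f"\nKS on sprout curvature: D = {ks.statistic:.3f}, p = {ks.p:.3g}")

    fit = linear_fit(co["coverage_ratio_all"], co["sprout_volume"])
    print(
        f"coverage→sprout-volume OLS over {len(co)} co samples: slope "
        f"{fit.statistic:.3g}, r² = {fit.extra['r2']:.3f}"
    )
    (OUT / "summary.json").write_text(
        json.dumps(
            {
                "ks_sprout_curvature": {"D": ks.statistic, "p": ks.p},
                "coverage_volume_ols": {
                    "slope": fit.statistic,
                    "intercept": fit.extra["intercept"],
                    "r2": fit.extra["r2"],
                    "n": len(co),
                },
                "median_sprout_H_mono": float(np.median(h_mono)),
                "median_sprout_H_co": float(np.median(h_co)),
            },
            indent=2,
        )
    )

    fig, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.linspace(-0.12, 0.12, 61)
    ax.hist(h_mono, bins=bins, alpha=0.6, density=True, label="monoculture-like")
    ax.hist(h_co, bins=bins, alpha=0.6, density=True, label="co-culture-like")
    ax.set_xlabel("sprout mean curvature H (μm⁻¹)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "sprout_curvature_histograms.png", dpi=150)


if __name__ == "__main__":
    main()
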