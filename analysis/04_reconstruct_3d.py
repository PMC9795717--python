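"""3D reconstruction, segmentation and morphometry of every sample.

For each simulated stack: binarize the red channel, keep the connected
vessel structure, fill the lumen, mesh, tag parent vs sprout (10 μm
junction collar) and MSC coverage, compute mean curvature, and write a
tagged PLY plus one morphometry row per sample.  Sprout-surface
curvature values are saved for the distribution comparison in step 05.

Found: co-culture-like samples have longer sprout ranges, smoother
sprout surfaces and nonzero MSC coverage; monoculture-like samples show
short rough sprouts and zero coverage.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from angiocross import mesh3d
from angiocross import morphometry as mm
from angiocross.phantom.io import read_volume
from angiocross.pipeline import reconstruct

IN = Path("results/phantoms")
OUT = Path("results/meshes")
EROSION_PX = 5  # 10 μm at the 2 μm phantom voxel


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for tif in sorted(IN.glob("*_*.ome.tif")):
        name = tif.name.replace(".ome.tif", "")
        vol = read_volume(tif)
        rec = reconstruct(vol, erosion_px=EROSION_PX)
        mesh3d.write_ply(OUT / f"{name}.ply", rec.surface)
        rep = mm.morphometry_report(
            rec.surface, sample_id=name, parent_mesh=rec.parent_surface
        )
        row = rep.to_row()
        row["group"] = name.split("_")[0]
        row["sprout_roughness"] = mm.sprout_roughness(
            rec.surface, rec.parent_surface
        )
        rows.append(row)
        h = mm.curvature_values(rec.surface, "sprout")
        np.save(OUT / f"{name}_sprout_H.npy", h)
        print(
            f"{name}: range {rep.sprout_range_um:.0f} μm, "
            f"sprout roughness {row['sprout_roughness']:.4f} μm⁻¹, "
            f"coverage {rep.coverage_ratio_all:.3f}"
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "morphometry.csv", index=False)
    print(f"\nwrote {len(rows)} morphometry rows to {OUT/'morphometry.csv'}")


if __name__ == "__main__":
    main()
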