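"""Generate the synthetic study data: 2D day series and 3D stacks.

Writes OME-TIFF phantoms with ground-truth sidecars under
results/phantoms/: one 10-day 2D co-culture series, plus day-10-like 3D
stacks for 4 monoculture and 5 co-culture samples (the group sizes of
the morphometric comparison).
"""

from pathlib import Path

from angiocross.phantom import (
    coculture_spec_2d,
    coculture_spec_3d,
    make_coculture_series_2d,
    make_vessel_phantom_3d,
    monoculture_spec_3d,
)
from angiocross.phantom import io as phio

OUT = Path("results/phantoms")
N_MONO, N_CO = 4, 5
BASE_SEED = 20


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec2d = coculture_spec_2d(seed=BASE_SEED, noise=True)
    series, gt2d = make_coculture_series_2d(spec2d)
    phio.write_series(OUT / "series2d.ome.tif", series)
    phio.write_ground_truth_2d(OUT, gt2d, name="series2d")
    print(f"2D series: {len(series)} frames, {gt2d.centroids.shape[1]} MSCs")

    for kind, n, make in (
        ("mono", N_MONO, monoculture_spec_3d),
        ("co", N_CO, coculture_spec_3d),
    ):
        for i in range(n):
            spec = make(seed=BASE_SEED + 100 * (kind == "co") + i)
            vol, gt = make_vessel_phantom_3d(spec)
            name = f"{kind}_{i}"
            phio.write_volume(OUT / f"{name}.ome.tif", vol)
            phio.write_ground_truth_3d(OUT, gt, name=name)
            print(
                f"{name}: shape {vol.shape}, sprouts "
                f"{[round(s.length) for s in spec.sprouts]} μm, "
                f"true coverage {gt.overall_coverage:.3f}"
            )
    print(f"wrote phantoms to {OUT}/")


if __name__ == "__main__":
    main()
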