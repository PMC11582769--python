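"""Distance-map construction and watershed reconstruction round trip.

Builds cell distance maps and neighbor distance maps from synthetic label
images of elliptical nuclei, reconstructs labels by seeded watershed and
scores object-count fidelity across seeded fields.  Also writes one example
field (labels + maps, 32-bit float TIFFs) under results/ for inspection.
"""

import numpy as np
import pandas as pd
import tifffile

from estrocycle.image_maps import (
    make_cell_distance_map,
    make_neighbor_distance_map,
    reconstruct_labels,
)
from estrocycle.synth import SynthConfig, gen_label_movie

N_FIELDS = 25


def main() -> None:
    rows = []
    for seed in range(N_FIELDS):
        cfg = SynthConfig(seed=seed, n_nuclei=5, field_shape=(160, 160),
                          n_frames=1, drift_px=0.0)
        lab = gen_label_movie(cfg)[0][0]
        cdp = make_cell_distance_map(lab)
        ndp = make_neighbor_distance_map(lab)
        rec = reconstruct_labels(cdp, ndp)
        rows.append({
            "seed": seed,
            "n_true": int(len(np.unique(lab)) - 1),
            "n_reconstructed": int(len(np.unique(rec)) - 1),
        })
        if seed == 0:
            tifffile.imwrite("results/example_labels.tif", lab.astype(np.uint16))
            tifffile.imwrite("results/example_cdp.tif", cdp.astype(np.float32))
            tifffile.imwrite("results/example_ndp.tif", ndp.astype(np.float32))
    tab = pd.DataFrame(rows)
    tab["match"] = tab["n_true"] == tab["n_reconstructed"]
    tab.to_csv("results/segmentation_roundtrip.csv", index=False)
    print(tab.to_string(index=False))
    print(f"\nobject-count fidelity: {tab['match'].mean():.0%} of {N_FIELDS} fields")


if __name__ == "__main__":
    main()
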