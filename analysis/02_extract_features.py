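"""Image path: segment the demo tiles, measure the 10 cell-level
features per nucleus, and aggregate each patient into the 150-feature
vector with cohort-shared histogram bins.

Reads scratch/demo/tiles (from 01_simulate.py); writes
results/imaging_features.csv and results/bins.json, and reports
segmentation recovery against the bundled ground truth.

Run from the repository root:  python analysis/02_extract_features.py
"""

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from histomorph.cellfeat import extract_cell_features
from histomorph.patientfeat import aggregate_cohort
from histomorph.pipeline import segment_tile_image

ROOT = Path(__file__).resolve().parents[1]
DEMO = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    RESULTS.mkdir(exist_ok=True)
    cells = {}
    matched = total = spurious = 0
    for pdir in sorted((DEMO / "tiles").iterdir()):
        tile = pdir / "tile1.png"
        image = np.asarray(iio.imread(tile))[..., :3]
        result = segment_tile_image(image)
        cells[pdir.name] = extract_cell_features(result.labels, image)
        truth = pd.read_csv(DEMO / "truth" / pdir.name / "tile1.csv")
        if result.n_nuclei:
            d, idx = cKDTree(result.centroids).query(truth[["row", "col"]].to_numpy())
            hit = d <= 5
            matched += int(hit.sum())
            spurious += result.n_nuclei - len(set(idx[hit]))
        total += len(truth)
    features, scheme = aggregate_cohort(cells)
    features.to_csv(RESULTS / "imaging_features.csv")
    scheme.to_json(RESULTS / "bins.json")
    print(f"segmentation: {matched}/{total} ground-truth nuclei matched, {spurious} spurious")
    print(f"feature matrix: {features.shape[0]} patients x {features.shape[1]} features")
    print(f"-> {RESULTS / 'imaging_features.csv'}")
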