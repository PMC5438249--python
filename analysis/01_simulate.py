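#!/usr/bin/env python
"""Generate the synthetic study datasets.

Two imaging-site analogues are produced with full ground truth:

* a 13-odorant panel site (single 1:10,000 dilution), and
* a concentration-series site (3 odorants x 3 ten-fold dilutions),

both with 300 cells, 4 trials per stimulus and the default response
structure (~20% activated, ~11% suppressed, ~10% concentration-invariant),
plus a small 64 x 64 movie (25 planted cells) for the segmentation stage.

Outputs under results/data/: responses_*.csv, ground_truth_*.json,
demo_movie.tif.
"""

import json
from pathlib import Path

from pirinv.pipeline import default_movie_sim
from pirinv.synth import (SimConfig, generate_movie,
                          generate_response_dataset, odor_panel,
                          write_ground_truth)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel_cfg = SimConfig(n_cells=300, stimulus_set=odor_panel(13),
                          seed=SEED)
    table, gt = generate_response_dataset(panel_cfg)
    table.to_csv(OUT / "responses_panel13.csv")
    write_ground_truth(gt, OUT / "ground_truth_panel13.json")
    print(f"13-odorant panel: {table.n_cells} cells, "
          f"{len(table.stimuli)} stimuli -> {OUT / 'responses_panel13.csv'}")

    series_cfg = SimConfig(n_cells=300, seed=SEED + 1)
    table, gt = generate_response_dataset(series_cfg)
    table.to_csv(OUT / "responses_series.csv")
    write_ground_truth(gt, OUT / "ground_truth_series.json")
    n_inv = int((gt.category == "identity_only").sum())
    print(f"concentration series: {table.n_cells} cells of which "
          f"{n_inv} planted concentration-invariant")

    movie_cfg = default_movie_sim(SEED + 2)
    movie, gt = generate_movie(movie_cfg)
    movie.to_tiff(OUT / "demo_movie.tif")
    write_ground_truth(gt, OUT / "ground_truth_movie.json",
                       field_size=movie_cfg.field_size)
    meta = {"frame_rate": movie.frame_rate, "pixel_size": movie.pixel_size,
            "n_cells": movie_cfg.n_cells, "field_size":
            list(movie_cfg.field_size), "seed": movie_cfg.seed}
    (OUT / "demo_movie_meta.json").write_text(json.dumps(meta, indent=2))
    print(f"demo movie: {movie.shape} frames x rows x cols "
          f"-> {OUT / 'demo_movie.tif'}")


if __name__ == "__main__":
    main()
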