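"""Quantify what each preprocessing stage removes.

Superficial signal regression should collapse the shared scalp
component (visible as long-range inter-voxel correlation); the
0.02-0.5 Hz bandpass should suppress drift and pulse-rate frequencies;
downsampling to 1 Hz sets the analysis rate.  Writes
results/preprocessing_summary.tsv.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, analysis_config
from dotppi import preprocess
from dotppi.experiments import battery_truth, simulate_subject
from dotppi.hemodynamics import build_canonical_hrf
from dotppi.synth import RegionLayout, generate_design


def mean_distant_corr(series, n_pairs=50, seed=0):
    flat = series.flat()
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.shape[0], (n_pairs, 2))
    return float(np.mean([np.corrcoef(flat[i], flat[j])[0, 1]
                          for i, j in idx if i != j]))


def main():
    cfg = analysis_config()
    designs = generate_design(cfg.sim.n_runs, seed=cfg.seed)
    layout = RegionLayout.default(cfg.sim.voxel_size_mm)
    rec = simulate_subject(designs, layout, battery_truth(layout),
                           build_canonical_hrf(), seed=cfg.seed)
    run = rec.series[0]
    stages = [("raw", run)]
    run = preprocess.superficial_regress(run, rec.superficial[0])
    stages.append(("superficial_regressed", run))
    run = preprocess.bandpass(run, cfg.filter.low_hz, cfg.filter.high_hz)
    stages.append(("bandpassed", run))
    run = preprocess.downsample(run, cfg.filter.target_rate_hz)
    stages.append(("downsampled", run))

    rows = [{"stage": name,
             "rate_hz": s.rate,
             "n_timepoints": s.n_timepoints,
             "voxel_sd": float(s.data.std()),
             "mean_distant_voxel_corr": mean_distant_corr(s)}
            for name, s in stages]
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "preprocessing_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    before = rows[0]["mean_distant_voxel_corr"]
    after = rows[1]["mean_distant_voxel_corr"]
    print(f"\nSuperficial regression cut mean long-range correlation from "
          f"{before:.3f} to {after:.3f}.")
    mask = preprocess.fov_mask(rec.sensitivity)
    print(f"Two-decade field-of-view mask keeps {mask.mean():.1%} of voxels.")


if __name__ == "__main__":
    main()
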