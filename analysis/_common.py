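"""Shared configuration for the numbered analysis scripts.

The analyses run on a deterministic synthetic session at a desk-scale
grid (12-mm voxels, 3 subjects, 2 runs) so every script finishes in
about a minute on one CPU; all stages use the same library code that a
full-resolution session would.  Large intermediates (NIfTI volumes, the
full pipeline report) live under scratch/; the tables every script
produces land under results/.
"""

from pathlib import Path

from dotppi.config import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
REPORT = SCRATCH / "pipeline_report"


def analysis_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.seed = 20
    cfg.sim.n_subjects = 3
    cfg.sim.n_runs = 2
    cfg.sim.voxel_size_mm = 12.0
    cfg.stats.n_permutations = 100
    # with three subjects (dof 2) permutation-thresholded group maps are
    # almost empty; build the matrices from unthresholded maps instead
    cfg.stats.use_thresholded_matrices = False
    return cfg


def ensure_report() -> Path:
    """Run the end-to-end pipeline once; later scripts reuse the report."""
    if not (REPORT / "scrambled_control.tsv").exists():
        from dotppi.pipeline import run_all

        RESULTS.mkdir(exist_ok=True)
        run_all(analysis_config(), REPORT)
    return REPORT
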