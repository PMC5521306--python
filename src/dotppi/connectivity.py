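"""Seed-to-ROI connectivity matrices and model comparisons.

A connectivity matrix summarizes one gPPI map per seed: for every
canonical ROI, z-values are averaged within a 9-mm cube centered on the
ROI coordinate (sub-threshold voxels of a thresholded map contribute
zero), and those averages form the seed's row.  The matrices are not
symmetric — each row comes from a different gPPI fit, not from a
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import StatMap
from .volume import voxel_centers_world

__all__ = [
    "ConnectivityMatrix",
    "roi_average",
    "build_matrix",
    "matrix_correlation",
    "compare_deconv",
]


@dataclass
class ConnectivityMatrix:
    """seeds x ROIs table of averaged z-values."""

    values: np.ndarray
    seed_labels: list
    roi_labels: list
    kind: str = "TDC"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.seed_labels), len(self.roi_labels)):
            raise ValueError("values shape inconsistent with labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.seed_labels,
                            columns=self.roi_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="seed")

    @classmethod
    def from_tsv(cls, path, kind="TDC") -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), seed_labels=list(df.index),
                   roi_labels=list(df.columns), kind=kind)

    def plot(self, path=None, ax=None, **imshow_kw):
        """Heatmap rendering (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.values, cmap="RdBu_r",
                       vmin=-np.abs(self.values).max() or -1,
                       vmax=np.abs(self.values).max() or 1, **imshow_kw)
        ax.set_xticks(range(len(self.roi_labels)), self.roi_labels,
                      rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.seed_labels)), self.seed_labels, fontsize=7)
        ax.set_xlabel("ROI")
        ax.set_ylabel("seed")
        ax.figure.colorbar(im, ax=ax, label=f"{self.kind} z")
        if path is not None:
            ax.figure.tight_layout()
            ax.figure.savefig(path, dpi=120)
            plt.close(ax.figure)
        return ax


def roi_average(stat_map: StatMap, center_mm, cube_side_mm: float = 9.0) -> float:
    """Mean map value over in-mask voxels whose centers fall inside the
    axis-aligned cube of side ``cube_side_mm`` centered at ``center_mm``.

    On a thresholded map, zeroed sub-threshold voxels simply contribute
    zero to the mean.  Values outside the cube never matter.
    """
    centers = voxel_centers_world(stat_map.values.shape, stat_map.affine)
    half = cube_side_mm / 2.0
    inside = np.all(np.abs(centers - np.asarray(center_mm, dtype=float)) <= half,
                    axis=1)
    sel = inside & stat_map.mask.ravel()
    if not np.any(sel):
        raise ValueError(f"no in-mask voxels inside the {cube_side_mm}-mm cube "
                         f"at {tuple(center_mm)}")
    return float(stat_map.values.ravel()[sel].mean())


def build_matrix(maps, roi_seeds, cube_side_mm: float = 9.0,
                 kind: str = "TDC") -> ConnectivityMatrix:
    """Seed-to-ROI matrix: one row per (seed, map) pair, one column per
    canonical ROI; entries are cube-averaged z-values."""
    maps = list(maps)
    if not maps:
        raise ValueError("no seed maps supplied")
    roi_seeds = list(roi_seeds)
    values = np.empty((len(maps), len(roi_seeds)))
    seed_labels = []
    for i, (seed, smap) in enumerate(maps):
        seed_labels.append(seed.label)
        for j, roi in enumerate(roi_seeds):
            values[i, j] = roi_average(smap, roi.center_mm, cube_side_mm)
    return ConnectivityMatrix(values=values, seed_labels=seed_labels,
                              roi_labels=[r.label for r in roi_seeds], kind=kind)


def matrix_correlation(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Pearson correlation over the flattened entries of two matrices
    sharing labels and order."""
    if a.seed_labels != b.seed_labels or a.roi_labels != b.roi_labels:
        raise ValueError("matrices must share seed and ROI labels in order")
    return float(stats.pearsonr(a.values.ravel(), b.values.ravel())[0])


def compare_deconv(values_deconv, values_nodeconv, alpha_family: float = 0.05,
                   pair_labels=None) -> pd.DataFrame:
    """Paired comparison of seed-to-ROI connectivity under the two TDC
    constructions, Bonferroni-corrected over pairs.

    ``values_deconv`` and ``values_nodeconv`` are (subjects x pairs)
    arrays paired by subject.  Each pair gets a two-sided paired t-test;
    significance is declared at ``alpha_family / n_pairs`` (0.005 for
    the standard 10 comparisons at family alpha 0.05).
    """
    a = np.asarray(values_deconv, dtype=float)
    b = np.asarray(values_nodeconv, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired value shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need (subjects x pairs) arrays with >= 3 subjects")
    n_subj, n_pairs = a.shape
    threshold = alpha_family / n_pairs
    if pair_labels is None:
        pair_labels = [f"pair_{j}" for j in range(n_pairs)]
    rows = []
    for j in range(n_pairs):
        d = a[:, j] - b[:, j]
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a[:, j], b[:, j])
        rows.append({
            "pair": pair_labels[j],
            "mean_difference": float(d.mean()),
            "sem_difference": float(d.std(ddof=1) / np.sqrt(n_subj)),
            "t": float(t),
            "p": float(p),
            "threshold": threshold,
            "significant": bool(p < threshold),
        })
    return pd.DataFrame(rows)
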