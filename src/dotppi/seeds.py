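"""Seed definition and seed-signal extraction.

Canonical seeds are ten nonoverlapping speech-network locations (group
activation peaks; see :data:`dotppi.synth.CANONICAL_REGION_TABLE`).
Subject-specific seeds move a canonical seed to the nearest significant
local peak of the individual's activation map when that peak lies
within 18 mm (a couple of voxels beyond the ~14-mm point spread of the
imaging array); otherwise the canonical location is kept, so every
subject always has a seed.

Two radii are deliberately distinct: the seed *definition* radius
(3 mm, a 6-mm-diameter sphere) and the *signal-extraction* radius
(6 mm), both exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

from .glm import StatMap
from .synth import CANONICAL_REGION_TABLE
from .volume import VolumetricTimeSeries, voxel_centers_world

__all__ = [
    "SeedSpec",
    "canonical_seeds",
    "local_maxima",
    "subject_seed",
    "seed_signal",
    "seeds_to_tsv",
    "seeds_from_tsv",
    "DEFAULT_PEAK_MIN_Z",
]

#: Default peak-search threshold: one-sided p < 0.001 uncorrected.
DEFAULT_PEAK_MIN_Z = float(stats.norm.isf(0.001))


@dataclass(frozen=True)
class SeedSpec:
    label: str
    center_mm: tuple
    radius_mm: float = 3.0
    origin: str = "canonical"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")
        if self.origin not in ("canonical", "subject_specific"):
            raise ValueError(f"unknown seed origin {self.origin!r}")


def canonical_seeds(table=None, radius_mm: float = 3.0) -> list:
    """One canonical SeedSpec per (label, x, y, z) row.

    Raises on duplicate labels and on spheres that overlap (center
    distance <= 2 * radius).
    """
    if table is None:
        table = CANONICAL_REGION_TABLE
    rows = list(table)
    labels = [r[0] for r in rows]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate seed labels: {dupes}")
    seeds = [SeedSpec(label=lab, center_mm=(float(x), float(y), float(z)),
                      radius_mm=radius_mm, origin="canonical")
             for lab, x, y, z in rows]
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            d = np.linalg.norm(np.subtract(seeds[i].center_mm, seeds[j].center_mm))
            if d <= 2 * radius_mm:
                raise ValueError(
                    f"seeds {seeds[i].label} and {seeds[j].label} overlap "
                    f"(distance {d:.1f} mm <= {2 * radius_mm} mm)"
                )
    return seeds


def local_maxima(stat_map: StatMap, min_z: float = DEFAULT_PEAK_MIN_Z) -> np.ndarray:
    """World-mm coordinates of strict 26-neighborhood local maxima with
    z > min_z, sorted by descending z.  Returns an (N, 3) array (empty
    when no voxel qualifies; plateaus never qualify by strictness).
    """
    v = np.where(stat_map.mask, stat_map.values, -np.inf)
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(v, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    is_peak = (v > neigh_max) & (v > min_z) & stat_map.mask
    idx = np.argwhere(is_peak)
    if idx.size == 0:
        return np.empty((0, 3))
    zvals = stat_map.values[tuple(idx.T)]
    order = np.argsort(-zvals, kind="stable")
    idx = idx[order]
    return idx.astype(float) @ stat_map.affine[:3, :3].T + stat_map.affine[:3, 3]


def subject_seed(canonical: SeedSpec, peaks, max_dist_mm: float = 18.0) -> SeedSpec:
    """Relocate a canonical seed to the nearest individual peak.

    ``peaks`` is an (N, 3) array of world coordinates sorted by
    descending z (as returned by :func:`local_maxima`).  If the nearest
    peak lies within ``max_dist_mm`` (inclusive) the seed moves there
    with origin ``subject_specific``; ties in distance go to the higher
    z (earlier row), then lexicographic coordinates.  With no peak in
    range the canonical seed is returned unchanged.
    """
    peaks = np.asarray(peaks, dtype=float).reshape(-1, 3)
    if peaks.shape[0] == 0:
        return canonical
    d = np.linalg.norm(peaks - np.asarray(canonical.center_mm), axis=1)
    dmin = d.min()
    if dmin > max_dist_mm:
        return canonical
    # rows arrive sorted by descending z (stable over lexicographic voxel
    # order), so the first row among distance ties has the highest z and,
    # within equal z, the lexicographically smallest coordinates.
    best = int(np.where(np.isclose(d, dmin))[0][0])
    return replace(canonical, center_mm=tuple(peaks[best]), origin="subject_specific")


def seed_signal(series: VolumetricTimeSeries, seed: SeedSpec,
                signal_radius_mm: float = 6.0) -> np.ndarray:
    """Mean ΔHbO series over in-mask voxels whose centers lie within
    ``signal_radius_mm`` of the seed center."""
    centers = voxel_centers_world(series.spatial_shape, series.affine)
    d2 = ((centers - np.asarray(seed.center_mm)) ** 2).sum(axis=1)
    sel = (d2 <= signal_radius_mm**2) & series.mask.ravel()
    if not np.any(sel):
        raise ValueError(
            f"seed {seed.label}: no in-mask voxels within "
            f"{signal_radius_mm} mm of {seed.center_mm}"
        )
    return series.flat()[sel].mean(axis=0).astype(np.float64)


def seeds_to_tsv(seeds, path) -> None:
    pd.DataFrame(
        [{"label": s.label, "x": s.center_mm[0], "y": s.center_mm[1],
          "z": s.center_mm[2], "radius_mm": s.radius_mm, "origin": s.origin}
         for s in seeds]
    ).to_csv(path, sep="\t", index=False)


def seeds_from_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [SeedSpec(label=str(r.label), center_mm=(r.x, r.y, r.z),
                     radius_mm=float(r.radius_mm),
                     origin=getattr(r, "origin", "canonical"))
            for r in df.itertuples()]
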