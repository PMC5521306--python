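"""Physiological-relevance control with scrambled seed signals.

If the gPPI results reflect genuine coupling to the seed's physiology,
replacing each run's seed signal with the signal recorded in a
*different* run (stimulus order differs between runs, so the swapped
signal is task-irrelevant) must change the distribution of seed-to-ROI
values.  The run re-assignment is a seeded derangement (no run keeps
its own signal), and the real vs scrambled value distributions are
compared with a two-sample chi-square test on shared histogram bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import build_matrix
from .ppi import build_ppi_design, fit_ppi_runs, ppi_contrast

__all__ = [
    "DistributionComparison",
    "scramble_runs",
    "chi2_two_sample",
    "scrambled_control",
]


@dataclass
class DistributionComparison:
    """Two-sample histogram comparison: counts on shared bins, the
    chi-square statistic, its degrees of freedom and p-value."""

    bin_edges: np.ndarray
    counts_real: np.ndarray
    counts_scrambled: np.ndarray
    chi2: float
    dof: int
    p: float


def scramble_runs(seed_signals, seed: int = 0):
    """Reassign per-run seed signals by a seeded derangement.

    ``seed_signals`` is a sequence (or dict keyed by run) of 1-D arrays;
    all are truncated to the shortest length.  Every run receives the
    signal of some *other* run; the derangement is drawn uniformly
    (rejection sampling over random permutations) and is reproducible
    from the seed.
    """
    is_dict = isinstance(seed_signals, dict)
    keys = list(seed_signals) if is_dict else list(range(len(seed_signals)))
    signals = [np.asarray(seed_signals[k], dtype=float) for k in keys]
    n = len(signals)
    if n < 2:
        raise ValueError("scrambling needs at least two runs")
    n_min = min(s.size for s in signals)
    signals = [s[:n_min] for s in signals]
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            break
    out = [signals[perm[i]] for i in range(n)]
    return dict(zip(keys, out)) if is_dict else out


def chi2_two_sample(sample_a, sample_b, n_bins: int = 48) -> DistributionComparison:
    """Two-sample chi-square test of distributional equality.

    Both samples are histogrammed on common equal-width bins spanning
    the pooled range; bins whose smaller expected count (under the
    pooled distribution) falls below 5 are merged rightward with their
    neighbor (the last bin merges leftward); the homogeneity statistic
    sums (O - E)^2 / E over both samples with dof = usable_bins - 1.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; histogram is degenerate")
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)

    # merge low-expectation bins (expected under pooled proportions)
    n_a, n_b, n_tot = a.size, b.size, pooled.size
    min_frac = min(n_a, n_b) / n_tot
    ca, cb, edges = list(ca), list(cb), list(edges)
    i = 0
    while i < len(ca):
        if (ca[i] + cb[i]) * min_frac < 5 and len(ca) > 1:
            j = i + 1 if i + 1 < len(ca) else i - 1
            ca[min(i, j)] = ca[i] + ca[j]
            cb[min(i, j)] = cb[i] + cb[j]
            del ca[max(i, j)], cb[max(i, j)], edges[max(i, j) + 1 - (j < i)]
            if j < i:
                i -= 1
        else:
            i += 1
    ca = np.array(ca)
    cb = np.array(cb)
    edges = np.array(edges)

    pooled_counts = ca + cb
    ea = pooled_counts * n_a / n_tot
    eb = pooled_counts * n_b / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (ca - ea) ** 2 / ea + (cb - eb) ** 2 / eb
    chi2 = float(np.nansum(terms))
    dof = int(ca.size - 1)
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    return DistributionComparison(bin_edges=edges, counts_real=ca,
                                  counts_scrambled=cb, chi2=chi2, dof=dof, p=p)


def _truncate_design(design, end_s: float):
    """Drop events at or beyond ``end_s`` and clip durations to it."""
    from .synth import Event, EventDesign

    events = [Event(e.condition, e.onset, min(e.duration, end_s - e.onset))
              for e in design.events if e.onset < end_s]
    return EventDesign(run_id=design.run_id, events=events, length_s=end_s)


def _matrices_for_signals(series_by_run, designs, seed_signals_by_seed, seeds,
                          roi_seeds, hrf, rate, level, contrast, cube_side_mm,
                          match_band):
    """One TIC matrix and one TDC matrix from per-seed gPPI fits."""
    tic_maps, tdc_maps = [], []
    for seed in seeds:
        per_run = [
            build_ppi_design(d, seed_signals_by_seed[seed.label][i], hrf, rate,
                             s.n_timepoints, level=level, match_band=match_band)
            for i, (s, d) in enumerate(zip(series_by_run, designs))
        ]
        fit = fit_ppi_runs(series_by_run, per_run, seed=seed,
                           affine=series_by_run[0].affine)
        tic_maps.append((seed, fit.zmap({"tic": 1.0})))
        tdc_maps.append((seed, ppi_contrast(fit, *contrast)))
    tic = build_matrix(tic_maps, roi_seeds, cube_side_mm, kind="TIC")
    tdc = build_matrix(tdc_maps, roi_seeds, cube_side_mm, kind="TDC")
    return tic, tdc


def scrambled_control(series_by_run, designs, seeds, roi_seeds, hrf,
                      rate: float = 1.0, level: str = "hemodynamic",
                      contrast=("complex", "easy"), cube_side_mm: float = 9.0,
                      signal_radius_mm: float = 6.0, seed: int = 0,
                      n_bins: int = 48, exclude_self_pairs: bool = True,
                      match_band=(0.02, 0.5)):
    """Run the gPPI twice — real and run-scrambled seed signals — and
    compare the pooled seed-to-ROI value distributions.

    Returns ``(real, scrambled, tic_comparison, tdc_comparison)`` where
    ``real`` and ``scrambled`` are dicts with "TIC" and "TDC"
    :class:`ConnectivityMatrix` objects for one subject (pool entries
    across subjects before the chi-square when several are available).

    ``exclude_self_pairs`` drops seed-to-own-ROI entries from the pooled
    comparison (the returned matrices keep them): a seed trivially
    predicts its own region whatever the coupling structure, so those
    entries would make the comparison reject even for an uncoupled
    brain.
    """
    from .seeds import seed_signal

    series_by_run = list(series_by_run)
    if len(series_by_run) < 2:
        raise ValueError("the scrambled control needs at least two runs")
    # scrambling requires equal lengths: truncate every run (and its
    # event list) to the shortest run.
    n_min = min(s.n_timepoints for s in series_by_run)
    end_s = n_min / rate
    series_by_run = [s.with_data(s.data[..., :n_min]) for s in series_by_run]
    designs = [_truncate_design(d, end_s) for d in designs]

    real_signals = {
        s.label: [seed_signal(run, s, signal_radius_mm) for run in series_by_run]
        for s in seeds
    }
    scram_signals = {
        label: scramble_runs(sigs, seed=seed)
        for label, sigs in real_signals.items()
    }
    real_tic, real_tdc = _matrices_for_signals(
        series_by_run, designs, real_signals, seeds, roi_seeds, hrf, rate,
        level, contrast, cube_side_mm, match_band)
    scr_tic, scr_tdc = _matrices_for_signals(
        series_by_run, designs, scram_signals, seeds, roi_seeds, hrf, rate,
        level, contrast, cube_side_mm, match_band)
    keep = pooling_mask(real_tic.seed_labels, real_tic.roi_labels,
                        exclude_self_pairs)
    tic_cmp = chi2_two_sample(real_tic.values[keep], scr_tic.values[keep],
                              n_bins=n_bins)
    tdc_cmp = chi2_two_sample(real_tdc.values[keep], scr_tdc.values[keep],
                              n_bins=n_bins)
    return ({"TIC": real_tic, "TDC": real_tdc},
            {"TIC": scr_tic, "TDC": scr_tdc}, tic_cmp, tdc_cmp)


def pooling_mask(seed_labels, roi_labels, exclude_self_pairs: bool = True):
    """Boolean (seeds x ROIs) mask for pooling matrix entries."""
    mask = np.ones((len(seed_labels), len(roi_labels)), dtype=bool)
    if exclude_self_pairs:
        for i, s in enumerate(seed_labels):
            for j, r in enumerate(roi_labels):
                if s == r:
                    mask[i, j] = False
    return mask
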