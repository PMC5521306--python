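"""Synthetic ΔHbO recordings with known condition-dependent couplings.

Emulates the study protocol end to end so every downstream stage is
testable without any recorded data: an auditory sentence-comprehension
session of four runs, each with 30 easy (subject-relative) sentences,
30 complex (object-relative) sentences and 10 noise trials (2-s stimuli,
pseudorandom 2-10 s inter-stimulus intervals, button presses after
sentences), region-level neural activity with task-independent and
condition-modulated inter-region couplings, canonical-HRF hemodynamics
painted onto a 3-mm voxel grid with a 14-mm FWHM point spread, plus a
shared superficial (scalp) nuisance signal, 1/f noise and white noise
at a 10-Hz frame rate.

The generative coupling model is acyclic: region order in the layout is
a topological order, and only earlier regions may drive later ones.
Every artifact is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hemodynamics import HRFKernel, convolve
from .volume import VolumetricTimeSeries, voxel_centers_world

__all__ = [
    "Event",
    "EventDesign",
    "Region",
    "RegionLayout",
    "GroundTruthCouplings",
    "SyntheticRecording",
    "STIMULUS_CONDITIONS",
    "CONDITIONS",
    "generate_design",
    "generate_neural",
    "generate_recording",
    "pink_noise",
]

STIMULUS_CONDITIONS = ("easy", "complex", "noise")
CONDITIONS = STIMULUS_CONDITIONS + ("button_left", "button_right")

#: Per-run stimulus counts of the experimental protocol.
TRIALS_PER_RUN = {"easy": 30, "complex": 30, "noise": 10}

#: Seconds between a sentence onset and its button-press event.
BUTTON_LATENCY_S = 1.5

#: Quiet baseline before the first stimulus and after the last offset.
RUN_PAD_START_S = 10.0
RUN_PAD_END_S = 24.0

#: Point-spread full width at half maximum of the imaging array (mm).
POINT_SPREAD_FWHM_MM = 14.0


@dataclass(frozen=True)
class Event:
    condition: str
    onset: float
    duration: float


@dataclass
class EventDesign:
    """Ordered event list for one run (condition, onset s, duration s)."""

    run_id: int
    events: list
    length_s: float

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing within a run")
        if any(e.duration < 0 for e in self.events):
            raise ValueError("event durations must be non-negative")

    def of_condition(self, condition: str) -> list:
        return [e for e in self.events if e.condition == condition]

    @property
    def stimulus_events(self) -> list:
        return [e for e in self.events if e.condition in STIMULUS_CONDITIONS]

    def conditions_present(self) -> list:
        present = {e.condition for e in self.events}
        return [c for c in CONDITIONS if c in present]

    def task_vector(self, condition: str, rate: float, n_timepoints: int) -> np.ndarray:
        """Binary indicator: 1 while a stimulus of ``condition`` is on.

        Zero-duration events (button presses) become single-sample impulses.
        """
        tv = np.zeros(n_timepoints)
        t = np.arange(n_timepoints) / rate
        for e in self.of_condition(condition):
            if e.duration == 0:
                k = int(round(e.onset * rate))
                if k >= n_timepoints:
                    raise ValueError(f"event at {e.onset} s beyond series end")
                tv[k] = 1.0
            else:
                sel = (t >= e.onset) & (t < e.onset + e.duration)
                if e.onset + e.duration > n_timepoints / rate + 1e-9:
                    raise ValueError(f"event at {e.onset} s beyond series end")
                tv[sel] = 1.0
        return tv

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": self.run_id,
                "condition": [e.condition for e in self.events],
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, length_s: float | None = None) -> "EventDesign":
        events = [
            Event(str(r.condition), float(r.onset_s), float(r.duration_s))
            for r in frame.itertuples()
        ]
        if length_s is None:
            length_s = max(e.onset + e.duration for e in events) + RUN_PAD_END_S
        return cls(run_id=int(frame["run"].iloc[0]), events=events, length_s=length_s)


def generate_design(n_runs: int = 4, seed: int = 0,
                    isi_range=(2.0, 10.0), stim_duration: float = 2.0) -> list:
    """Generate per-run event designs for the sentence-comprehension protocol.

    Each run contains 30 easy, 30 complex and 10 noise 2-s stimuli in a
    seeded pseudorandom order (constant across simulated subjects for a
    fixed seed; the order differs between runs), with inter-stimulus
    intervals drawn uniformly on a 0.1-s grid over ``isi_range``.  Every
    sentence trial is followed by one zero-duration button event
    (side by seeded coin flip) 1.5 s after its onset.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    lo, hi = float(isi_range[0]), float(isi_range[1])
    if not (0 < lo < hi):
        raise ValueError(f"invalid ISI range {isi_range}: need 0 < low < high")
    if stim_duration <= 0:
        raise ValueError(f"stimulus duration must be positive, got {stim_duration}")

    root = np.random.SeedSequence(seed)
    designs = []
    for run_id, ss in enumerate(root.spawn(n_runs)):
        rng = np.random.default_rng(ss)
        conditions = sum(([c] * n for c, n in TRIALS_PER_RUN.items()), [])
        rng.shuffle(conditions)
        # ISIs on a 0.1-s grid, inclusive endpoints
        grid = np.round(np.arange(round(lo * 10), round(hi * 10) + 1) / 10.0, 1)
        isis = rng.choice(grid, size=len(conditions))
        events = []
        t = RUN_PAD_START_S
        for cond, isi in zip(conditions, isis):
            events.append(Event(cond, round(t, 1), stim_duration))
            if cond in ("easy", "complex"):
                side = "button_left" if rng.random() < 0.5 else "button_right"
                events.append(Event(side, round(t + BUTTON_LATENCY_S, 1), 0.0))
            t = t + stim_duration + isi
        length = round(t - isis[-1] + RUN_PAD_END_S, 1)
        designs.append(EventDesign(run_id=run_id, events=events, length_s=length))
    return designs


# ---------------------------------------------------------------------------
# Region layout


@dataclass(frozen=True)
class Region:
    label: str
    center_mm: tuple
    radius_mm: float


#: Canonical speech-network seed centers (MNI-style mm): dorsal premotor,
#: dorsal middle frontal, dorsal inferior parietal, lateral superior
#: temporal, posterior middle temporal, anterior superior temporal and
#: ventral inferior prefrontal cortex, left-lateralized plus three right
#: homologues.
CANONICAL_REGION_TABLE = [
    ("L_dpreMG", -61.5, 3.0, 45.5),
    ("L_dMFG", -46.5, 24.0, 39.0),
    ("L_dIPG", -55.5, -54.0, 45.0),
    ("L_lSTG", -52.5, -21.0, -3.0),
    ("L_pMTG", -55.5, -66.0, 3.0),
    ("L_aSTG", -67.5, 9.0, -15.0),
    ("L_vIFG", -40.5, 39.0, -6.0),
    ("R_lSTG", 67.5, -21.0, 0.0),
    ("R_pMTG", 64.5, -57.0, 3.0),
    ("R_vIFG", 52.5, 27.0, -9.0),
]

#: Fixed world box (mm) of the default grid, chosen so all canonical
#: region spheres (radius 6 mm) lie inside it at any voxel size; the
#: voxel lattice is centered in this box.
_GRID_BOX_LO_MM = (-75.0, -87.0, -51.0)
_GRID_EXTENT_MM = (150.0, 174.0, 132.0)


@dataclass
class RegionLayout:
    """Spherical regions on a regular voxel grid with a diagonal affine."""

    regions: list
    voxel_size: float
    grid_shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        lo = np.array(_world_box(self.grid_shape, self.affine)[0])
        hi = np.array(_world_box(self.grid_shape, self.affine)[1])
        for r in self.regions:
            c = np.asarray(r.center_mm, dtype=float)
            if np.any(c - r.radius_mm < lo) or np.any(c + r.radius_mm > hi):
                raise ValueError(f"region {r.label} sphere extends outside the grid")

    @property
    def labels(self) -> list:
        return [r.label for r in self.regions]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def center(self, label: str) -> np.ndarray:
        return np.asarray(self.regions[self.index(label)].center_mm, dtype=float)

    @classmethod
    def default(cls, voxel_size: float = 3.0, region_radius_mm: float = 6.0,
                table=None) -> "RegionLayout":
        """Canonical 10-region speech-network layout.

        ``voxel_size`` scales the grid resolution (3 mm default; coarser
        values give desk-scale grids over the same world extent).
        """
        if table is None:
            table = CANONICAL_REGION_TABLE
        shape = tuple(int(np.ceil(e / voxel_size)) for e in _GRID_EXTENT_MM)
        # center the lattice in the fixed world box: first voxel center
        # sits half a voxel in, shifted by half the rounding overhang
        origin = [lo + voxel_size / 2.0 - (voxel_size * n - e) / 2.0
                  for lo, e, n in zip(_GRID_BOX_LO_MM, _GRID_EXTENT_MM, shape)]
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
        affine[:3, 3] = origin
        regions = [Region(lab, (x, y, z), region_radius_mm) for lab, x, y, z in table]
        layout = cls(regions=regions, voxel_size=voxel_size,
                     grid_shape=shape, affine=affine)
        _check_nonoverlap(layout)
        return layout


def _world_box(grid_shape, affine):
    vs = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    lo = origin - vs / 2.0
    hi = origin + vs * (np.array(grid_shape) - 1) + vs / 2.0
    return lo, hi


def _check_nonoverlap(layout: RegionLayout) -> None:
    centers = np.array([r.center_mm for r in layout.regions])
    radii = np.array([r.radius_mm for r in layout.regions])
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = np.linalg.norm(centers[i] - centers[j])
            if d <= radii[i] + radii[j]:
                raise ValueError(
                    f"regions {layout.regions[i].label} and "
                    f"{layout.regions[j].label} overlap (distance {d:.1f} mm)"
                )


# ---------------------------------------------------------------------------
# Ground-truth couplings


@dataclass
class GroundTruthCouplings:
    """Known generative gains: evoked amplitudes, task-independent
    couplings ``a`` and condition-dependent modulations ``b``.

    ``baseline[r, c]`` is the evoked neural amplitude of region r to
    condition c; ``coupling[t, s]`` the task-independent gain from
    source s onto target t; ``modulation[t, s, c]`` the extra gain
    active while condition-c stimuli are on.  The coupling diagonal is
    zero and modulation defaults to zero.
    """

    labels: list
    conditions: tuple = STIMULUS_CONDITIONS
    baseline: np.ndarray = None
    coupling: np.ndarray = None
    modulation: np.ndarray = None

    def __post_init__(self):
        n, c = len(self.labels), len(self.conditions)
        if self.baseline is None:
            self.baseline = np.zeros((n, c))
        if self.coupling is None:
            self.coupling = np.zeros((n, n))
        if self.modulation is None:
            self.modulation = np.zeros((n, n, c))
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.modulation = np.asarray(self.modulation, dtype=float)
        if self.baseline.shape != (n, c) or self.coupling.shape != (n, n) \
                or self.modulation.shape != (n, n, c):
            raise ValueError("coupling array shapes inconsistent with labels/conditions")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero")

    @classmethod
    def null(cls, labels, conditions=STIMULUS_CONDITIONS) -> "GroundTruthCouplings":
        return cls(labels=list(labels), conditions=tuple(conditions))

    def set_baseline(self, region: str, condition: str, gain: float) -> None:
        self.baseline[self.labels.index(region), self.conditions.index(condition)] = gain

    def set_coupling(self, target: str, source: str, gain: float) -> None:
        self.coupling[self.labels.index(target), self.labels.index(source)] = gain

    def set_modulation(self, target: str, source: str, condition: str, gain: float) -> None:
        self.modulation[self.labels.index(target), self.labels.index(source),
                        self.conditions.index(condition)] = gain

    def check_acyclic(self) -> None:
        """Couplings may only run from earlier-listed to later-listed regions."""
        upper = np.triu(np.abs(self.coupling) + np.abs(self.modulation).sum(axis=2))
        if np.any(upper != 0):
            t, s = np.argwhere(upper != 0)[0]
            raise ValueError(
                f"cyclic coupling graph: source {self.labels[s]} does not precede "
                f"target {self.labels[t]} in the declared region order"
            )


def generate_neural(design: EventDesign, layout: RegionLayout,
                    truth: GroundTruthCouplings, rate: float = 10.0,
                    noise_sd: float = 0.0, noise_tau_s: float = 1.0,
                    seed: int = 0) -> np.ndarray:
    """Region-by-time neural activity for one run.

    Each region's activity is the sum of its evoked responses (boxcars of
    the condition task vectors scaled by the baseline gains), coupling
    inputs from earlier-listed regions (task-independent gain plus
    condition-gated modulation), and its own white noise.  Couplings act
    on the source's *full* activity — evoked plus the source's intrinsic
    noise — computed in the declared region order, so the forward model
    stays acyclic.  Propagating the intrinsic fluctuations matters: a
    purely deterministic interaction would be exactly collinear with the
    task-response regressor and no interaction coefficient could be
    identified, whereas connectivity in the interaction model is carried
    precisely by the seed's endogenous trial-to-trial variability.

    The intrinsic noise has correlation time ``noise_tau_s`` (Gaussian-
    smoothed white noise renormalized to ``noise_sd``; 0 gives white
    noise).  Ongoing cortical activity is slow compared to the 10-Hz
    frame rate, and only fluctuations below the hemodynamic pass band
    are observable through the HRF at all.
    """
    truth.check_acyclic()
    n_t = int(round(design.length_s * rate))
    n_r = len(layout.regions)
    tvs = np.stack([design.task_vector(c, rate, n_t) for c in truth.conditions])
    rng = np.random.default_rng(seed)

    if noise_sd > 0:
        noise = rng.normal(0.0, 1.0, size=(n_r, n_t))
        if noise_tau_s > 0:
            from scipy import ndimage as _ndi

            noise = _ndi.gaussian_filter1d(noise, noise_tau_s * rate, axis=-1)
            noise /= noise.std(axis=-1, keepdims=True)
        noise *= noise_sd
    else:
        noise = np.zeros((n_r, n_t))
    neural = np.zeros((n_r, n_t))
    for r in range(n_r):
        act = truth.baseline[r] @ tvs + noise[r]
        for s in range(r):
            gain_t = truth.coupling[r, s] + truth.modulation[r, s] @ tvs
            act = act + gain_t * neural[s]
        neural[r] = act
    return neural


# ---------------------------------------------------------------------------
# Noise generators


def _spectral_noise(shape, amp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise (float32) whose rfft amplitude spectrum is ``amp``.

    For Hermitian-random coefficients c_k = amp_k (g1 + i g2) with unit
    normal g's, E|c_k|^2 = 2 amp_k^2 and the synthesized series has
    variance 4 sum_k amp_k^2 / n^2; callers scale ``amp`` so this equals
    the variance they want.  DC (amp[0]) is conventionally 0.
    """
    import scipy.fft

    shape = tuple(np.atleast_1d(shape))
    n = shape[-1]
    coeffs = rng.standard_normal(shape[:-1] + (amp.size, 2), dtype=np.float32) \
        .view(np.complex64)[..., 0]
    coeffs *= amp.astype(np.float32)
    return scipy.fft.irfft(coeffs, n=n, axis=-1)


def _unit_amp(amp: np.ndarray, n: int) -> np.ndarray:
    """Scale an amplitude spectrum so the synthesized noise has unit variance."""
    s = np.sqrt(4.0 * float((amp ** 2).sum()) / n**2)
    return amp / s if s > 0 else amp


def pink_noise(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (power) noise along the last axis, synthesized
    in the frequency domain."""
    shape = tuple(np.atleast_1d(shape))
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros(freqs.size)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    return _spectral_noise(shape, _unit_amp(amp, n), rng)


def _sensitivity_image(layout: RegionLayout) -> np.ndarray:
    """Flat-field sensitivity: positive, maximal centrally, decaying
    radially so corners fall more than two decades below the maximum."""
    centers = voxel_centers_world(layout.grid_shape, layout.affine)
    lo, hi = _world_box(layout.grid_shape, layout.affine)
    mid = (np.asarray(lo) + np.asarray(hi)) / 2.0
    d2 = ((centers - mid) ** 2).sum(axis=1)
    sigma = 40.0  # mm
    return np.exp(-d2 / (2.0 * sigma**2)).reshape(layout.grid_shape)


@dataclass
class SyntheticRecording:
    """Complete simulated session: per-run 4-D series and event designs,
    the shared region layout and ground-truth couplings, the superficial
    nuisance traces and the sensitivity image."""

    series: list
    designs: list
    layout: RegionLayout
    truth: GroundTruthCouplings
    superficial: list
    sensitivity: np.ndarray
    seed: int


def generate_recording(designs, layout: RegionLayout, truth: GroundTruthCouplings,
                       hrf: HRFKernel, superficial_amp: float = 3.0,
                       pink_amp: float = 2.0, white_amp: float = 1.0,
                       neural_noise_sd: float = 2.0, neural_noise_tau_s: float = 1.0,
                       rate: float = 10.0, seed: int = 0) -> SyntheticRecording:
    """Forward-model a full session of volumetric ΔHbO recordings.

    Per run: region neural activity is convolved with the HRF and painted
    onto the grid with a Gaussian spatial falloff (FWHM 14 mm, the
    imaging array's point spread), then a shared superficial (scalp)
    1/f-like nuisance trace, voxelwise 1/f noise and white noise are
    added.  Amplitudes are unitless (the pipeline is scale-invariant);
    the defaults give subject-level evoked z-scores in the range seen in
    optical imaging of auditory cortex.
    """
    for name, amp in [("superficial_amp", superficial_amp),
                      ("pink_amp", pink_amp), ("white_amp", white_amp)]:
        if amp < 0:
            raise ValueError(f"{name} must be non-negative, got {amp}")
    if not np.isclose(hrf.rate, rate):
        raise ValueError(f"HRF rate {hrf.rate} Hz != series rate {rate} Hz")

    centers = voxel_centers_world(layout.grid_shape, layout.affine)
    sig2 = (POINT_SPREAD_FWHM_MM / (2.0 * np.sqrt(2.0 * np.log(2.0)))) ** 2
    weights = np.empty((centers.shape[0], len(layout.regions)))
    for i, reg in enumerate(layout.regions):
        d2 = ((centers - np.asarray(reg.center_mm)) ** 2).sum(axis=1)
        weights[:, i] = np.exp(-d2 / (2.0 * sig2))

    root = np.random.SeedSequence(seed)
    run_seeds = root.spawn(len(designs))
    series, sup_signals = [], []
    for design, ss in zip(designs, run_seeds):
        ss_neural, ss_sup, ss_pink, ss_white = ss.spawn(4)
        n_t = int(round(design.length_s * rate))
        neural = generate_neural(design, layout, truth, rate=rate,
                                 noise_sd=neural_noise_sd,
                                 noise_tau_s=neural_noise_tau_s,
                                 seed=np.random.default_rng(ss_neural).integers(2**31))
        hemo = np.stack([convolve(neural[r], hrf) for r in range(neural.shape[0])])
        data = weights.astype(np.float32) @ hemo.astype(np.float32)  # (voxels, time)
        sup = pink_noise(n_t, rate, np.random.default_rng(ss_sup)).astype(np.float64)
        if superficial_amp > 0:
            data += np.float32(superficial_amp) * sup.astype(np.float32)
        if pink_amp > 0 or white_amp > 0:
            # voxelwise 1/f + white noise synthesized in one spectral pass
            freqs = np.fft.rfftfreq(n_t, d=1.0 / rate)
            amp_pink = np.zeros(freqs.size)
            amp_pink[1:] = 1.0 / np.sqrt(freqs[1:])
            amp_white = np.ones(freqs.size)
            amp_white[0] = 0.0
            amp = np.sqrt((pink_amp * _unit_amp(amp_pink, n_t)) ** 2
                          + (white_amp * _unit_amp(amp_white, n_t)) ** 2)
            data += _spectral_noise((data.shape[0], n_t), amp,
                                    np.random.default_rng(ss_pink))
        vol = VolumetricTimeSeries(
            data=data.reshape(layout.grid_shape + (n_t,)),
            affine=layout.affine, rate=rate,
        )
        series.append(vol)
        sup_signals.append(sup)
    return SyntheticRecording(series=series, designs=list(designs), layout=layout,
                              truth=truth, superficial=sup_signals,
                              sensitivity=_sensitivity_image(layout), seed=seed)
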