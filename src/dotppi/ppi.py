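"""Generalized psychophysiological interaction (gPPI) model.

Per voxel j the model is

    y_j(t) = X_TDR(t) b_TDR + y_s(t) b_TIC + X_TDC(t) b_TDC + e_j(t)

with X_TDR the task-response regressors (stimulus streams convolved
with the canonical HRF), y_s the seed's signal (task-independent
connectivity), and one task-dependent connectivity (TDC) column per
stimulus condition — the interaction terms that carry the effective
connectivity of interest.

Two TDC constructions are supported:

* hemodynamic level: elementwise product of the (mean-centered) seed
  signal and the condition's TDR column;
* neural level: deconvolve the HRF from the seed signal, mean-center,
  gate by the binary task vector (1 during 2-s stimulus epochs), and
  reconvolve with the same HRF.

Mean-centering the physiological signal before forming products keeps
the interaction columns from absorbing the main effects and is what
makes the model well-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import DesignMatrix, StatMap, build_design, fit_glm, fixed_effects
from .hemodynamics import HRFKernel, convolve, deconvolve
from .seeds import SeedSpec
from .synth import STIMULUS_CONDITIONS, EventDesign

__all__ = [
    "PPIDesign",
    "PPIFit",
    "tdc_hemodynamic",
    "tdc_neural",
    "build_ppi_design",
    "fit_ppi",
    "fit_ppi_runs",
    "ppi_contrast",
    "CONDITION_NUMBER_GUARD",
]

#: Condition-number limit of the standardized design beyond which the
#: fit aborts (uncentered seed products typically trip this).
CONDITION_NUMBER_GUARD = 1e8


def tdc_hemodynamic(tic, tdr_column) -> np.ndarray:
    """Hemodynamic-level interaction: elementwise product of the seed
    signal (already mean-centered by the caller) and a TDR column."""
    tic = np.asarray(tic, dtype=float)
    tdr_column = np.asarray(tdr_column, dtype=float)
    if tic.shape != tdr_column.shape:
        raise ValueError(f"length mismatch: tic {tic.shape} vs tdr {tdr_column.shape}")
    return tic * tdr_column


def tdc_neural(tic, hrf: HRFKernel, task_vector, regularization="auto",
               center: bool = True) -> np.ndarray:
    """Neural-level interaction: deconvolve the seed signal, mean-center
    the neural estimate, gate it by the binary task vector, and
    reconvolve with the same kernel."""
    task_vector = np.asarray(task_vector, dtype=float)
    if not np.all(np.isin(task_vector, (0.0, 1.0))):
        raise ValueError("task vector must be binary (1 during stimulus epochs)")
    est = deconvolve(tic, hrf, regularization).samples
    if center:
        est = est - est.mean()
    return convolve(est * task_vector, hrf)


@dataclass
class PPIDesign:
    """Assembled gPPI regressors for one run."""

    tdr: DesignMatrix
    tic: np.ndarray
    tdc: dict                      # condition -> column
    interaction_level: str
    rate: float

    def __post_init__(self):
        self.tic = np.asarray(self.tic, dtype=float)
        self.tdc = {c: np.asarray(v, dtype=float) for c, v in self.tdc.items()}
        n = self.tdr.n_timepoints
        if self.tic.size != n or any(c.size != n for c in self.tdc.values()):
            raise ValueError("PPI design columns must all share the run length")
        bad = set(self.tdc) - set(STIMULUS_CONDITIONS)
        if bad:
            raise ValueError(f"TDC conditions must be stimulus conditions, got {sorted(bad)}")

    def design_matrix(self) -> DesignMatrix:
        names = [f"tdr_{n}" if n != "intercept" else n for n in self.tdr.names]
        cols = [self.tdr.matrix]
        names.append("tic")
        cols.append(self.tic.reshape(-1, 1))
        for cond in STIMULUS_CONDITIONS:
            if cond in self.tdc:
                names.append(f"tdc_{cond}")
                cols.append(self.tdc[cond].reshape(-1, 1))
        return DesignMatrix(matrix=np.hstack(cols), names=names, rate=self.rate)


def build_ppi_design(events: EventDesign, seed_ts, hrf: HRFKernel, rate: float,
                     n_timepoints: int, level: str = "neural",
                     center_tic: bool = True, regularization="auto",
                     match_band=None) -> PPIDesign:
    """Build the full gPPI design for one run.

    ``level`` selects the TDC construction ("hemodynamic" or "neural").
    ``center_tic`` mean-centers the physiological signal before products
    are formed (recommended; the TIC column itself is centered too,
    which is inconsequential given the intercept).  ``match_band``
    filters the TDR and TDC columns with the preprocessing band so the
    regressors live in the same frequencies as the (already filtered)
    data; the seed signal needs no extra filtering.
    """
    if level not in ("hemodynamic", "neural"):
        raise ValueError(f"unknown interaction level {level!r}")
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.size != n_timepoints:
        raise ValueError("seed signal length must equal n_timepoints")
    from .glm import match_filter

    tdr = build_design(events, hrf, rate, n_timepoints, match_band=match_band)
    tic = seed_ts - seed_ts.mean() if center_tic else seed_ts
    stim_present = [c for c in STIMULUS_CONDITIONS if c in events.conditions_present()]
    tdc = {}
    if level == "hemodynamic":
        for cond in stim_present:
            col = tdr.matrix[:, tdr.names.index(cond)]
            tdc[cond] = tdc_hemodynamic(tic, col)
    else:
        est = deconvolve(seed_ts, hrf, regularization).samples
        if center_tic:
            est = est - est.mean()
        for cond in stim_present:
            tv = events.task_vector(cond, rate, n_timepoints)
            tdc[cond] = convolve(est * tv, hrf)
    if match_band is not None:
        tdc = {c: match_filter(v, rate, match_band) for c, v in tdc.items()}
    return PPIDesign(tdr=tdr, tic=tic, tdc=tdc, interaction_level=level, rate=rate)


@dataclass
class PPIFit:
    """Per-run GLM fits of the gPPI model for one seed."""

    fits: list                     # one GLMFit per run
    seed: SeedSpec
    interaction_level: str
    affine: np.ndarray = None

    @property
    def tdc_conditions(self) -> list:
        return [n[4:] for n in self.fits[0].design.names if n.startswith("tdc_")]

    def beta(self, column: str) -> np.ndarray:
        """Per-run-averaged coefficient field for a named column."""
        vals = [f.beta[:, f.design.names.index(column)] for f in self.fits]
        return np.mean(vals, axis=0).reshape(self.fits[0].spatial_shape)

    def zmap(self, contrast) -> StatMap:
        """Fixed-effects z-map for a contrast over the model columns."""
        return fixed_effects(self.fits, contrast, affine=self.affine)


def _check_conditioning(dm: DesignMatrix) -> None:
    X = dm.matrix
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    cond = np.linalg.cond(X / sd)
    if cond > CONDITION_NUMBER_GUARD:
        raise ValueError(
            f"gPPI design is ill-conditioned (condition number {cond:.3g}); "
            "mean-center the seed signal before forming interaction columns"
        )


def fit_ppi(series, design: PPIDesign, seed: SeedSpec = None,
            affine=None) -> PPIFit:
    """Fit the gPPI model for a single run."""
    dm = design.design_matrix()
    _check_conditioning(dm)
    return PPIFit(fits=[fit_glm(series, dm)], seed=seed,
                  interaction_level=design.interaction_level, affine=affine)


def fit_ppi_runs(series_list, designs, seed: SeedSpec = None, affine=None) -> PPIFit:
    """Fit the gPPI model run by run; contrasts pool by fixed effects."""
    designs = list(designs)
    series_list = list(series_list)
    if len(series_list) != len(designs):
        raise ValueError("one PPI design per run is required")
    fits = []
    for s, d in zip(series_list, designs):
        dm = d.design_matrix()
        _check_conditioning(dm)
        fits.append(fit_glm(s, dm))
    level = designs[0].interaction_level
    return PPIFit(fits=fits, seed=seed, interaction_level=level, affine=affine)


def ppi_contrast(fit: PPIFit, condition_a: str, condition_b: str = None) -> StatMap:
    """z-map of b_TDC(condition_a) - b_TDC(condition_b).

    With ``condition_b=None`` the map tests condition_a's TDC against
    zero.  Identical conditions give the zero map; swapping the two
    conditions negates it.
    """
    conds = fit.tdc_conditions
    for c in filter(None, (condition_a, condition_b)):
        if c not in conds:
            raise ValueError(f"condition {c!r} has no TDC column (available: {conds})")
    contrast = {f"tdc_{condition_a}": 1.0}
    if condition_b is not None:
        contrast[f"tdc_{condition_b}"] = contrast.get(f"tdc_{condition_b}", 0.0) - 1.0
    return fit.zmap(contrast)
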