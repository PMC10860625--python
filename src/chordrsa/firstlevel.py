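"""Minimal first-level GLM for synthetic BOLD time series.

Condition regressors are boxcars over the chord blocks convolved with a
canonical double-gamma haemodynamic response (peak ~5 s), optionally with
temporal-derivative columns; an ordinary least squares fit per run yields
the condition x voxel activity patterns and the residual series that the
crossnobis stage consumes.  No prewhitening: the RSA stage uses the
residual covariance directly, so GLM-level autocorrelation modelling is
deliberately omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .designs import SessionDesign

# canonical double-gamma parameters: response gamma peaking at 6 (shape 6,
# scale 1), undershoot gamma peaking at 16, undershoot ratio 1/6
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_DISPERSION = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


def hrf_double_gamma(
    t_s: np.ndarray | float,
    peak_delay: float = HRF_PEAK_DELAY,
    undershoot_delay: float = HRF_UNDERSHOOT_DELAY,
    dispersion: float = HRF_DISPERSION,
    undershoot_ratio: float = HRF_UNDERSHOOT_RATIO,
) -> np.ndarray:
    """Canonical difference-of-gamma-densities response, normalised to
    unit peak.  Zero at t = 0 and for t < 0; decays to ~0 by 30 s."""
    if min(peak_delay, undershoot_delay, dispersion) <= 0:
        raise ValueError("shape parameters must be positive")
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    h = sps.gamma.pdf(t, peak_delay / dispersion, scale=dispersion) - (
        undershoot_ratio * sps.gamma.pdf(t, undershoot_delay / dispersion, scale=dispersion)
    )
    h[t < 0] = 0.0
    # unit peak normalisation on a dense internal grid
    grid = np.linspace(0, 32, 3201)
    hg = sps.gamma.pdf(grid, peak_delay / dispersion, scale=dispersion) - (
        undershoot_ratio * sps.gamma.pdf(grid, undershoot_delay / dispersion, scale=dispersion)
    )
    h = h / hg.max()
    return h if np.ndim(t_s) else float(h[0])


@dataclass
class DesignMatrix:
    values: np.ndarray  # (n_volumes, n_regressors)
    labels: list[str]
    condition_labels: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


def build_design_matrix(
    design: SessionDesign,
    run: int,
    tr_s: float | None = None,
    n_volumes: int | None = None,
    with_derivatives: bool = True,
    nuisance: np.ndarray | None = None,
    oversample_dt_s: float = 0.05,
) -> DesignMatrix:
    """Per-run design matrix: one boxcar-convolved-with-HRF column per
    condition (sampled at the TR), finite-difference temporal
    derivatives if requested, an intercept, and optional nuisance
    columns.  Raises on rank deficiency, naming the collinear columns.
    """
    tr_s = design.tr_s if tr_s is None else tr_s
    n_volumes = design.n_volumes_per_run if n_volumes is None else n_volumes
    trials = design.trials_in_run(run)
    conditions = [c.label for c in design.configs]

    run_s = n_volumes * tr_s
    if trials and max(t.onset_s + t.response_window_s for t in trials) > run_s:
        raise ValueError("design does not fit within the run duration")

    n_fine = int(np.ceil(run_s / oversample_dt_s)) + 1
    t_fine = np.arange(n_fine) * oversample_dt_s
    hrf = hrf_double_gamma(np.arange(0, 32, oversample_dt_s))
    t_scan = np.arange(n_volumes) * tr_s

    cols, labels = [], []
    for cond in conditions:
        box = np.zeros(n_fine)
        for tr in trials:
            if tr.config.label == cond:
                box[(t_fine >= tr.onset_s) & (t_fine < tr.onset_s + tr.response_window_s)] = 1.0
        conv = np.convolve(box, hrf)[:n_fine] * oversample_dt_s
        cols.append(np.interp(t_scan, t_fine, conv))
        labels.append(cond)
    if with_derivatives:
        for cond, col in zip(conditions, list(cols)):
            d = np.gradient(col, tr_s)
            cols.append(d)
            labels.append(f"{cond}_deriv")

    cols.append(np.ones(n_volumes))
    labels.append("intercept")

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_volumes:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_volumes:
            raise ValueError("nuisance rows must match n_volumes")
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            labels.append(f"nuisance{j}")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        keep, bad = [], []
        for j in range(X.shape[1]):
            trial_rank = np.linalg.matrix_rank(X[:, keep + [j]])
            if trial_rank == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(labels[j])
        raise np.linalg.LinAlgError(f"design matrix rank deficient; collinear columns: {bad}")
    return DesignMatrix(values=X, labels=labels, condition_labels=conditions)


@dataclass
class GlmFit:
    betas: np.ndarray  # (n_regressors, n_voxels)
    residuals: np.ndarray  # (n_volumes, n_voxels)
    design: DesignMatrix

    def condition_patterns(self) -> np.ndarray:
        """(n_conditions, n_voxels) slice of the betas."""
        idx = [self.design.labels.index(c) for c in self.design.condition_labels]
        return self.betas[idx]


def fit_glm(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> GlmFit:
    """Ordinary least squares per voxel; residuals are orthogonal to the
    design columns by construction."""
    design = X if isinstance(X, DesignMatrix) else DesignMatrix(np.asarray(X, float), [f"x{i}" for i in range(np.asarray(X).shape[1])])
    Xv = design.values
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != Xv.shape[0]:
        raise ValueError("Y and X must have matching rows")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    betas, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    residuals = Y - Xv @ betas
    return GlmFit(betas=betas, residuals=residuals, design=design)
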