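"""Crossnobis RSA: noise normalisation, cross-validated distances,
pair selection, interhemispheric homotopy and contralateral typicality.

The crossnobis (cross-validated Mahalanobis) distance between condition
patterns is computed across independent runs after multivariate noise
normalisation, so that two patterns differing only by noise have zero
expected dissimilarity — estimates can therefore be negative, and
values significantly above zero indicate genuine information content.
Distances are divided by the voxel count so they are comparable across
regions of different size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .patterns import PatternSet
from .rdm import RDM, mean_rdm


class UndefinedCorrelationError(ValueError):
    """Correlation of a zero-variance RDM is undefined."""


@dataclass
class NoiseModel:
    covariance: np.ndarray  # voxel x voxel, after shrinkage
    whitener: np.ndarray  # inverse symmetric square root
    shrinkage: float

    @property
    def n_voxels(self) -> int:
        return self.covariance.shape[0]


def _shrinkage_weight(X: np.ndarray, S: np.ndarray) -> float:
    """Optimal shrinkage intensity toward the diagonal target
    (Schafer-Strimmer estimator for the off-diagonal entries)."""
    n = X.shape[0]
    if n < 4:
        return 1.0
    Xc = X - X.mean(axis=0, keepdims=True)
    wbar = (Xc.T @ Xc) / n
    A = (Xc**2).T @ (Xc**2)  # sum_k x_ki^2 x_kj^2
    var_s = n / (n - 1) ** 3 * (A - n * wbar**2)
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = (S[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    lam = var_s[off].sum() / denom
    return float(np.clip(lam, 0.0, 1.0))


def estimate_noise_model(
    residuals: np.ndarray | list[np.ndarray],
    shrinkage: float | None = None,
    eig_floor: float = 1e-10,
) -> NoiseModel:
    """Pooled voxel covariance of run-wise GLM residuals with shrinkage
    toward its diagonal, and the inverse symmetric square root used for
    whitening.

    ``residuals``: (n_runs, n_samples, n_voxels) array or list of
    (n_samples, n_voxels) arrays; each run is demeaned before pooling.
    ``shrinkage=None`` selects the optimal weight; 1 gives an exactly
    diagonal model.
    """
    if isinstance(residuals, np.ndarray) and residuals.ndim == 3:
        runs = list(residuals)
    elif isinstance(residuals, np.ndarray) and residuals.ndim == 2:
        runs = [residuals]
    else:
        runs = [np.asarray(r, dtype=float) for r in residuals]
    X = np.concatenate([r - r.mean(axis=0, keepdims=True) for r in runs], axis=0)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residual samples per voxel")
    S = (X.T @ X) / (n - 1)
    lam = _shrinkage_weight(X, S) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    Sigma = lam * np.diag(np.diag(S)) + (1.0 - lam) * S
    w, V = np.linalg.eigh(Sigma)
    w = np.maximum(w, eig_floor * w.max())
    whitener = (V / np.sqrt(w)) @ V.T
    return NoiseModel(covariance=Sigma, whitener=whitener, shrinkage=lam)


def crossnobis_rdm(patterns: PatternSet, noise: NoiseModel | None = None, **meta) -> RDM:
    """Cross-validated (squared) Mahalanobis distances between condition
    patterns, averaged over all ordered run pairs m != n and divided by
    the voxel count:

        d(i, j) = mean_{m != n} (b_i^m - b_j^m) S^-1 (b_i^n - b_j^n)^T / P

    ``noise=None`` skips noise normalisation (Euclidean crossnobis).
    """
    B = patterns.patterns
    M, n_cond, P = B.shape
    if M < 2:
        raise ValueError("crossnobis needs >= 2 runs")
    if noise is not None:
        if noise.n_voxels != P:
            raise ValueError("noise model voxel count does not match patterns")
        B = B @ noise.whitener
    iu, ju = np.triu_indices(n_cond, k=1)
    deltas = B[:, iu, :] - B[:, ju, :]  # (M, n_pairs, P)
    total = deltas.sum(axis=0)  # (n_pairs, P)
    cross = (total**2).sum(axis=1) - (deltas**2).sum(axis=(0, 2))
    d = cross / (M * (M - 1) * P)
    return RDM(labels=patterns.condition_labels, values=d, meta={**patterns.meta, **meta})


def select_pairs(rdm: RDM, pair_spec) -> tuple[dict[tuple[str, str], float], float]:
    """Requested RDM entries and their mean.

    ``pair_spec`` is either the string ``"all"`` (all 10 cells) or an
    iterable of (label_a, label_b) pairs; unknown labels raise.
    """
    if isinstance(pair_spec, str):
        if pair_spec != "all":
            raise KeyError(f"unknown pair spec {pair_spec!r}")
        entries = dict(zip(rdm.pairs(), rdm.values))
    else:
        entries = {}
        for a, b in pair_spec:
            entries[(str(a), str(b))] = rdm.entry(a, b)
    return entries, float(np.mean(list(entries.values())))


@dataclass(frozen=True)
class RdmComparison:
    r: float
    z: float
    kind: str  # "homotopy" | "typicality"
    method: str  # "pearson" | "spearman"


def fisher_z(r: float) -> float:
    """atanh of r clipped to +/-(1 - 1e-12) to keep z finite."""
    return float(np.arctanh(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)))


def _rdm_correlation(a: RDM, b: RDM, method: str) -> float:
    if a.labels != b.labels:
        raise ValueError("RDMs must share condition labels")
    x, y = a.values, b.values
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance RDM")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def homotopy(rdm_contra: RDM, rdm_ipsi: RDM, method: str = "pearson") -> RdmComparison:
    """Interhemispheric similarity of representational geometry: the
    correlation across the 10 pair dissimilarities of homologous
    regions, Fisher r-to-z standardised."""
    r = _rdm_correlation(rdm_contra, rdm_ipsi, method)
    return RdmComparison(r=r, z=fisher_z(r), kind="homotopy", method=method)


def control_template(control_rdms: list[RDM], exclude: int | None = None) -> RDM:
    """Entrywise mean of control contralateral RDMs — the "typical"
    contralateral representation.  ``exclude`` drops one control (used
    when scoring a control subject against the template)."""
    rdms = [r for i, r in enumerate(control_rdms) if i != exclude]
    if not rdms:
        raise ValueError("empty control set")
    return mean_rdm(rdms, role="control_template")


def typicality(rdm_subject: RDM, rdm_control_template: RDM, method: str = "pearson") -> RdmComparison:
    """Similarity of a subject's RDM to the average contralateral RDM of
    the controls, Fisher r-to-z standardised."""
    r = _rdm_correlation(rdm_subject, rdm_control_template, method)
    return RdmComparison(r=r, z=fisher_z(r), kind="typicality", method=method)
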