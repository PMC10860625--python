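"""Multivoxel pattern simulation with known representational geometry.

Condition mean patterns are constructed by classical multidimensional
scaling of a target RDM into a latent space and embedded into voxel
space through a random orthonormal map, so the noiseless pairwise
squared Euclidean distances reproduce the target exactly.  Run-wise
patterns add spatially correlated Gaussian noise drawn from a supplied
voxel covariance; matching residual series are generated from the same
covariance so the noise-normalisation stage can estimate it.

The ipsilateral hemisphere's latent geometry interpolates between
independent (homotopy 0) and identical to the contralateral geometry
(homotopy 1) via ``h * U + sqrt(1 - h^2) * W`` with an independent
latent configuration ``W`` of matched scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .rdm import RDM


@dataclass
class PatternSet:
    """Run-wise condition x voxel patterns plus residual series."""

    patterns: np.ndarray  # (n_runs, n_conditions, n_voxels)
    residuals: np.ndarray  # (n_runs, n_residual_samples, n_voxels)
    condition_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be (runs, conditions, voxels)")
        if self.patterns.shape[0] < 2:
            raise ValueError("need >= 2 runs for cross-validated distances")

    @property
    def n_runs(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]


@dataclass
class PatternGroundTruth:
    true_rdm_contra: RDM
    homotopy_level: float = 0.0
    signal_scale_by_hemisphere: tuple[float, float] = (1.0, 1.0)  # (contra, ipsi)
    noise_covariance: np.ndarray | float = 1.0  # scalar -> sigma^2 * I
    n_voxels: int = 100
    n_runs: int = 4
    n_residual_samples: int = 120

    def __post_init__(self) -> None:
        if not -1.0 <= self.homotopy_level <= 1.0:
            raise ValueError("homotopy_level must be in [-1, 1]")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")

    def covariance_matrix(self) -> np.ndarray:
        if np.isscalar(self.noise_covariance):
            return float(self.noise_covariance) * np.eye(self.n_voxels)
        C = np.asarray(self.noise_covariance, dtype=float)
        if C.shape != (self.n_voxels, self.n_voxels):
            raise ValueError("noise_covariance must be n_voxels x n_voxels")
        if not np.allclose(C, C.T):
            raise ValueError("noise_covariance must be symmetric")
        return C


def mds_embed(rdm: RDM, n_voxels: int) -> np.ndarray:
    """Latent condition configuration whose squared Euclidean distances
    equal ``rdm.values * n_voxels`` (RDM entries are per-voxel squared
    distances).  Classical MDS; small negative eigenvalues are clipped,
    a strongly non-Euclidean RDM raises."""
    D2 = rdm.as_matrix() * n_voxels
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("target RDM is not Euclidean-embeddable")
    w = np.clip(w, 0.0, None)
    U = V * np.sqrt(w)  # (n_conditions, n_latent)
    return U[:, ::-1]  # dominant axes first


def _random_orthonormal_rows(k: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """(k, p) matrix with orthonormal rows (requires p >= k)."""
    if p < k:
        raise ValueError("need at least as many voxels as latent dimensions")
    A = rng.standard_normal((p, k))
    Q, _ = np.linalg.qr(A)
    return Q[:, :k].T


def _matched_scale_latent(U: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent centered latent configuration with the same total
    variance as U (so mixing weights trade geometry, not magnitude)."""
    W = rng.standard_normal(U.shape)
    W -= W.mean(axis=0, keepdims=True)
    norm_u = np.linalg.norm(U)
    norm_w = np.linalg.norm(W)
    if norm_w > 0 and norm_u > 0:
        W *= norm_u / norm_w
    return W


def simulate_patterns(
    gt: PatternGroundTruth,
    seed: int | np.random.Generator = 0,
) -> tuple[PatternSet, PatternSet]:
    """(contra, ipsi) pattern sets with the requested geometry.

    The contralateral noiseless means reproduce ``true_rdm_contra``
    exactly (per-voxel squared distances); run-wise noise is drawn
    independently per run so cross-validated distance estimates are
    unbiased for the target.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = gt.covariance_matrix()
    # cholesky also validates positive definiteness
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise_covariance must be positive definite") from exc

    U = mds_embed(gt.true_rdm_contra, gt.n_voxels)
    h = gt.homotopy_level
    W = _matched_scale_latent(U, rng)
    U_ipsi = h * U + np.sqrt(max(0.0, 1.0 - h * h)) * W

    labels = gt.true_rdm_contra.labels
    out = []
    for hemi, latent, scale in (
        ("contra", U, gt.signal_scale_by_hemisphere[0]),
        ("ipsi", U_ipsi, gt.signal_scale_by_hemisphere[1]),
    ):
        Q = _random_orthonormal_rows(latent.shape[1], gt.n_voxels, rng)
        means = scale * (latent @ Q)  # (n_conditions, n_voxels)
        pats = np.empty((gt.n_runs, len(labels), gt.n_voxels))
        resid = np.empty((gt.n_runs, gt.n_residual_samples, gt.n_voxels))
        for m in range(gt.n_runs):
            noise = rng.standard_normal((len(labels), gt.n_voxels)) @ L.T
            pats[m] = means + noise
            resid[m] = rng.standard_normal((gt.n_residual_samples, gt.n_voxels)) @ L.T
        out.append(
            PatternSet(
                patterns=pats,
                residuals=resid,
                condition_labels=labels,
                meta={"hemisphere": hemi, "signal_scale": scale, "homotopy_level": h},
            )
        )
    return out[0], out[1]


def save_pattern_set(ps: PatternSet, directory) -> None:
    """Serialise to a directory of per-run CSVs plus a JSON manifest."""
    import json
    from pathlib import Path

    import pandas as pd

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for m in range(ps.n_runs):
        pd.DataFrame(ps.patterns[m], index=list(ps.condition_labels)).to_csv(
            d / f"run{m:02d}_patterns.csv"
        )
        pd.DataFrame(ps.residuals[m]).to_csv(d / f"run{m:02d}_residuals.csv", index=False)
    (d / "manifest.json").write_text(
        json.dumps(
            {
                "condition_labels": list(ps.condition_labels),
                "n_runs": ps.n_runs,
                "n_voxels": ps.n_voxels,
                "meta": ps.meta,
            },
            indent=2,
        )
    )


def load_pattern_set(directory) -> PatternSet:
    import json
    from pathlib import Path

    import pandas as pd

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    pats, resids = [], []
    for m in range(manifest["n_runs"]):
        pats.append(pd.read_csv(d / f"run{m:02d}_patterns.csv", index_col=0).to_numpy(float))
        resids.append(pd.read_csv(d / f"run{m:02d}_residuals.csv").to_numpy(float))
    return PatternSet(
        patterns=np.stack(pats),
        residuals=np.stack(resids),
        condition_labels=tuple(manifest["condition_labels"]),
        meta=manifest.get("meta", {}),
    )


def latent_rdm(latent: np.ndarray, n_voxels: int, labels) -> RDM:
    """Per-voxel squared-distance RDM implied by a latent configuration."""
    return RDM(labels=tuple(labels), values=pdist(latent, metric="sqeuclidean") / n_voxels)
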