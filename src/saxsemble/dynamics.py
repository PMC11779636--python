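"""Ensemble statistics and decomposition of conformational heterogeneity.

Given a superposed conformer ensemble this module computes per-residue
r.m.s.f., finds the invariant core by iterative ellipsoid-volume pruning,
decomposes the coordinate covariance by PCA (variance fractions, per-residue
amplitudes, min-to-max interpolation trajectories), builds the atomic
movement similarity matrix (AMSM, a dynamic cross-correlation of positional
deviations), clusters members in PC space, and correlates r.m.s.f. with
crystallographic B-factors.

All per-residue vectors follow the ensemble's ``residue_numbers`` order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .structures import Conformer, ConformerEnsemble

__all__ = [
    "CoreResult",
    "PCAResult",
    "MovementSimilarityMatrix",
    "per_residue_rmsf",
    "find_invariant_core",
    "ensemble_pca",
    "per_residue_pc_amplitude",
    "interpolate_pc_trajectory",
    "movement_similarity_matrix",
    "cluster_pc_space",
    "rmsf_bfactor_correlation",
]

#: Default ellipsoid-volume cutoff (Å³) at which pruning stops; the valley
#: of the volume-vs-residues derivative can be used instead (cutoff=None).
DEFAULT_CORE_VOLUME_CUTOFF = 150.0


@dataclass(frozen=True)
class CoreResult:
    """Trajectory and outcome of the invariant-core search.

    ``iterations`` records, per pruning round, the removed residue, the
    remaining residue count and the total ellipsoid volume (Å³) over the
    remaining residues after re-superposition.
    """

    iterations: pd.DataFrame
    core_residues: np.ndarray
    volume_cutoff: float

    @property
    def n_core(self) -> int:
        return len(self.core_residues)


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the 3N-coordinate covariance across members.

    ``eigenvectors`` rows are orthonormal 3N modes sorted by descending
    eigenvalue (Å²); ``projections`` holds each member's coordinates
    projected on each mode; ``variance_fractions`` are cumulative.
    """

    residue_numbers: np.ndarray
    mean_coords: np.ndarray  # (N, 3)
    eigenvalues: np.ndarray  # (k,)
    eigenvectors: np.ndarray  # (k, 3N)
    projections: np.ndarray  # (M, k)
    total_variance: float

    @property
    def variance_fractions(self) -> np.ndarray:
        return np.cumsum(self.eigenvalues) / self.total_variance

    def n_components_for(self, fraction: float) -> int:
        """Smallest number of leading components covering ``fraction`` of variance."""
        return int(np.searchsorted(self.variance_fractions, fraction) + 1)


@dataclass(frozen=True)
class MovementSimilarityMatrix:
    """AMSM: normalized cross-correlation of residue displacement vectors."""

    values: np.ndarray
    residue_numbers: np.ndarray
    zero_fluctuation: np.ndarray  # bool flags for residues with no motion

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.residue_numbers, columns=self.residue_numbers)


def _deviations(ensemble: ConformerEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """(M, N, 3) deviations from the ensemble-mean structure, plus the mean."""
    x = ensemble.coordinate_array()
    mean = x.mean(axis=0)
    return x - mean, mean


def per_residue_rmsf(
    ensemble: ConformerEnsemble,
    superpose_subset: Sequence[int] | None = None,
    presuperposed: bool = False,
) -> np.ndarray:
    """Per-residue root-mean-square fluctuation (Å) about the mean structure.

    rmsf_i = sqrt( mean_m |r_i^(m) − ⟨r_i⟩|² ).  Members are superposed on
    ``superpose_subset`` first unless ``presuperposed``.
    """
    if not presuperposed:
        ensemble = ensemble.superposed(superpose_subset)
    dev, _ = _deviations(ensemble)
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def _per_residue_ellipsoid_volumes(ensemble: ConformerEnsemble) -> np.ndarray:
    """Ellipsoid volume (Å³) of each residue's positional spread across members.

    v_i = (4/3)·π·sqrt(λ1·λ2·λ3) with λ the eigenvalues of the residue's
    3×3 positional covariance over members — the volume of the ellipsoid
    whose semi-axes are one standard deviation along each principal axis.
    """
    dev, _ = _deviations(ensemble)
    m = dev.shape[0]
    # covariance per residue: (N, 3, 3)
    cov = np.einsum("mni,mnj->nij", dev, dev) / m
    lam = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    return (4.0 / 3.0) * np.pi * np.sqrt(np.prod(lam, axis=1))


def find_invariant_core(
    ensemble: ConformerEnsemble,
    volume_cutoff: float | None = DEFAULT_CORE_VOLUME_CUTOFF,
    min_core: int = 3,
) -> CoreResult:
    """Iterative ellipsoid-volume pruning to find the invariant core.

    Each round superposes all members on the current residue set, computes
    each residue's positional-covariance ellipsoid volume across members,
    and removes the residue with the largest volume.  With a numeric
    ``volume_cutoff`` pruning stops once the largest per-residue volume
    falls to or below it; with ``volume_cutoff=None`` the stopping point is
    chosen automatically at the valley of the (3-point smoothed) first
    difference of total volume versus remaining residue count.
    """
    residues = list(ensemble.residue_numbers)
    records: list[tuple[int | None, int, float, float]] = []
    states: list[list[int]] = []

    current = list(residues)
    removed_last: int | None = None
    while True:
        sup = ensemble.superposed(current)
        sub = ConformerEnsemble(
            [c.subset(current) for c in sup], reference_index=ensemble.reference_index
        )
        vols = _per_residue_ellipsoid_volumes(sub)
        total = float(vols.sum())
        vmax_idx = int(np.argmax(vols))
        vmax = float(vols[vmax_idx])
        records.append((removed_last, len(current), total, vmax))
        states.append(list(current))
        if volume_cutoff is not None and vmax <= volume_cutoff:
            break
        if len(current) <= min_core:
            if volume_cutoff is not None:
                raise ValueError(
                    f"core would shrink below {min_core} residues before reaching "
                    f"the {volume_cutoff} ų cutoff"
                )
            break
        removed_last = current[vmax_idx]
        current = current[:vmax_idx] + current[vmax_idx + 1 :]

    table = pd.DataFrame(
        records, columns=["removed_residue", "remaining", "total_volume", "max_residue_volume"]
    )
    if volume_cutoff is None:
        # automatic cutoff: the valley of the derivative of total volume
        # with respect to remaining-residue count — pruning stops at the
        # first removal whose (3-point smoothed) volume shed drops below 1%
        # of the largest shed, i.e. where removals stop paying off
        tv = table["total_volume"].to_numpy()
        if len(tv) < 3 or tv[0] <= 0:
            stop = 0
        else:
            shed = -np.diff(tv)  # volume shed by each removal
            smooth = np.convolve(shed, np.ones(3) / 3.0, mode="same")
            below = np.flatnonzero(smooth < 0.01 * smooth.max())
            stop = int(below[0]) if below.size else len(tv) - 1
        core = np.array(states[stop], dtype=int)
        cutoff = float(table["max_residue_volume"].iloc[stop])
    else:
        core = np.array(states[-1], dtype=int)
        cutoff = float(volume_cutoff)
    return CoreResult(iterations=table, core_residues=core, volume_cutoff=cutoff)


def ensemble_pca(
    ensemble: ConformerEnsemble,
    superpose_subset: Sequence[int] | None = None,
    presuperposed: bool = False,
) -> PCAResult:
    """PCA of the coordinate covariance across ensemble members.

    Members are superposed on ``superpose_subset`` (typically the invariant
    core), flattened to 3N vectors, and decomposed by SVD of the centred
    coordinate matrix — equivalent to diagonalizing the 3N×3N covariance.
    Eigenvector signs follow the convention that the largest-magnitude
    coefficient is positive.
    """
    if not presuperposed:
        ensemble = ensemble.superposed(superpose_subset)
    dev, mean = _deviations(ensemble)
    m, n, _ = dev.shape
    flat = dev.reshape(m, 3 * n)
    u, s, vt = np.linalg.svd(flat, full_matrices=False)
    eigenvalues = s**2 / m  # population covariance convention
    # deterministic sign: largest-|coefficient| entry positive
    for row in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[row])))
        if vt[row, j] < 0:
            vt[row] *= -1.0
    projections = flat @ vt.T
    total_var = float(np.sum(flat**2) / m)
    return PCAResult(
        residue_numbers=ensemble.residue_numbers,
        mean_coords=mean,
        eigenvalues=eigenvalues,
        eigenvectors=vt,
        projections=projections,
        total_variance=total_var,
    )


def per_residue_pc_amplitude(pca: PCAResult, component: int = 0) -> np.ndarray:
    """Motion amplitude of each residue in one principal component (Å).

    amplitude_i = sqrt(eigenvalue) · ‖eigenvector coefficients of residue i‖,
    so the squared amplitudes over residues sum to the eigenvalue.
    """
    if not 0 <= component < len(pca.eigenvalues):
        raise IndexError(f"component {component} out of range")
    vec = pca.eigenvectors[component].reshape(-1, 3)
    return np.sqrt(pca.eigenvalues[component]) * np.linalg.norm(vec, axis=1)


def interpolate_pc_trajectory(
    pca: PCAResult, component: int = 0, n_frames: int = 11
) -> ConformerEnsemble:
    """Min-to-max interpolation of the ensemble along one principal component.

    Frames are the mean structure displaced along the component's
    eigenvector by amplitudes spanning linearly from the minimum to the
    maximum observed projection.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if not 0 <= component < len(pca.eigenvalues):
        raise IndexError(f"component {component} out of range")
    proj = pca.projections[:, component]
    amplitudes = np.linspace(proj.min(), proj.max(), n_frames)
    mode = pca.eigenvectors[component].reshape(-1, 3)
    members = [
        Conformer(
            id=f"pc{component + 1}_frame{i:03d}",
            residue_numbers=pca.residue_numbers,
            coords=pca.mean_coords + t * mode,
        )
        for i, t in enumerate(amplitudes)
    ]
    return ConformerEnsemble(members)


def movement_similarity_matrix(
    ensemble: ConformerEnsemble,
    superpose_subset: Sequence[int] | None = None,
    presuperposed: bool = False,
) -> MovementSimilarityMatrix:
    """Atomic movement similarity matrix (AMSM).

    Entry (i, j) = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over members,
    where Δr is the deviation from the mean position — the standard dynamic
    cross-correlation, in [−1, 1] with unit diagonal.  Residues with zero
    fluctuation get 0 off-diagonal (flagged) and 1 on the diagonal.
    """
    if not presuperposed:
        ensemble = ensemble.superposed(superpose_subset)
    dev, _ = _deviations(ensemble)
    m = dev.shape[0]
    inner = np.einsum("mik,mjk->ij", dev, dev) / m
    var = np.diag(inner).copy()
    # relative threshold: catches exact rigidity despite float cancellation
    zero = var <= 1e-12 * max(var.max(), 1e-300)
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    values = inner / denom
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    return MovementSimilarityMatrix(
        values=values, residue_numbers=ensemble.residue_numbers, zero_fluctuation=zero
    )


def cluster_pc_space(
    pca: PCAResult, n_components: int = 7, n_clusters: int = 3
) -> np.ndarray:
    """Hierarchical clustering of members in truncated PC-projection space.

    Average-linkage, Euclidean distance, deterministic.  Returns integer
    labels 1..n_clusters per member.
    """
    m = pca.projections.shape[0]
    if n_clusters > m:
        raise ValueError("more clusters than members")
    x = pca.projections[:, : min(n_components, pca.projections.shape[1])]
    z = linkage(x, method="average", metric="euclidean")
    return fcluster(z, t=n_clusters, criterion="maxclust")


def rmsf_bfactor_correlation(
    rmsf: np.ndarray, bfactors: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pearson correlation of per-residue r.m.s.f. against B-factors.

    Both vectors are min-max normalized (for plotting parity; the affine
    rescaling leaves Pearson r unchanged).  Residues with non-finite
    B-factors are masked out.  Returns (r, norm_rmsf, norm_bfactor) over the
    masked residues.
    """
    rmsf = np.asarray(rmsf, dtype=float)
    b = np.asarray(bfactors, dtype=float)
    if rmsf.shape != b.shape:
        raise ValueError("rmsf and bfactors must have equal length")
    mask = np.isfinite(b) & np.isfinite(rmsf)
    x, y = rmsf[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    r, _ = pearsonr(xn, yn)
    return float(r), xn, yn
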